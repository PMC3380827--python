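#!/usr/bin/env python
"""Map the POLLED locus by shared homozygosity with a permutation null.

Reads the simulated panel (falling back to regenerating it), computes the
per-marker statistic, derives the genome-wide significance threshold from
marker permutations, and extracts the homozygous core plus its informative
flanking markers.  The candidate interval between the flankers is the mapping
result handed to the resequencing stages.
"""

import argparse
from pathlib import Path

from polledmap import io, mapping, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=500)
    ap.add_argument("--alpha", type=float, default=0.01)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/mapping"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    if (args.datadir / "panel.ped").exists():
        panel = io.read_ped_map(args.datadir / "panel")
    else:
        panel = simulate.generate_genotype_panel(simulate.PanelSpec(seed=args.seed))

    result = mapping.map_locus(panel, n_perm=args.n_perm, alpha=args.alpha,
                               seed=args.seed + 10)
    report = mapping.extract_candidate_interval(result, panel)

    io.write_stats_tsv(panel, result.stats, result.pvalues,
                       args.outdir / "asshom.tsv")
    io.write_intervals_bed(result.significant_intervals,
                           args.outdir / "significant.bed")

    print(f"genome-wide threshold (alpha={args.alpha}, {args.n_perm} "
          f"permutations): {result.threshold:.3f}")
    print(f"significant markers: {(result.stats > result.threshold).sum()}")
    if report.candidate_interval is not None:
        ci = report.candidate_interval
        left, right = report.flanking_markers
        print(f"homozygous core: {report.core_marker_count} markers "
              f"({report.core_interval.start:,}-{report.core_interval.end:,})")
        print(f"informative flanking markers: {left} / {right}")
        print(f"candidate interval: {ci.start:,}-{ci.end:,} "
              f"({round((ci.end - ci.start) / 1000)} kb)")


if __name__ == "__main__":
    main()
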