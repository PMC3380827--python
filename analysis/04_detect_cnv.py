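#!/usr/bin/env python
"""Detect large copy-number events from group read-depth ratios.

Builds dynamic 400-read bins on the reference (horned) track, computes
median-centred log2 coverage ratios of the target (polled) track, segments the
ratio profile with circular binary segmentation and calls segments with a high
positive mean as duplications.
"""

import argparse
from pathlib import Path

from polledmap import catalog, cnv, io, simulate
from polledmap.intervals import interval_length


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bin-reads", type=int, default=400)
    ap.add_argument("--min-log2", type=float, default=0.4)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/cnv"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    if (args.datadir / "reads_reference.bed").exists():
        ref = io.read_read_track_bed(args.datadir / "reads_reference.bed",
                                     catalog.TARGET_REGION)
        tgt = io.read_read_track_bed(args.datadir / "reads_target.bed",
                                     catalog.TARGET_REGION)
    else:
        ref, tgt = simulate.generate_read_tracks(
            catalog.P_80KBID_INTERVAL, catalog.TARGET_REGION,
            rate_per_bp=0.2, copy_ratio=2.0, seed=args.seed + 2)

    bins = cnv.dynamic_bins(ref, n_reads=args.bin_reads)
    track = cnv.log2_ratio_track(bins, tgt)
    io.write_bedgraph(catalog.CHROM, track["start"], track["end"],
                      track["log2_ratio"], args.outdir / "log2_ratios.bedgraph")

    segments = cnv.segment_ratios(track, seed=args.seed + 20)
    calls = cnv.call_duplication(segments, catalog.CHROM,
                                 min_log2=args.min_log2, min_span_bp=20_000)
    io.write_intervals_bed([c.interval for c in calls],
                           args.outdir / "dup_calls.bed",
                           names=[c.id for c in calls])

    print(f"{len(bins)} dynamic bins ({args.bin_reads} reference reads each), "
          f"{len(segments)} segments")
    for s in segments:
        print(f"  segment {s.start_bp:,}-{s.end_bp:,}: mean log2 {s.mean:+.3f} "
              f"({s.n_bins} bins)")
    for c in calls:
        print(f"duplication call: {c.interval.start:,}-{c.interval.end:,} "
              f"({interval_length(c.interval):,} bp); planted event "
              f"{catalog.P_80KBID_INTERVAL.start:,}-{catalog.P_80KBID_INTERVAL.end:,} "
              f"({interval_length(catalog.P_80KBID_INTERVAL):,} bp)")


if __name__ == "__main__":
    main()
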