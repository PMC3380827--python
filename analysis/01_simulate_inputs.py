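#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes a case/control SNP panel (PED/MAP) with a planted nine-marker shared
homozygous haplotype, a sixteen-sire resequencing variant table with
group-private causal alleles, read-start tracks with a planted 80 kb
duplication, and the population allele-call table with pedigree records.
"""

import argparse
from pathlib import Path

from polledmap import catalog, io, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    panel = simulate.generate_genotype_panel(simulate.PanelSpec(seed=args.seed))
    io.write_ped_map(panel, out / "panel")
    print(f"panel: {panel.n_animals} animals x {panel.n_markers} markers "
          f"({len(panel.case_indices)} cases, {len(panel.control_indices)} controls)")

    table = simulate.generate_variant_tables(simulate.ReseqSpec(seed=args.seed + 1))
    io.write_variant_table(table, out / "variants.tsv", out / "samples.tsv")
    print(f"resequencing table: {len(table.records)} records over "
          f"{table.records[['chrom', 'pos']].drop_duplicates().shape[0]} sites, "
          f"{len(table.samples)} sires")

    ref, tgt = simulate.generate_read_tracks(
        catalog.P_80KBID_INTERVAL, catalog.TARGET_REGION,
        rate_per_bp=0.2, copy_ratio=2.0, seed=args.seed + 2)
    io.write_read_track_bed(ref, out / "reads_reference.bed")
    io.write_read_track_bed(tgt, out / "reads_target.bed")
    print(f"read tracks: {len(ref)} reference / {len(tgt)} target starts "
          f"(duplication planted at "
          f"{catalog.P_80KBID_INTERVAL.start}-{catalog.P_80KBID_INTERVAL.end})")

    calls, pedigree = simulate.generate_population_table(seed=args.seed + 3)
    calls.to_csv(out / "allele_calls.tsv", sep="\t", index=False)
    pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    print(f"population table: {len(calls)} genotyped animals, "
          f"{len(pedigree)} pedigree records")


if __name__ == "__main__":
    main()
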