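#!/usr/bin/env python
"""Rank the Friesian candidate variants by conservation context.

Applies the rule-based prioritiser to the five P_F block members using
synthetic conservation profiles that encode the published qualitative
descriptions (repeat-masked InDel/SNV, the goat-shared base, the 24-nt block
identical in all bovids, the large duplication).
"""

import argparse
from pathlib import Path

from polledmap import catalog, conservation
from polledmap.pipeline import demo_conservation_profiles


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tau-hi", type=float, default=0.8)
    ap.add_argument("--tau-lo", type=float, default=0.3)
    ap.add_argument("--outdir", type=Path, default=Path("results/ranking"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ranked = conservation.rank_candidates(
        list(catalog.FRIESIAN_BLOCK.members), demo_conservation_profiles(),
        tau_hi=args.tau_hi, tau_lo=args.tau_lo)
    ranked.to_csv(args.outdir / "ranked_candidates.tsv", sep="\t", index=False)

    print(f"category thresholds: bovid mean >= {args.tau_hi}, "
          f"unhorned mean <= {args.tau_lo}")
    for _, row in ranked.iterrows():
        rank = int(row["rank"]) if row["rankable"] else "-"
        print(f"  {rank}\t{row['id']}\t{row['category']}")


if __name__ == "__main__":
    main()
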