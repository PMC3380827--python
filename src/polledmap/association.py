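"""Population-level analysis of the two candidate POLLED alleles.

Consumes an allele-call table (per-animal copy numbers of the Celtic allele P_C
and the Friesian haplotype P_F plus per-variant genotypes of the typed
candidates) and pedigree/progeny records.  Provides the perfect-association
test under dominance, the compound-heterozygote scan, the within-block
recombination check, progeny-based PP/Pp declaration and the genotype
cross-tabulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import HaplotypeBlock

ALLELE_COLUMNS = ("pc_copies", "pf_copies")


@dataclass
class AssociationReport:
    holds: bool
    violations: List[str] = field(default_factory=list)
    degenerate: bool = False
    n_evaluated: int = 0


def _validate_calls(table: pd.DataFrame) -> None:
    for col in ALLELE_COLUMNS + ("animal", "phenotype"):
        if col not in table.columns:
            raise ValueError(f"allele-call table missing column {col!r}")
    copies = table[list(ALLELE_COLUMNS)].sum(axis=1)
    if (copies.dropna() > 2).any():
        raise ValueError("total allele copies exceed 2 for some animal")


def perfect_association_test(table: pd.DataFrame) -> AssociationReport:
    """Test that allele carriage and the polled phenotype coincide exactly.

    Holds iff every carrier of >=1 copy of either allele is polled, every
    polled animal carries >=1 copy, and every horned animal carries none.
    Horned animals with unknown (missing) candidate genotypes are excluded
    rather than imputed.  An empty table holds vacuously, flagged degenerate.
    """
    _validate_calls(table)
    t = table.copy()
    typed = t[list(ALLELE_COLUMNS)].notna().all(axis=1)
    t = t[typed & t["phenotype"].isin(["polled", "horned"])]
    if len(t) == 0:
        return AssociationReport(holds=True, degenerate=True)

    copies = t["pc_copies"].to_numpy() + t["pf_copies"].to_numpy()
    polled = (t["phenotype"] == "polled").to_numpy()
    violations = []
    for animal, c, is_polled in zip(t["animal"], copies, polled):
        if c >= 1 and not is_polled:
            violations.append(f"{animal}: carries {c:g} mutant copies but is horned")
        elif c == 0 and is_polled:
            violations.append(f"{animal}: polled without any candidate allele")
    return AssociationReport(holds=not violations, violations=violations,
                             n_evaluated=len(t))


def compound_heterozygote_scan(table: pd.DataFrame) -> pd.DataFrame:
    """Animals carrying exactly one copy of each allele (P_C/P_F).

    Under dominance a compound heterozygote transmits a mutant allele to every
    offspring, so all progeny from horned mates are expected polled; the
    prediction is annotated per animal.
    """
    _validate_calls(table)
    hit = table[(table["pc_copies"] == 1) & (table["pf_copies"] == 1)].copy()
    hit["predicted_offspring_vs_horned_mates"] = "all polled"
    return hit.reset_index(drop=True)


def block_recombination_check(table: pd.DataFrame,
                              block: HaplotypeBlock) -> List[str]:
    """Animals whose typed copy numbers differ across block members.

    Expects per-variant genotype columns named ``gt_<variant id>``.  Animals
    with an untyped member are skipped with a warning.
    """
    cols = [f"gt_{m.id}" for m in block.members]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks genotype columns: {missing_cols}")
    recombinant = []
    skipped = 0
    for _, row in table.iterrows():
        values = row[cols]
        if values.isna().any():
            skipped += 1
            continue
        if values.nunique() > 1:
            recombinant.append(str(row["animal"]))
    if skipped:
        warnings.warn(f"{skipped} animals skipped: untyped block member")
    return recombinant


def declare_genotype(pedigree: pd.DataFrame, animal: str,
                     n_required: int = 12) -> Tuple[str, Optional[float]]:
    """Progeny-based POLLED genotype declaration for a polled animal.

    One horned offspring from a horned mate is sufficient for Pp.  With
    ``n_required`` or more consecutive polled offspring from horned mates and
    none horned, the animal is declared PP with misclassification probability
    0.5**n (the chance a true Pp produces n polled offspring in a row from
    horned mates); otherwise undeclared.  Pedigree columns: animal, sire, dam,
    phenotype.
    """
    ped = pedigree.set_index("animal")
    if ped.loc[animal, "phenotype"] != "polled":
        raise ValueError(f"{animal}: genotype declaration requires a polled proband")

    pheno = ped["phenotype"]
    offspring = pedigree[(pedigree["sire"] == animal) | (pedigree["dam"] == animal)]
    mate = np.where(offspring["sire"] == animal, offspring["dam"], offspring["sire"])
    from_horned = offspring[[pheno.get(m, "unknown") == "horned" for m in mate]]

    n_horned = int((from_horned["phenotype"] == "horned").sum())
    n_polled = int((from_horned["phenotype"] == "polled").sum())
    if n_horned >= 1:
        return "Pp", None
    if n_polled >= n_required:
        return "PP", 0.5 ** n_polled
    return "undeclared", None


def genotype_distribution_summary(table: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Cross-tabulation of (P_C copies x P_F copies) with percentages.

    Returns counts, percentages of the typed total (rounded to 2 decimals) and
    a breed-resolved count table.
    """
    _validate_calls(table)
    t = table.dropna(subset=list(ALLELE_COLUMNS)).copy()
    counts = pd.crosstab(t["pc_copies"].astype(int), t["pf_copies"].astype(int))
    counts.index.name, counts.columns.name = "pc_copies", "pf_copies"
    pct = (100.0 * counts / counts.to_numpy().sum()).round(2)
    by_breed = (t.groupby(["breed", "pc_copies", "pf_copies"]).size()
                .rename("n").reset_index()
                if "breed" in t.columns else pd.DataFrame())
    return {"counts": counts, "percent": pct, "by_breed": by_breed}
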