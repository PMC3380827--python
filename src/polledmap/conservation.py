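"""Rule-based prioritisation of candidate variants from conservation scores.

Consumes precomputed per-base conservation scores (phastCons-style, in [0, 1])
for three species groups — bovid ruminants, unhorned mammals and all aligned
species — plus a repeat mask and, where available, the base observed in
another bovid at the candidate position.  A variant in functional sequence
specific to horned ruminants should sit in a window conserved among bovids but
not among unhorned mammals; a variant allele segregating as the normal base in
another bovid argues against functional constraint; repeat-masked positions
cannot be scored at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import CandidateVariant, VariantKind

GROUPS = ("bovid", "unhorned", "all")

CATEGORY_ORDER = ["most_plausible", "intermediate", "least_likely", "unlikely",
                  "unrankable"]


@dataclass
class ConservationProfile:
    """Conservation context of one candidate position.

    ``scores``: per-group arrays of per-base scores over a window centred on
    the candidate; ``repeat_masked``: the position lies in repeat-masked /
    unalignable sequence; ``cross_species_allele``: base observed at the
    orthologous position in another bovid, if known.
    """

    scores: Dict[str, np.ndarray] = field(default_factory=dict)
    repeat_masked: bool = False
    cross_species_allele: Optional[str] = None

    def __post_init__(self) -> None:
        for g, arr in self.scores.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{g}: conservation scores must lie in [0, 1]")
            self.scores[g] = arr

    def mean(self, group: str) -> float:
        arr = self.scores.get(group)
        return float(np.mean(arr)) if arr is not None and len(arr) else np.nan


def _categorise(variant: CandidateVariant, profile: Optional[ConservationProfile],
                tau_hi: float, tau_lo: float) -> str:
    if variant.kind is VariantKind.LARGE_DUP:
        # element-level conservation does not capture what a large duplication
        # may do; large events are always retained as plausible
        return "most_plausible"
    if profile is None:
        return "unrankable"
    if profile.repeat_masked:
        return "unlikely"
    if (profile.cross_species_allele is not None
            and profile.cross_species_allele.upper() == variant.alt_allele.upper()):
        return "least_likely"
    bovid, unhorned = profile.mean("bovid"), profile.mean("unhorned")
    if not np.isnan(bovid) and not np.isnan(unhorned) \
            and bovid >= tau_hi and unhorned <= tau_lo:
        return "most_plausible"
    return "intermediate"


def rank_candidates(candidates: Sequence[CandidateVariant],
                    profiles: Dict[str, Optional[ConservationProfile]],
                    window_bp: int = 25, tau_hi: float = 0.8,
                    tau_lo: float = 0.3) -> pd.DataFrame:
    """Order candidates most-plausible first with category labels.

    Categories: large events and bovid-only-conserved variants are most
    plausible; variants whose alt allele is the normal base of another bovid
    are least likely; repeat-masked variants are unlikely (no score can be
    computed); candidates without a profile are unrankable.  Within a
    category, ties sort by mean bovid conservation (large events first).
    Output carries the thresholds used, so the ranking is auditable.
    """
    rows = []
    for v in candidates:
        profile = profiles.get(v.id)
        cat = _categorise(v, profile, tau_hi, tau_lo)
        bovid = profile.mean("bovid") if profile is not None else np.nan
        rankable = cat not in ("unlikely", "unrankable")
        rows.append({
            "id": v.id, "kind": v.kind.value, "position": v.position,
            "category": cat, "bovid_score": bovid, "rankable": rankable,
            "tau_hi": tau_hi, "tau_lo": tau_lo, "window_bp": window_bp,
        })
    df = pd.DataFrame(rows)
    df["category"] = pd.Categorical(df["category"], categories=CATEGORY_ORDER,
                                    ordered=True)
    df["_dup"] = df["kind"] == VariantKind.LARGE_DUP.value
    df = df.sort_values(["category", "_dup", "bovid_score"],
                        ascending=[True, False, False], kind="mergesort")
    df["rank"] = np.where(df["rankable"], np.arange(1, len(df) + 1), np.nan)
    # re-number ranks over rankable candidates only
    df.loc[df["rankable"], "rank"] = np.arange(1, int(df["rankable"].sum()) + 1)
    return df.drop(columns="_dup").reset_index(drop=True)
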