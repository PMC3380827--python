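"""Genotype-class concordance filtering of targeted-resequencing variant calls.

Under a biallelic dominant model and a reference genome derived from a horned
animal, a causative variant must be homozygous-alt in every homozygous polled
(PP) sire (variant allele frequency 95-100%), heterozygous in every carrier
(Pp, 40-60%), undetected in every horned (pp) sire, and different from the
reference allele.  Running the same filter on the pooled sample set and on
breed subgroups separately detects allelic heterogeneity: no shared survivor
overall, but disjoint survivor sets per subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import pandas as pd

RECORD_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "kind",
                  "sample", "depth", "alt_count", "vaf"]

#: Caller sensitivity floor: a variant record exists only at VAF >= this.
CALLER_MIN_VAF = 0.01


@dataclass
class VariantTable:
    """Per-site, per-sample variant records plus the sample sheet.

    ``records``: long-format DataFrame with RECORD_COLUMNS; absence of a record
    for a (site, sample) pair means the variant was undetected in that sample.
    ``samples``: DataFrame with columns id, group, polled_class.
    """

    records: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        bad = set(self.samples["polled_class"]) - {"PP", "Pp", "pp"}
        if bad:
            raise ValueError(f"unknown POLLED class labels: {sorted(bad)}")
        r = self.records
        if len(r) and (((r["vaf"] < 0) | (r["vaf"] > 1)).any()
                       or (r["alt_count"] > r["depth"]).any()):
            raise ValueError("records violate 0<=vaf<=1 or alt_count<=depth")

    def subset(self, sample_ids: Sequence[str]) -> "VariantTable":
        ids = set(sample_ids)
        return VariantTable(
            records=self.records[self.records["sample"].isin(ids)].copy(),
            samples=self.samples[self.samples["id"].isin(ids)].copy(),
        )


@dataclass
class FilterConfig:
    """Acceptance bands and calling thresholds of the concordance filter."""

    pp_band: tuple = (0.95, 1.00)
    het_band: tuple = (0.40, 0.60)
    min_depth: int = 20
    require_absent_in_controls: bool = True
    require_non_reference: bool = True

    def __post_init__(self) -> None:
        for band in (self.pp_band, self.het_band):
            if not (0 <= band[0] <= band[1] <= 1):
                raise ValueError("bands must lie within [0, 1]")
        if self.het_band[1] > self.pp_band[0]:
            raise ValueError("PP and carrier bands must not overlap")


@dataclass
class HeterogeneityReport:
    """Combined vs per-partition filter outcomes."""

    combined_survivors: pd.DataFrame
    partition_survivors: Dict[str, pd.DataFrame]
    heterogeneity: bool
    exclusivity: Dict[str, bool] = field(default_factory=dict)


def concordance_filter(table: VariantTable,
                       config: Optional[FilterConfig] = None) -> pd.DataFrame:
    """Sites concordant with the dominant model in every sample.

    A site survives iff VAF lies in the PP band in every PP sample, in the
    carrier band in every Pp sample, no pp sample has a record there, and the
    alt allele differs from the reference.  Sites where any required (PP/Pp)
    sample is covered below ``min_depth`` are inconclusive and dropped rather
    than failed.  Returns one row per surviving site (chrom, pos, id, ref,
    alt, kind).
    """
    config = config or FilterConfig()
    site_cols = ["chrom", "pos", "id", "ref", "alt", "kind"]
    if len(table.records) == 0:
        return pd.DataFrame(columns=site_cols)

    cls = table.samples.set_index("id")["polled_class"]
    pp_ids = set(cls[cls == "PP"].index)
    het_ids = set(cls[cls == "Pp"].index)
    ctl_ids = set(cls[cls == "pp"].index)

    survivors = []
    for key, site in table.records.groupby(["chrom", "pos"], sort=True):
        by_sample = site.set_index("sample")
        recorded = set(by_sample.index)

        required = by_sample.loc[list(recorded & (pp_ids | het_ids))]
        if len(required) and (required["depth"] < config.min_depth).any():
            continue  # inconclusive coverage, not evidence either way
        if config.require_non_reference and (site["alt"] == site["ref"]).all():
            continue
        if config.require_absent_in_controls and recorded & ctl_ids:
            continue  # any control record at caller sensitivity disqualifies
        lo, hi = config.pp_band
        if not pp_ids <= recorded:
            continue
        if not by_sample.loc[list(pp_ids), "vaf"].between(lo, hi).all():
            continue
        lo, hi = config.het_band
        if not het_ids <= recorded:
            continue
        if het_ids and not by_sample.loc[list(het_ids), "vaf"].between(lo, hi).all():
            continue
        survivors.append(site.iloc[0][site_cols])

    if not survivors:
        return pd.DataFrame(columns=site_cols)
    return pd.DataFrame(survivors).reset_index(drop=True)


def _homref_in_other_pp(table: VariantTable, sites: pd.DataFrame,
                        other_samples: Sequence[str]) -> bool:
    """True if none of ``sites`` is detected in the given PP samples."""
    cls = table.samples.set_index("id")["polled_class"]
    other_pp = [s for s in other_samples if cls.get(s) == "PP"]
    rec = table.records
    hits = rec[rec["sample"].isin(other_pp)
               & rec.set_index(["chrom", "pos"]).index.isin(
                   sites.set_index(["chrom", "pos"]).index)]
    return len(hits) == 0


def subgroup_heterogeneity_scan(table: VariantTable,
                                partitions: Dict[str, Sequence[str]],
                                config: Optional[FilterConfig] = None
                                ) -> HeterogeneityReport:
    """Run the concordance filter on the pooled set and on each partition.

    Heterogeneity is reported when the pooled set yields no survivor while at
    least two partitions each yield >=1 survivor and their survivor sets are
    disjoint.  Cross-partition exclusivity additionally verifies that each
    partition's survivors are homozygous-reference (undetected) in the PP
    samples of every other partition.
    """
    config = config or FilterConfig()
    all_ids = set(table.samples["id"])
    covered = set()
    for name, ids in partitions.items():
        ids = list(ids)
        covered |= set(ids)
        cls = table.samples[table.samples["id"].isin(ids)]["polled_class"]
        if "PP" not in set(cls) or "pp" not in set(cls):
            raise ValueError(f"partition {name!r} must contain >=1 PP and >=1 pp sample")
    if covered != all_ids:
        raise ValueError("partitions must cover all samples")

    combined = concordance_filter(table, config)
    per_part = {name: concordance_filter(table.subset(ids), config)
                for name, ids in partitions.items()}

    keys = {name: set(map(tuple, df[["chrom", "pos"]].to_numpy()))
            for name, df in per_part.items()}
    nonempty = [name for name, k in keys.items() if k]
    disjoint = all(not (keys[a] & keys[b])
                   for i, a in enumerate(nonempty) for b in nonempty[i + 1:])
    heterogeneity = (len(combined) == 0 and len(nonempty) >= 2 and disjoint)

    exclusivity = {}
    for name, df in per_part.items():
        if len(df) == 0:
            continue
        others = [s for n2, ids in partitions.items() if n2 != name for s in ids]
        exclusivity[name] = _homref_in_other_pp(table, df, others)

    return HeterogeneityReport(combined_survivors=combined,
                               partition_survivors=per_part,
                               heterogeneity=heterogeneity,
                               exclusivity=exclusivity)
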