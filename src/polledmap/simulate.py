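"""Synthetic inputs with the statistical structure the study design assumes.

Generators for every pipeline input: a multi-breed SNP panel with a planted
shared homozygous haplotype in all cases; targeted-resequencing variant tables
whose causal events follow genotype-class VAF expectations (near 1.0 in PP,
near 0.5 in Pp, absent in pp) next to class-independent passenger variants;
read-start tracks with a planted duplication; and a population allele-call
table with compound heterozygotes and pedigree links.  Everything is a pure
function of (spec, seed).

Breed structure follows a Balding-Nichols drift model: each breed's allele
frequency at a marker is a Beta draw around the ancestral frequency with a
configurable differentiation parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import catalog
from .cnv import ReadStartTrack
from .filtering import RECORD_COLUMNS, VariantTable
from .intervals import CandidateVariant, Convention, GenomicInterval
from .mapping import GenotypePanel

# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------


@dataclass
class PanelSpec:
    """Design of a synthetic multi-breed case/carrier/control SNP panel.

    Defaults emulate the mapping design at a size where permutation inference
    is exercised meaningfully: a handful of chromosomes at 50K-chip-like
    spacing, a nine-marker shared homozygous core planted in the cases inside
    the causal interval, and Hardy-Weinberg genotypes elsewhere.
    """

    seed: int
    n_chromosomes: int = 5
    markers_per_chromosome: int = 100
    n_cases: int = 20
    n_carriers: int = 0
    n_controls: int = 20
    n_breeds: int = 3
    causal_chrom: str = "1"
    causal_interval: GenomicInterval = field(default_factory=lambda: GenomicInterval(
        "1", 1_600_000, 2_100_000, Convention.INCLUSIVE))
    shared_haplotype_markers: int = 9
    marker_spacing_bp: int = 40_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    fst: float = 0.1
    missing_rate: float = 0.0
    causal_positions: Optional[Sequence[int]] = None
    ensure_informative_flanks: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for n in (self.n_chromosomes, self.markers_per_chromosome, self.n_cases,
                  self.n_controls, self.n_breeds):
            if n <= 0:
                raise ValueError("panel counts must be positive")
        if self.causal_interval.chrom != self.causal_chrom:
            raise ValueError("causal interval must lie on the causal chromosome")


def _breed_freqs(ancestral: np.ndarray, n_breeds: int, fst: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols per-breed allele frequencies, (n_breeds, n_markers)."""
    if fst <= 0:
        return np.tile(ancestral, (n_breeds, 1))
    a = ancestral * (1 - fst) / fst
    b = (1 - ancestral) * (1 - fst) / fst
    f = rng.beta(a, b, size=(n_breeds, len(ancestral)))
    return np.clip(f, 0.01, 0.99)


def generate_genotype_panel(spec: PanelSpec) -> GenotypePanel:
    """Multi-breed panel with a shared homozygous haplotype planted in cases.

    All cases are homozygous for one haplotype across
    ``shared_haplotype_markers`` consecutive markers inside the causal
    interval; carriers are heterozygous there; controls (and everyone
    elsewhere) draw Hardy-Weinberg genotypes at per-breed frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [str(c + 1) for c in range(spec.n_chromosomes)]

    marker_rows = []
    for c in chroms:
        if c == spec.causal_chrom and spec.causal_positions is not None:
            bp = np.asarray(spec.causal_positions, dtype=np.int64)
            if np.any(np.diff(bp) <= 0):
                raise ValueError("causal_positions must be strictly increasing")
        else:
            bp = spec.marker_spacing_bp * (1 + np.arange(spec.markers_per_chromosome))
        for k, p in enumerate(bp):
            marker_rows.append((f"SNP{c}_{k}", c, int(p)))
    markers = pd.DataFrame(marker_rows, columns=["id", "chrom", "bp"])

    M = len(markers)
    ancestral = rng.uniform(spec.maf_low, spec.maf_high, size=M)
    freqs = _breed_freqs(ancestral, spec.n_breeds, spec.fst, rng)

    groups = ([("PP", spec.n_cases), ("Pp", spec.n_carriers), ("pp", spec.n_controls)])
    animal_rows = []
    i = 0
    for cls, n in groups:
        for k in range(n):
            animal_rows.append((f"{cls}_{k}", f"breed{i % spec.n_breeds}", cls))
            i += 1
    animals = pd.DataFrame(animal_rows, columns=["id", "breed", "polled_class"])

    breed_of = animals["breed"].str.removeprefix("breed").astype(int).to_numpy()
    G = rng.binomial(2, freqs[breed_of], size=(len(animals), M)).astype(np.int8)

    core_idx = np.array([], dtype=int)
    if spec.shared_haplotype_markers > 0:
        on_causal = (markers["chrom"] == spec.causal_chrom).to_numpy()
        inside = on_causal & markers["bp"].apply(spec.causal_interval.contains).to_numpy()
        candidates = np.flatnonzero(inside)
        if len(candidates) < spec.shared_haplotype_markers:
            raise ValueError("causal interval holds fewer markers than the "
                             "requested shared haplotype length")
        mid = len(candidates) // 2
        half = spec.shared_haplotype_markers // 2
        start = max(0, min(mid - half, len(candidates) - spec.shared_haplotype_markers))
        core_idx = candidates[start:start + spec.shared_haplotype_markers]
        if np.any(np.diff(core_idx) != 1):
            raise ValueError("markers inside the causal interval are not consecutive")

        hap = rng.integers(0, 2, size=len(core_idx)).astype(np.int8)  # allele per marker
        is_case = (animals["polled_class"] == "PP").to_numpy()
        is_carrier = (animals["polled_class"] == "Pp").to_numpy()
        G[np.ix_(is_case, core_idx)] = 2 * hap
        G[np.ix_(is_carrier, core_idx)] = 1

        if spec.ensure_informative_flanks:
            # the study design had informative chip SNPs bounding the core;
            # make the adjacent markers variable in the case group if a random
            # draw left them uniform
            case_rows = np.flatnonzero(is_case)
            chrom_idx = np.flatnonzero(on_causal)
            for adj in (core_idx[0] - 1, core_idx[-1] + 1):
                if adj < chrom_idx[0] or adj > chrom_idx[-1]:
                    continue
                col = G[case_rows, adj]
                if (col == 1).any() or len(np.unique(col)) > 1:
                    continue
                G[case_rows[0], adj] = 1

    if spec.missing_rate > 0:
        mask = rng.random(G.shape) < spec.missing_rate
        if len(core_idx):
            mask[:, core_idx] = False
        G[mask] = -1

    return GenotypePanel(animals=animals, markers=markers, genotypes=G)


def planted_core_indices(spec: PanelSpec, panel: GenotypePanel) -> np.ndarray:
    """Marker indices of the planted core (re-derived from the spec geometry)."""
    if spec.shared_haplotype_markers <= 0:
        return np.array([], dtype=int)
    on_causal = (panel.markers["chrom"] == spec.causal_chrom).to_numpy()
    inside = on_causal & panel.markers["bp"].apply(spec.causal_interval.contains).to_numpy()
    candidates = np.flatnonzero(inside)
    mid = len(candidates) // 2
    half = spec.shared_haplotype_markers // 2
    start = max(0, min(mid - half, len(candidates) - spec.shared_haplotype_markers))
    return candidates[start:start + spec.shared_haplotype_markers]


# ---------------------------------------------------------------------------
# Resequencing variant tables
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One sequenced breed subgroup and its planted causal events."""

    label: str
    n_pp: int
    n_carrier: int
    n_horned: int
    causal_variants: Tuple[CandidateVariant, ...] = ()


@dataclass
class ReseqSpec:
    """Design of a synthetic targeted-resequencing variant table.

    Defaults emulate the 16-sire design: two subgroups sequenced at ~40x over
    the 547 kb target, causal events concordant with POLLED class inside their
    own subgroup only, plus class-independent passenger variants.
    """

    seed: int
    groups: Tuple[GroupSpec, ...] = (
        GroupSpec("HF", n_pp=3, n_carrier=1, n_horned=4,
                  causal_variants=catalog.HF_CANDIDATES),
        GroupSpec("nonHF", n_pp=4, n_carrier=0, n_horned=4,
                  causal_variants=(catalog.P_202ID_VARIANT,)),
    )
    target_interval: GenomicInterval = field(
        default_factory=lambda: catalog.TARGET_REGION)
    n_passenger_variants: int = 60
    depth_mean: float = 40.0
    vaf_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.vaf_noise_sd < 0:
            raise ValueError("vaf_noise_sd must be >= 0")
        for g in self.groups:
            for v in g.causal_variants:
                if not self.target_interval.contains(v.position):
                    raise ValueError(f"{v.id} outside the target interval")


def _noisy_vaf(centre: float, sd: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, centre)
    a, b = (0.0 - centre) / sd, (1.0 - centre) / sd
    return stats.truncnorm.rvs(a, b, loc=centre, scale=sd, size=size,
                               random_state=rng)


def _records_for(site: dict, sample_ids: Sequence[str], centres: np.ndarray,
                 depth_mean: float, sd: float, rng: np.random.Generator) -> List[dict]:
    rows = []
    vafs = np.array([_noisy_vaf(c, sd, 1, rng)[0] for c in centres])
    depths = np.maximum(rng.poisson(depth_mean, size=len(sample_ids)), 1)
    for sid, vaf, depth in zip(sample_ids, vafs, depths):
        alt = int(round(vaf * depth))
        rows.append({**site, "sample": sid, "depth": int(depth),
                     "alt_count": alt, "vaf": alt / depth})
    return rows


def generate_variant_tables(spec: ReseqSpec) -> VariantTable:
    """Variant table with group-private causal events and shared passengers.

    Causal events are recorded near VAF 1.0 in their group's PP samples and
    near 0.5 in its carriers, and have no record in horned samples or in other
    groups.  Passenger variants segregate independently of POLLED class in all
    samples (Hardy-Weinberg at a random allele frequency); a sample
    homozygous-reference at a passenger site has no record, matching caller
    semantics.
    """
    rng = np.random.default_rng(spec.seed)
    sample_rows = []
    for g in spec.groups:
        for cls, n in (("PP", g.n_pp), ("Pp", g.n_carrier), ("pp", g.n_horned)):
            for k in range(n):
                sample_rows.append((f"{g.label}-{cls}{k + 1}", g.label, cls))
    samples = pd.DataFrame(sample_rows, columns=["id", "group", "polled_class"])

    rows: List[dict] = []
    causal_pos = set()
    for g in spec.groups:
        own = samples[samples["group"] == g.label]
        pp_ids = own[own["polled_class"] == "PP"]["id"].tolist()
        het_ids = own[own["polled_class"] == "Pp"]["id"].tolist()
        for v in g.causal_variants:
            causal_pos.add(v.position)
            site = {"chrom": v.chrom, "pos": v.position, "id": v.id,
                    "ref": v.ref_allele or "N", "alt": v.alt_allele or "N",
                    "kind": v.kind.value}
            rows += _records_for(site, pp_ids, np.full(len(pp_ids), 1.0),
                                 spec.depth_mean, spec.vaf_noise_sd, rng)
            rows += _records_for(site, het_ids, np.full(len(het_ids), 0.5),
                                 spec.depth_mean, spec.vaf_noise_sd, rng)

    iv = spec.target_interval
    hi = iv.end if iv.convention is Convention.INCLUSIVE else iv.end - 1
    bases = np.array(list("ACGT"))
    pos_pool = rng.choice(np.arange(iv.start, hi + 1), size=4 * spec.n_passenger_variants,
                          replace=False)
    pos_pool = [p for p in pos_pool if p not in causal_pos][:spec.n_passenger_variants]
    for j, pos in enumerate(sorted(pos_pool)):
        ref, alt = rng.choice(bases, size=2, replace=False)
        site = {"chrom": iv.chrom, "pos": int(pos), "id": f"passenger_{j}",
                "ref": str(ref), "alt": str(alt), "kind": "snp"}
        q = rng.uniform(0.05, 0.5)
        gts = rng.binomial(2, q, size=len(samples))
        for sid, gt in zip(samples["id"], gts):
            if gt == 0:
                continue
            centre = 1.0 if gt == 2 else 0.5
            rows += _records_for(site, [sid], np.array([centre]),
                                 spec.depth_mean, spec.vaf_noise_sd, rng)

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = records.sort_values(["chrom", "pos", "sample"]).reset_index(drop=True)
    return VariantTable(records=records, samples=samples)


def sixteen_sire_fixture(n_decoys: int = 20) -> VariantTable:
    """Deterministic 16-sample table reproducing the subgroup filter counts.

    Synthetic stand-in for the study's sequenced-sire call set (the real calls
    are not public): the seven Friesian candidates are concordant within the
    HF subgroup only, the Celtic InDel within the non-HF subgroup only, and
    ``n_decoys`` additional sites each violate exactly one filter rule.
    Filtering the pooled 16 samples yields nothing; the HF partition yields 7
    survivors and the non-HF partition 1.
    """
    sample_rows = (
        [(f"HF-PP{i}", "HF", "PP") for i in (1, 2, 3)]
        + [("HF-Pp4", "HF", "Pp")]
        + [(f"HF-pp{i}", "HF", "pp") for i in (5, 6, 7, 8)]
        + [("nonHF-PP-DAN1", "nonHF", "PP"), ("nonHF-PP-GLW1", "nonHF", "PP"),
           ("nonHF-PP-GLW2", "nonHF", "PP"), ("nonHF-PP-DFV1", "nonHF", "PP")]
        + [("nonHF-pp-FGV1", "nonHF", "pp"), ("nonHF-pp-DFV2", "nonHF", "pp"),
           ("nonHF-pp-DFV3", "nonHF", "pp"), ("nonHF-pp-MWF1", "nonHF", "pp")]
    )
    samples = pd.DataFrame(sample_rows, columns=["id", "group", "polled_class"])
    hf_pp = [s for s, g, c in sample_rows if g == "HF" and c == "PP"]
    hf_het = [s for s, g, c in sample_rows if g == "HF" and c == "Pp"]
    nonhf_pp = [s for s, g, c in sample_rows if g == "nonHF" and c == "PP"]

    def rec(site, sample, vaf, depth=40):
        return {**site, "sample": sample, "depth": depth,
                "alt_count": int(round(vaf * depth)), "vaf": vaf}

    def site_of(v: CandidateVariant) -> dict:
        return {"chrom": v.chrom, "pos": v.position, "id": v.id,
                "ref": v.ref_allele or "N", "alt": v.alt_allele or "N",
                "kind": v.kind.value}

    rows = []
    for v in catalog.HF_CANDIDATES:
        site = site_of(v)
        rows += [rec(site, s, 1.0) for s in hf_pp]
        rows += [rec(site, s, 0.5) for s in hf_het]
    celtic = site_of(catalog.P_202ID_VARIANT)
    rows += [rec(celtic, s, 1.0) for s in nonhf_pp]

    # decoys: each violates exactly one rule, alternating between subgroups
    violations = ["pp_low", "pp_detected", "het_high", "het_low", "pp_missing",
                  "reference_allele", "low_depth"]
    pos0 = 1_550_000
    for d in range(n_decoys):
        kind = violations[d % len(violations)]
        site = {"chrom": "1", "pos": pos0 + 997 * d, "id": f"decoy_{d}",
                "ref": "A", "alt": "C", "kind": "snp"}
        pp, het = (hf_pp, hf_het) if d % 2 == 0 else (nonhf_pp, [])
        pp_vafs = {s: 1.0 for s in pp}
        het_vafs = {s: 0.5 for s in het}
        extra = []
        if kind == "pp_low":
            pp_vafs[pp[0]] = 0.94
        elif kind == "pp_detected":
            extra.append(rec(site, "HF-pp5" if d % 2 == 0 else "nonHF-pp-FGV1", 0.05))
        elif kind == "het_high":
            if het:
                het_vafs[het[0]] = 0.65
            else:
                pp_vafs[pp[0]] = 0.5  # no carrier in the subgroup: fail PP band
        elif kind == "het_low":
            if het:
                het_vafs[het[0]] = 0.35
            else:
                pp_vafs[pp[0]] = 0.2
        elif kind == "pp_missing":
            pp_vafs.pop(pp[-1])
        elif kind == "reference_allele":
            site = {**site, "alt": site["ref"]}
        elif kind == "low_depth":
            rows.append(rec(site, pp[0], 1.0, depth=15))
            pp_vafs.pop(pp[0])
        rows += [rec(site, s, v) for s, v in pp_vafs.items()]
        rows += [rec(site, s, v) for s, v in het_vafs.items()]
        rows += extra

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = records.sort_values(["chrom", "pos", "sample"]).reset_index(drop=True)
    return VariantTable(records=records, samples=samples)


# ---------------------------------------------------------------------------
# Read-start tracks
# ---------------------------------------------------------------------------


def generate_read_tracks(dup: GenomicInterval, target_interval: GenomicInterval,
                         rate_per_bp: float, copy_ratio: float, seed: int
                         ) -> Tuple[ReadStartTrack, ReadStartTrack]:
    """Uniform reference reads and target reads boosted inside the duplication.

    Read counts are Poisson at ``rate_per_bp``; target intensity is multiplied
    by ``copy_ratio`` inside ``dup``.  Returns (reference, target) tracks with
    sorted positions.
    """
    if copy_ratio <= 0:
        raise ValueError("copy_ratio must be positive")
    if not target_interval.overlaps(dup):
        raise ValueError("duplication must lie inside the target interval")
    rng = np.random.default_rng(seed)
    iv = target_interval
    lo = iv.start
    hi = iv.end if iv.convention is Convention.INCLUSIVE else iv.end - 1
    L = hi - lo + 1
    d_lo = dup.start
    d_hi = dup.end if dup.convention is Convention.INCLUSIVE else dup.end - 1
    Ld = d_hi - d_lo + 1

    def uniform(n: int, a: int, b: int) -> np.ndarray:
        return rng.integers(a, b + 1, size=n)

    n_ref = rng.poisson(rate_per_bp * L)
    ref = np.sort(uniform(n_ref, lo, hi))

    n_out = rng.poisson(rate_per_bp * (L - Ld))
    n_in = rng.poisson(rate_per_bp * copy_ratio * Ld)
    out = uniform(int(1.5 * n_out) + 10, lo, hi)
    out = out[(out < d_lo) | (out > d_hi)][:n_out]
    tgt = np.sort(np.concatenate([out, uniform(n_in, d_lo, d_hi)]))

    return (ReadStartTrack("reference", ref, iv),
            ReadStartTrack("target", tgt, iv))


# ---------------------------------------------------------------------------
# Population allele-call table
# ---------------------------------------------------------------------------

WILDTYPE_BREEDS = ("Buša", "Podolian", "Hereford", "Braunvieh", "Pinzgauer")
CELTIC_BREEDS = ("Fleckvieh", "Angus", "Galloway", "Norwegian Red")
FRIESIAN_BREEDS = ("Holstein-Friesian", "Jersey", "Witrug")


def generate_population_table(n_prs_hom: int = 1261, n_pc_het: int = 86,
                              n_pc_hom: int = 192, n_pf_het: int = 50,
                              n_pf_hom: int = 24, n_compound: int = 3,
                              pedigree_depth: int = 1, seed: int = 0
                              ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-call table plus pedigree records under strict dominance.

    Phenotype is polled iff the animal carries >=1 copy of either allele;
    compound heterozygotes carry one Celtic and one Friesian copy and are
    declared PP (progeny tested).  Per-variant genotype columns are consistent
    with the block copy numbers (no recombinants).  Pedigrees link every
    mutant-allele carrier to a per-allele founder through ``pedigree_depth``
    generations.
    """
    for n in (n_prs_hom, n_pc_het, n_pc_hom, n_pf_het, n_pf_hom, n_compound):
        if n < 0:
            raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    classes = ([(0, 0)] * n_prs_hom + [(1, 0)] * n_pc_het + [(2, 0)] * n_pc_hom
               + [(0, 1)] * n_pf_het + [(0, 2)] * n_pf_hom + [(1, 1)] * n_compound)
    rows = []
    for k, (pc, pf) in enumerate(classes):
        if pc and pf:
            breed = rng.choice(FRIESIAN_BREEDS[:2])
        elif pc:
            breed = rng.choice(CELTIC_BREEDS)
        elif pf:
            breed = rng.choice(FRIESIAN_BREEDS)
        else:
            breed = rng.choice(WILDTYPE_BREEDS)
        total = pc + pf
        row = {
            "animal": f"A{k + 1:05d}", "breed": str(breed),
            "pc_copies": pc, "pf_copies": pf,
            "phenotype": "polled" if total >= 1 else "horned",
            "declared_genotype": {0: "pp", 1: "Pp", 2: "PP"}[total],
            "gt_P_202ID": pc,
        }
        for m in catalog.FRIESIAN_BLOCK.members:
            row[f"gt_{m.id}"] = pf
        rows.append(row)
    columns = (["animal", "breed", "pc_copies", "pf_copies", "phenotype",
                "declared_genotype", "gt_P_202ID"]
               + [f"gt_{m.id}" for m in catalog.FRIESIAN_BLOCK.members])
    table = pd.DataFrame(rows, columns=columns)

    ped_rows = []
    founders = {}
    for allele, pheno in (("PC", "polled"), ("PF", "polled")):
        chain = []
        for d in range(max(pedigree_depth, 1)):
            name = f"FOUNDER_{allele}" if d == 0 else f"{allele}_GEN{d}"
            sire = chain[-1] if chain else "0"
            ped_rows.append({"animal": name, "sire": sire, "dam": "0",
                             "phenotype": pheno})
            chain.append(name)
        founders[allele] = chain[-1]
    for _, row in table.iterrows():
        pc, pf = row["pc_copies"], row["pf_copies"]
        sire = founders["PC"] if pc else (founders["PF"] if pf else "0")
        dam = founders["PF"] if (pc and pf) else "0"
        ped_rows.append({"animal": row["animal"], "sire": sire, "dam": dam,
                         "phenotype": row["phenotype"]})
    pedigree = pd.DataFrame(ped_rows, columns=["animal", "sire", "dam", "phenotype"])
    return table, pedigree


def simulate_progeny_records(bull: str, genotype: str, n_offspring: int,
                             seed: int = 0) -> pd.DataFrame:
    """Pedigree rows for a bull's offspring from horned mates.

    Offspring phenotypes follow Mendelian segregation under dominance: a PP
    bull produces only polled offspring, a Pp bull polled with probability 1/2.
    """
    if genotype not in ("PP", "Pp"):
        raise ValueError("genotype must be PP or Pp")
    rng = np.random.default_rng(seed)
    rows = [{"animal": bull, "sire": "0", "dam": "0", "phenotype": "polled"}]
    for k in range(n_offspring):
        dam = f"{bull}_mate{k}"
        rows.append({"animal": dam, "sire": "0", "dam": "0", "phenotype": "horned"})
        if genotype == "PP":
            pheno = "polled"
        else:
            pheno = "polled" if rng.random() < 0.5 else "horned"
        rows.append({"animal": f"{bull}_off{k}", "sire": bull, "dam": dam,
                     "phenotype": pheno})
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "phenotype"])
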