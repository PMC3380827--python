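"""Shared-homozygosity association mapping with a marker-permutation null.

The mapping statistic scores, for each case animal and marker, the run of
consecutive homozygous markers containing that marker, weighting each marker in
the run by how improbable chance homozygosity is there (control-group allele
frequencies).  Per-case run scores are combined across cases as a harmonic
mean, so a single heterozygous case annihilates the statistic: a marker scores
above zero if and only if every case is homozygous.  Genome-wide significance
comes from permuting whole marker columns (genotype vectors of all animals
jointly, with their frequency weights) along the chromosomes and recording the
genome-wide maximum statistic per permutation.

Genotypes are coded 0 (hom ref), 1 (het), 2 (hom alt), -1 (missing).  Missing
genotypes break the run at the query marker (scored 0) but inside a run they
neither break nor extend it and contribute nothing to the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import Convention, GenomicInterval

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class GenotypePanel:
    """Animals x ordered markers with genotype codes and POLLED-class labels.

    ``animals``: DataFrame with columns id, breed, polled_class (PP/Pp/pp/unknown).
    ``markers``: DataFrame with columns id, chrom, bp (bp strictly increasing
    within chromosome, chromosomes in block order).
    ``genotypes``: int8 array (n_animals x n_markers), codes 0/1/2/-1.
    """

    animals: pd.DataFrame
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.animals), len(self.markers)):
            raise ValueError("genotype matrix shape does not match animals x markers")
        for _, sub in self.markers.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError("marker bp must be strictly increasing within chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def class_indices(self, polled_class: str) -> np.ndarray:
        return np.flatnonzero((self.animals["polled_class"] == polled_class).to_numpy())

    @property
    def case_indices(self) -> np.ndarray:
        return self.class_indices("PP")

    @property
    def control_indices(self) -> np.ndarray:
        return self.class_indices("pp")

    def chromosome_starts(self) -> np.ndarray:
        """Index of the first marker of each chromosome block."""
        chrom = self.markers["chrom"].to_numpy()
        return np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]])


@dataclass
class AsshomResult:
    """Per-marker statistic, permutation null and extracted intervals."""

    stats: np.ndarray
    pvalues: np.ndarray
    threshold: float
    n_permutations: int
    alpha: float
    maxima: np.ndarray
    significant_intervals: List[GenomicInterval] = field(default_factory=list)
    peak_index: Optional[int] = None


@dataclass
class CandidateIntervalReport:
    """Homozygous core plus flanking informative markers around the peak."""

    core_interval: Optional[GenomicInterval]
    core_marker_count: int
    flanking_markers: Tuple[Optional[Tuple[str, int]], Optional[Tuple[str, int]]]
    candidate_interval: Optional[GenomicInterval]
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Per-marker weights
# ---------------------------------------------------------------------------

def control_allele_freqs(panel: GenotypePanel) -> np.ndarray:
    """Alt-allele frequency per marker estimated from the control (pp) group."""
    ctrl = panel.genotypes[panel.control_indices]
    valid = ctrl != MISSING
    n = 2 * valid.sum(axis=0)
    alt = np.where(valid, ctrl, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return f


def hom_weights(freqs: np.ndarray) -> np.ndarray:
    """-log10 of chance homozygosity under Hardy-Weinberg, per marker.

    p_hom = f^2 + (1-f)^2 is symmetric in the allele, so the weight does not
    depend on which allele a case carries.  Monomorphic markers (f in {0,1})
    have p_hom = 1 and carry no information; markers with no control data
    are treated the same way.
    """
    f = np.nan_to_num(freqs, nan=0.0)
    p_hom = f ** 2 + (1.0 - f) ** 2
    return -np.log10(p_hom)


# ---------------------------------------------------------------------------
# Run scores (vectorised over animals x markers)
# ---------------------------------------------------------------------------

def _run_score_matrix(G: np.ndarray, w: np.ndarray, chrom_starts: np.ndarray) -> np.ndarray:
    """Per-animal, per-marker homozygous-run scores.

    A sentinel heterozygous column is inserted before each chromosome so runs
    cannot cross chromosome boundaries; the whole genome is then processed in
    one pass.  Score at marker m = sum of weights of homozygous markers in the
    maximal run (bounded by heterozygous markers) containing m, or 0 where the
    animal is not homozygous at m.
    """
    A, M = G.shape
    n_sent = len(chrom_starts)
    Mx = M + n_sent
    # map real column j -> extended position j + (#chrom starts <= j)
    real = np.arange(M) + np.searchsorted(chrom_starts, np.arange(M), side="right")
    Gx = np.full((A, Mx), HET, dtype=np.int8)
    wx = np.zeros(Mx)
    Gx[:, real] = G
    wx[real] = w

    hom = (Gx == HOM_REF) | (Gx == HOM_ALT)
    reset = Gx == HET
    contrib = wx * hom

    P = np.concatenate([np.zeros((A, 1)), np.cumsum(contrib, axis=1)], axis=1)
    idx = np.arange(Mx)
    left = np.maximum.accumulate(np.where(reset, idx, -1), axis=1)
    right = Mx - 1 - np.maximum.accumulate(
        np.where(reset[:, ::-1], idx, -1), axis=1)[:, ::-1]

    rows = np.arange(A)[:, None]
    s = P[rows, right] - P[rows, left + 1]
    s = np.where(hom, s, 0.0)
    return s[:, real]


def harmonic_mean_scores(s: np.ndarray) -> np.ndarray:
    """Harmonic mean across cases (rows); any zero score annihilates."""
    A, M = s.shape
    S = np.zeros(M)
    ok = (s > 0).all(axis=0)
    if ok.any():
        S[ok] = A / np.sum(1.0 / s[:, ok], axis=0)
    return S


def _case_run_scores(panel: GenotypePanel,
                     control_freqs: Optional[np.ndarray] = None) -> np.ndarray:
    if control_freqs is None:
        control_freqs = control_allele_freqs(panel)
    w = hom_weights(control_freqs)
    G = panel.genotypes[panel.case_indices]
    return _run_score_matrix(G, w, panel.chromosome_starts())


def homozygous_run(panel: GenotypePanel, animal: int, marker: int
                   ) -> Optional[Tuple[int, int]]:
    """Maximal homozygous run (global marker index range, inclusive) containing
    ``marker`` for one animal, or None if the animal is not homozygous there.

    Heterozygous markers bound the run; missing genotypes inside it are
    transparent.  The returned range is trimmed to its outermost homozygous
    markers.
    """
    g = panel.genotypes[animal]
    if g[marker] not in (HOM_REF, HOM_ALT):
        return None
    chrom = panel.markers["chrom"].iloc[marker]
    on_chrom = np.flatnonzero((panel.markers["chrom"] == chrom).to_numpy())
    lo, hi = on_chrom[0], on_chrom[-1]
    i = marker
    while i > lo and g[i - 1] != HET:
        i -= 1
    j = marker
    while j < hi and g[j + 1] != HET:
        j += 1
    hom_idx = np.flatnonzero((g[i:j + 1] == HOM_REF) | (g[i:j + 1] == HOM_ALT)) + i
    return int(hom_idx[0]), int(hom_idx[-1])


def case_score(panel: GenotypePanel, animal: int, marker: int,
               control_freqs: Optional[np.ndarray] = None) -> float:
    """Run score of one case animal at one marker."""
    if control_freqs is None:
        control_freqs = control_allele_freqs(panel)
    w = hom_weights(control_freqs)
    s = _run_score_matrix(panel.genotypes[[animal]], w, panel.chromosome_starts())
    return float(s[0, marker])


def asshom_profile(panel: GenotypePanel,
                   control_freqs: Optional[np.ndarray] = None) -> np.ndarray:
    """Mapping statistic S(m) at every marker."""
    if len(panel.case_indices) == 0:
        raise ValueError("panel has no case (PP) animals")
    return harmonic_mean_scores(_case_run_scores(panel, control_freqs))


def asshom_statistic(panel: GenotypePanel, marker: int,
                     control_freqs: Optional[np.ndarray] = None) -> float:
    return float(asshom_profile(panel, control_freqs)[marker])


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def permutation_max_stats(panel: GenotypePanel, n_perm: int, seed: int) -> np.ndarray:
    """Genome-wide maximum statistic under ``n_perm`` marker permutations.

    Each permutation relocates whole marker columns (genotypes of all animals,
    with the marker's frequency weight) along the genome; chromosome boundaries
    stay fixed.
    """
    rng = np.random.default_rng(seed)
    w = hom_weights(control_allele_freqs(panel))
    G = panel.genotypes[panel.case_indices]
    starts = panel.chromosome_starts()
    M = panel.n_markers
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(M)
        s = _run_score_matrix(G[:, perm], w[perm], starts)
        maxima[b] = harmonic_mean_scores(s).max() if M else 0.0
    return maxima


def permutation_threshold(panel: GenotypePanel, n_perm: int, alpha: float,
                          seed: int) -> Tuple[float, np.ndarray]:
    """Empirical genome-wide upper-alpha threshold from permutation maxima.

    With k = alpha * n_perm, the threshold is the k-th largest maximum (e.g.
    alpha 0.0002 with 50,000 permutations -> the 10th largest).
    """
    if n_perm * alpha < 1:
        raise ValueError("n_perm * alpha must be >= 1")
    if alpha < 1.0 / (n_perm + 1):
        raise ValueError("alpha below permutation resolution 1/(n_perm+1)")
    maxima = permutation_max_stats(panel, n_perm, seed)
    k = int(np.floor(alpha * n_perm))
    threshold = float(np.sort(maxima)[::-1][k - 1])
    return threshold, maxima


def map_locus(panel: GenotypePanel, n_perm: int = 500, alpha: float = 0.01,
              seed: int = 0) -> AsshomResult:
    """Full mapping scan: statistic, permutation threshold, p-values, intervals.

    Per-marker p-values are genome-wide adjusted: (r+1)/(n_perm+1) where r is
    the number of permutation maxima >= S(m).
    """
    stats = asshom_profile(panel)
    threshold, maxima = permutation_threshold(panel, n_perm, alpha, seed)
    sorted_max = np.sort(maxima)
    r = n_perm - np.searchsorted(sorted_max, stats, side="left")
    pvalues = (r + 1) / (n_perm + 1)

    sig = stats > threshold
    intervals: List[GenomicInterval] = []
    if sig.any():
        bp = panel.markers["bp"].to_numpy()
        chrom = panel.markers["chrom"].to_numpy()
        idx = np.flatnonzero(sig)
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1 or chrom[i] != chrom[prev]:
                intervals.append(GenomicInterval(str(chrom[run_start]),
                                                 int(bp[run_start]), int(bp[prev]),
                                                 Convention.INCLUSIVE))
                run_start = i
            prev = i
        intervals.append(GenomicInterval(str(chrom[run_start]), int(bp[run_start]),
                                         int(bp[prev]), Convention.INCLUSIVE))
    peak = int(np.argmax(stats)) if sig.any() else None  # leftmost of max plateau
    return AsshomResult(stats=stats, pvalues=pvalues, threshold=threshold,
                        n_permutations=n_perm, alpha=alpha, maxima=maxima,
                        significant_intervals=intervals, peak_index=peak)


# ---------------------------------------------------------------------------
# Candidate-interval extraction
# ---------------------------------------------------------------------------

def _case_informative(panel: GenotypePanel) -> np.ndarray:
    """Markers variable within the case group (>=2 distinct codes or any het)."""
    G = panel.genotypes[panel.case_indices]
    any_het = (G == HET).any(axis=0)
    valid = G != MISSING
    n_valid = valid.sum(axis=0)
    # uniform-homozygous = every non-missing case shares one homozygous code
    uniform_hom = np.zeros(panel.n_markers, dtype=bool)
    for code in (HOM_REF, HOM_ALT):
        uniform_hom |= ((G == code) | ~valid).all(axis=0) & (n_valid > 0)
    return any_het | ~uniform_hom


def extract_candidate_interval(result: AsshomResult,
                               panel: GenotypePanel) -> CandidateIntervalReport:
    """Homozygous core around the peak plus nearest informative flanking markers.

    The core is the maximal run of markers at which every case is homozygous
    (either allele), centred on the peak of the statistic; the candidate
    interval runs between the nearest markers on each side that are variable
    within the case group.  With no significant marker an empty report is
    returned with a warning.
    """
    if result.peak_index is None:
        warnings.warn("no marker exceeds the genome-wide threshold")
        return CandidateIntervalReport(None, 0, (None, None), None)

    peak = result.peak_index
    chrom = panel.markers["chrom"].iloc[peak]
    on_chrom = np.flatnonzero((panel.markers["chrom"] == chrom).to_numpy())
    lo, hi = int(on_chrom[0]), int(on_chrom[-1])

    G = panel.genotypes[panel.case_indices]
    all_hom = ((G == HOM_REF) | (G == HOM_ALT)).all(axis=0)
    if not all_hom[peak]:
        warnings.warn("peak marker is not homozygous in all cases")
        return CandidateIntervalReport(None, 0, (None, None), None)
    i = peak
    while i > lo and all_hom[i - 1]:
        i -= 1
    j = peak
    while j < hi and all_hom[j + 1]:
        j += 1

    bp = panel.markers["bp"].to_numpy()
    ids = panel.markers["id"].to_numpy()
    core = GenomicInterval(str(chrom), int(bp[i]), int(bp[j]), Convention.INCLUSIVE)

    informative = _case_informative(panel)
    left = next((k for k in range(i - 1, lo - 1, -1) if informative[k]), None)
    right = next((k for k in range(j + 1, hi + 1) if informative[k]), None)

    degenerate = left is None or right is None
    lo_bp = bp[left] if left is not None else bp[lo]
    hi_bp = bp[right] if right is not None else bp[hi]
    candidate = GenomicInterval(str(chrom), int(lo_bp), int(hi_bp), Convention.INCLUSIVE)
    flank = (
        (str(ids[left]), int(bp[left])) if left is not None else None,
        (str(ids[right]), int(bp[right])) if right is not None else None,
    )
    return CandidateIntervalReport(core_interval=core, core_marker_count=j - i + 1,
                                   flanking_markers=flank,
                                   candidate_interval=candidate,
                                   degenerate=degenerate)
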