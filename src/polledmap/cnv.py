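"""Read-depth CNV detection with dynamic reference-count bins and segmentation.

Bins are sized dynamically on the reference group: walking its sorted read
starts, every n-th read (default 400) closes the current bin at that read's
start position.  Per bin, the log2 ratio of library-size-normalised target vs
reference read counts is computed; the ratio track is segmented with circular
binary segmentation (recursive maximal-t arc search with permutation
significance) and segments with a high positive mean are emitted as duplication
candidates.  A duplicated segment present on one of two haplotypes in carriers
raises the target/reference coverage ratio towards 2 (log2 ratio towards 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import CandidateVariant, Convention, GenomicInterval, VariantKind


@dataclass
class ReadStartTrack:
    """Sorted read start positions of one group over a target interval."""

    group: str
    positions: np.ndarray
    interval: GenomicInterval

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("read start positions must be sorted ascending")
        if len(self.positions) and (
                self.positions[0] < self.interval.start
                or not self.interval.contains(int(self.positions[-1]))):
            raise ValueError("read starts must lie within the target interval")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class Segment:
    start_bin: int          # inclusive bin index
    end_bin: int            # inclusive bin index
    mean: float
    start_bp: int
    end_bp: int
    n_bins: int


def dynamic_bins(reference: ReadStartTrack, n_reads: int = 400) -> pd.DataFrame:
    """Bin boundaries from the reference track: every n-th read closes a bin.

    Bins are [previous boundary + 1, boundary] inclusive, the first starting at
    the target interval start.  A trailing bin holding fewer than ``n_reads``
    reads is emitted flagged incomplete and extends to the interval end.
    """
    pos = reference.positions
    if len(pos) == 0:
        raise ValueError("reference track is empty")
    iv = reference.interval
    iv_end = iv.end if iv.convention is Convention.INCLUSIVE else iv.end - 1

    starts, ends, counts, complete = [], [], [], []
    prev_end = iv.start - 1
    for k in range(n_reads - 1, len(pos), n_reads):
        boundary = int(pos[k])
        starts.append(prev_end + 1)
        ends.append(boundary)
        counts.append(n_reads)
        complete.append(True)
        prev_end = boundary
    n_left = len(pos) % n_reads if len(pos) >= n_reads else len(pos)
    if n_left:
        starts.append(prev_end + 1)
        ends.append(iv_end)
        counts.append(n_left)
        complete.append(False)
    return pd.DataFrame({"start": starts, "end": ends,
                         "ref_count": counts, "complete": complete})


def count_in_bins(track: ReadStartTrack, bins: pd.DataFrame) -> np.ndarray:
    """Reads assigned to bins by start position."""
    edges = np.r_[bins["start"].to_numpy() - 1, bins["end"].iloc[-1]]
    counts, _ = np.histogram(track.positions, bins=edges + 0.5)
    return counts.astype(np.int64)


def log2_ratios(ref_counts: np.ndarray, target_counts: np.ndarray,
                ref_total: Optional[int] = None,
                target_total: Optional[int] = None) -> np.ndarray:
    """Library-size-normalised per-bin log2(target/reference) ratios.

    Bins with a zero count on either side get a 0.5 pseudocount added to both
    counts (keeps ratios finite without masking deletions).
    """
    r = np.asarray(ref_counts, dtype=float)
    t = np.asarray(target_counts, dtype=float)
    ref_total = float(ref_total if ref_total is not None else r.sum())
    target_total = float(target_total if target_total is not None else t.sum())
    zero = (r == 0) | (t == 0)
    r = np.where(zero, r + 0.5, r)
    t = np.where(zero, t + 0.5, t)
    return np.log2((t / target_total) / (r / ref_total))


def log2_ratio_track(bins: pd.DataFrame, target: ReadStartTrack,
                     center: Optional[str] = "median") -> pd.DataFrame:
    """Attach target counts and log2 ratios to a dynamic-bin frame.

    With ``center="median"`` (default) the track is re-centred by its median
    log2 ratio so the copy-neutral baseline sits at 0 even when a large event
    inflates one group's library size; ``center=None`` keeps the raw
    library-size-normalised ratios.
    """
    out = bins.copy()
    out["target_count"] = count_in_bins(target, bins)
    ratios = log2_ratios(out["ref_count"].to_numpy(),
                         out["target_count"].to_numpy())
    if center == "median":
        ratios = ratios - np.median(ratios)
    elif center is not None:
        raise ValueError("center must be 'median' or None")
    out["log2_ratio"] = ratios
    return out


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def _arc_t_max(x: np.ndarray, min_size: int):
    """Maximal |t| over all arcs [i, j) whose removal leaves valid edge pieces.

    Edge pieces may be empty or >= min_size; the arc itself must be >= min_size
    and leave at least min_size points outside.  Returns (tmax, i, j) or None.
    """
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    if n < 2 * min_size or sd == 0:
        return None
    total = x.sum()
    csum = np.r_[0.0, np.cumsum(x)]
    best = (-np.inf, 0, 0)
    for l in range(min_size, n - min_size + 1):
        i = np.arange(0, n - l + 1)
        valid = ((i == 0) | (i >= min_size)) & ((i + l == n) | (n - i - l >= min_size))
        if not valid.any():
            continue
        arc = csum[i + l] - csum[i]
        t = np.abs((arc / l - (total - arc) / (n - l))
                   / (sd * np.sqrt(1.0 / l + 1.0 / (n - l))))
        t = np.where(valid, t, -np.inf)
        k = int(np.argmax(t))
        if t[k] > best[0]:
            best = (float(t[k]), int(i[k]), int(i[k] + l))
    return best if np.isfinite(best[0]) else None


def _perm_t_max(x: np.ndarray, min_size: int, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the maximal arc |t| under value permutations."""
    n = len(x)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    X = x[order]
    sd = X.std(axis=1, ddof=1)
    sd[sd == 0] = np.inf
    total = X.sum(axis=1)
    csum = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(X, axis=1)], axis=1)
    best = np.full(n_perm, -np.inf)
    for l in range(min_size, n - min_size + 1):
        i = np.arange(0, n - l + 1)
        valid = ((i == 0) | (i >= min_size)) & ((i + l == n) | (n - i - l >= min_size))
        if not valid.any():
            continue
        arc = csum[:, i + l] - csum[:, i]
        t = np.abs((arc / l - (total[:, None] - arc) / (n - l))
                   / (sd[:, None] * np.sqrt(1.0 / l + 1.0 / (n - l))))
        t[:, ~valid] = -np.inf
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _segment_recursive(x: np.ndarray, offset: int, min_size: int, alpha: float,
                       n_perm: int, rng: np.random.Generator,
                       breakpoints: List[int]) -> None:
    found = _arc_t_max(x, min_size)
    if found is None:
        return
    tmax, i, j = found
    null = _perm_t_max(x, min_size, n_perm, rng)
    p = (np.count_nonzero(null >= tmax) + 1) / (n_perm + 1)
    if p > alpha:
        return
    cuts = [c for c in (i, j) if 0 < c < len(x)]
    for c in cuts:
        breakpoints.append(offset + c)
    pieces = np.split(np.arange(len(x)), cuts)
    for piece in pieces:
        if len(piece) >= 2 * min_size:
            _segment_recursive(x[piece], offset + int(piece[0]), min_size,
                               alpha, n_perm, rng, breakpoints)


def segment_ratios(track: pd.DataFrame, alpha: float = 0.01, min_size: int = 3,
                   n_perm: int = 1000, seed: int = 0) -> List[Segment]:
    """Circular binary segmentation of a log2 ratio track.

    Recursive maximal-t changepoint search; each candidate split is kept only
    if its statistic is extreme relative to ``n_perm`` within-segment value
    permutations at level ``alpha``.  Tracks with fewer than ``min_size`` bins
    (or no significant split) come back as one segment.
    """
    x = track["log2_ratio"].to_numpy(dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    breakpoints: List[int] = []
    if n >= 3:
        _segment_recursive(x, 0, min_size, alpha, n_perm, rng, breakpoints)
    bounds = [0] + sorted(set(breakpoints)) + [n]
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segments.append(Segment(start_bin=a, end_bin=b - 1,
                                mean=float(x[a:b].mean()),
                                start_bp=int(starts[a]), end_bp=int(ends[b - 1]),
                                n_bins=b - a))
    return segments


def call_duplication(segments: Sequence[Segment], chrom: str,
                     min_log2: float = 0.4,
                     min_span_bp: int = 10_000) -> List[CandidateVariant]:
    """Segments with mean >= min_log2 and span >= min_span_bp, as duplications."""
    calls = []
    for k, seg in enumerate(segments):
        span = seg.end_bp - seg.start_bp + 1
        if seg.mean >= min_log2 and span >= min_span_bp:
            iv = GenomicInterval(chrom, seg.start_bp, seg.end_bp, Convention.INCLUSIVE)
            calls.append(CandidateVariant(id=f"dup_{chrom}_{seg.start_bp}",
                                          kind=VariantKind.LARGE_DUP, interval=iv))
    return calls
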