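"""Genomic coordinate conventions, interval arithmetic and shared domain objects.

Every printed coordinate in the locus catalogue is carried together with an
explicit coordinate convention (1-based inclusive or half-open).  Published
small-event lengths at this locus only come out right under the inclusive
convention while the large duplication's printed length is an end-minus-start
value, so the convention is a per-interval attribute and is never defaulted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class Convention(str, Enum):
    """Coordinate convention of a genomic interval."""

    INCLUSIVE = "inclusive"   # 1-based, both ends included: length = end - start + 1
    HALF_OPEN = "half_open"   # 1-based start, end excluded:  length = end - start


class VariantKind(str, Enum):
    SNP = "snp"
    SMALL_INDEL = "small_indel"
    LARGE_DUP = "large_dup"


@dataclass(frozen=True)
class GenomicInterval:
    """A closed or half-open interval on a chromosome, 1-based coordinates."""

    chrom: str
    start: int
    end: int
    convention: Convention

    def __post_init__(self) -> None:
        object.__setattr__(self, "convention", Convention(self.convention))
        if self.start < 1 or self.end < 1:
            raise ValueError("positions must be positive (1-based) integers")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return interval_length(self)

    def contains(self, pos: int) -> bool:
        if self.convention is Convention.INCLUSIVE:
            return self.start <= pos <= self.end
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        if self.chrom != other.chrom:
            return False
        # compare on the inclusive footprint of each interval
        a_end = self.end if self.convention is Convention.INCLUSIVE else self.end - 1
        b_end = other.end if other.convention is Convention.INCLUSIVE else other.end - 1
        return self.start <= b_end and other.start <= a_end


def interval_length(iv: GenomicInterval) -> int:
    """Length of an interval in bp under its own convention."""
    if iv.convention is Convention.INCLUSIVE:
        return iv.end - iv.start + 1
    return iv.end - iv.start


@dataclass(frozen=True)
class ComplexInDel:
    """A replacement event: a deleted segment replaced by inserted sequence.

    The inserted material is either a genomic copy (``inserted`` interval, e.g.
    a duplicated segment) or a novel sequence (``inserted_seq``); exactly one of
    the two must be given.  Net size change = inserted length − deleted length.
    """

    label: str
    deleted: GenomicInterval
    inserted: Optional[GenomicInterval] = None
    inserted_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.inserted is None) == (self.inserted_seq is None):
            raise ValueError("give exactly one of inserted interval / inserted_seq")

    @property
    def inserted_length(self) -> int:
        if self.inserted is not None:
            return interval_length(self.inserted)
        return len(self.inserted_seq or "")


def net_indel_change(ev: ComplexInDel) -> int:
    """Signed net size change of a replacement event in bp."""
    return ev.inserted_length - interval_length(ev.deleted)


@dataclass(frozen=True)
class CandidateVariant:
    """A candidate causal event: SNV, small InDel or large duplication."""

    id: str
    kind: VariantKind
    interval: GenomicInterval
    ref_allele: str = ""
    alt_allele: str = ""
    block: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", VariantKind(self.kind))
        if self.kind is VariantKind.SNP:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError(f"{self.id}: SNP must have single-base ref and alt")
        if self.kind is VariantKind.LARGE_DUP and interval_length(self.interval) < 1000:
            raise ValueError(f"{self.id}: large duplication must span >= 1 kb")

    @property
    def position(self) -> int:
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @classmethod
    def snp(cls, id: str, chrom: str, pos: int, ref: str, alt: str,
            block: Optional[str] = None) -> "CandidateVariant":
        iv = GenomicInterval(chrom, pos, pos, Convention.INCLUSIVE)
        return cls(id, VariantKind.SNP, iv, ref, alt, block)

    @classmethod
    def small_indel(cls, id: str, chrom: str, start: int, end: int, ref: str,
                    alt: str, block: Optional[str] = None) -> "CandidateVariant":
        iv = GenomicInterval(chrom, start, end, Convention.INCLUSIVE)
        return cls(id, VariantKind.SMALL_INDEL, iv, ref, alt, block)

    @classmethod
    def large_dup(cls, id: str, interval: GenomicInterval,
                  block: Optional[str] = None) -> "CandidateVariant":
        return cls(id, VariantKind.LARGE_DUP, interval, "", "", block)


@dataclass(frozen=True)
class HaplotypeBlock:
    """An ordered set of candidate variants inherited as one haplotype."""

    label: str
    members: Sequence[CandidateVariant] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        pos = [m.position for m in members]
        if pos != sorted(pos):
            raise ValueError("block members must be sorted by position")
        chroms = {m.chrom for m in members}
        if len(chroms) > 1:
            raise ValueError("block members must share one chromosome")

    @property
    def span(self) -> GenomicInterval:
        if len(self.members) < 2:
            raise ValueError("span undefined for blocks with < 2 members")
        first, last = self.members[0], self.members[-1]
        return GenomicInterval(first.chrom, first.position, last.position,
                               Convention.INCLUSIVE)


def block_span_kb(block: HaplotypeBlock) -> int:
    """Block span (first to last member start) in kb, rounded half-up."""
    span_bp = block.span.end - block.span.start
    return int(math.floor(span_bp / 1000.0 + 0.5))
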