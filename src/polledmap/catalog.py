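"""Published coordinates of the bovine POLLED locus (BTA1, UMD3.1 build).

This module is the single place where the known candidate mutations of the two
POLLED alleles live: the Celtic allele P_C (a complex 202 bp insertion-deletion,
P_202ID) and the Friesian haplotype P_F (a ~260 kb block of a 5 bp InDel, three
SNVs and an 80 kb duplication).  Small replacement events are inclusive
intervals; the 80 kb duplication's published length is an end-minus-start value
and is therefore encoded half-open.
"""

from __future__ import annotations

from .intervals import (
    CandidateVariant,
    ComplexInDel,
    Convention,
    GenomicInterval,
    HaplotypeBlock,
)

CHROM = "1"

#: 547 kb target interval chosen for targeted resequencing.
TARGET_REGION = GenomicInterval(CHROM, 1_543_412, 2_089_648, Convention.HALF_OPEN)

#: Region of near-complete absence of sequence variability among all 16 sires
#: (1.697–1.822 Mb, 125 kb).
LOW_DIVERSITY_REGION = GenomicInterval(CHROM, 1_697_000, 1_822_000, Convention.HALF_OPEN)

#: Homozygous core from chip mapping: nine markers homozygous in all cases.
MAPPING_CORE = GenomicInterval(CHROM, 1_760_113, 1_983_902, Convention.INCLUSIVE)
MAPPING_CORE_MARKERS = 9
#: Shared nine-marker chip haplotype carried by the cases.
SHARED_CHIP_HAPLOTYPE = "AGACAAGGA"

#: The two informative chip SNPs flanking the core; their positions bound the
#: candidate interval (~381 kb).
FLANKING_MARKERS = (("ARS-BFGL-NGS-39992", 1_668_494), ("ARS-BFGL-NGS-29653", 2_049_400))

# ---------------------------------------------------------------------------
# Celtic allele
# ---------------------------------------------------------------------------

#: P_202ID: 212 bp (1,705,834–1,706,045) duplicated, replacing 10 bp
#: (1,706,051–1,706,060); net +202 bp.
P_202ID = ComplexInDel(
    label="P_202ID",
    inserted=GenomicInterval(CHROM, 1_705_834, 1_706_045, Convention.INCLUSIVE),
    deleted=GenomicInterval(CHROM, 1_706_051, 1_706_060, Convention.INCLUSIVE),
)

#: The same event as a site record, anchored at the replaced segment.
P_202ID_VARIANT = CandidateVariant.small_indel(
    "P_202ID", CHROM, 1_706_051, 1_706_060, ref="N" * 10, alt="<DUP212>", block="P_C"
)

# ---------------------------------------------------------------------------
# Friesian haplotype
# ---------------------------------------------------------------------------

#: P_5ID: 7 bp (cgcatca; 1,649,163–1,649,169) replaced by 12 bp; net +5 bp.
P_5ID = ComplexInDel(
    label="P_5ID",
    deleted=GenomicInterval(CHROM, 1_649_163, 1_649_169, Convention.INCLUSIVE),
    inserted_seq="ttctcagaatag",
)

P_5ID_VARIANT = CandidateVariant.small_indel(
    "P_5ID", CHROM, 1_649_163, 1_649_169, ref="CGCATCA", alt="TTCTCAGAATAG", block="P_F"
)

#: 80,128 bp duplication (1,909,352–1,989,480).
P_80KBID_INTERVAL = GenomicInterval(CHROM, 1_909_352, 1_989_480, Convention.HALF_OPEN)
P_80KBID_VARIANT = CandidateVariant.large_dup("P_80kbID", P_80KBID_INTERVAL, block="P_F")

#: Junction variants nested at the start of the duplicated copy; they allow the
#: duplication to be typed (and called) as ordinary site records.
P_T1909354A = CandidateVariant.snp("P_T1909354A", CHROM, 1_909_354, "T", "A", block="P_F")
P_1909396D2 = CandidateVariant.small_indel(
    "P_1909396D2", CHROM, 1_909_396, 1_909_397, ref="TG", alt="", block="P_F"
)

#: The five point mutations detected in the Holstein-Friesian comparison.
P_G1654405A = CandidateVariant.snp("P_G1654405A", CHROM, 1_654_405, "G", "A", block="P_F")
P_C1655463T = CandidateVariant.snp("P_C1655463T", CHROM, 1_655_463, "C", "T", block="P_F")
P_T1671849G = CandidateVariant.snp("P_T1671849G", CHROM, 1_671_849, "T", "G")
P_T1680646C = CandidateVariant.snp("P_T1680646C", CHROM, 1_680_646, "T", "C")
P_C1768587A = CandidateVariant.snp("P_C1768587A", CHROM, 1_768_587, "C", "A", block="P_F")

#: The seven candidates surviving the concordance filter in the HF subgroup.
#: The 80 kb duplication is represented by its typable junction SNV.
HF_CANDIDATES = (
    P_5ID_VARIANT,
    P_G1654405A,
    P_C1655463T,
    P_T1671849G,
    P_T1680646C,
    P_C1768587A,
    P_T1909354A,
)

#: P_F haplotype block as typed in the population screen (five members; the two
#: SNVs excluded after sporadic occurrence on wild-type background are absent).
FRIESIAN_BLOCK = HaplotypeBlock(
    "P_F",
    members=(P_5ID_VARIANT, P_G1654405A, P_C1655463T, P_C1768587A, P_80KBID_VARIANT),
)

#: The six candidate variants typed in the population screen.
TYPED_CANDIDATES = ("P_202ID",) + tuple(m.id for m in FRIESIAN_BLOCK.members)
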