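# Methods

## Coordinate conventions

Published event lengths at this locus mix two conventions: every small
replacement event (212 bp duplicated segment, 10 bp and 7 bp replaced
segments) is consistent with 1-based inclusive coordinates
(length = end − start + 1), while the large duplication's printed length
(80,128 bp from 1,909,352–1,989,480) equals end − start. Rather than silently
"correcting" either, `GenomicInterval` carries its convention explicitly and
the locus catalogue encodes the duplication half-open. Whether the published
duplication length is an off-by-one cannot be decided from the printed
coordinates alone; supporting both conventions reproduces every printed length
exactly. kb-scale spans round half-up (380,906 bp → 381 kb; 260,189 bp →
260 kb).

## Mapping statistic

The shared-homozygosity statistic scores, for each case animal and marker, the
maximal run of consecutive homozygous markers containing that marker:
s_i(m) = Σ_k −log10 p_hom(k) over the run, with p_hom(k) = f_k² + (1−f_k)²
the Hardy-Weinberg probability of chance homozygosity at the control-group
allele frequency f_k (p_hom is symmetric in the allele, so the score does not
depend on which allele the case carries). Control frequencies are used because
cases are enriched for the shared haplotype and would deflate the weights.
Scores are combined across the N cases as a harmonic mean
S(m) = N / Σ_i 1/s_i(m), so one heterozygous case annihilates the statistic:
S(m) > 0 iff every case is homozygous at m (given informative weights). Long
runs of improbable homozygosity shared by all cases score high.

Missing genotypes break the run at the query marker (scored 0) but are
transparent inside a run: they neither terminate it nor contribute weight.
This is conservative and moot on complete (imputed or synthetic) data.

**Permutation null.** Whole marker columns — the genotype vector of all
animals jointly, with the marker's frequency weight — are relocated along the
genome; chromosome boundaries stay fixed. Each permutation records the
genome-wide maximum of S, and the significance threshold is the empirical
upper-α quantile of the maxima (the k-th largest with k = α·n_perm), which
controls the family-wise error rate via the max statistic. Per-marker p-values
are reported as (r+1)/(n_perm+1) with r the number of maxima ≥ S(m); α below
the resolution 1/(n_perm+1) is rejected. Ties at the peak break to the
leftmost marker of the maximal plateau.

**Interval extraction.** The homozygous core is the maximal run of markers
around the peak at which every case is homozygous (either allele — a case
carrying an alternative shared haplotype still counts). The candidate interval
runs between the nearest marker on each side that is variable within the case
group (any heterozygote or ≥2 distinct genotypes). A core reaching a
chromosome end without an informative flanker is flagged degenerate.

## Synthetic panel

`PanelSpec` defaults: 5 chromosomes × 100 markers at 40 kb spacing (SNP-chip
density), 20 cases, 20 controls, 3 breeds, a 9-marker shared homozygous core
planted inside a 1.6–2.1 Mb causal interval on chromosome 1. Ancestral minor
allele frequencies are uniform on [0.05, 0.5]; breeds differentiate by a
Balding-Nichols Beta model with F_ST 0.1. Cases are otherwise unrelated given
breed frequencies — the generator does not model LD decay, recombination maps
or within-breed pedigree structure, so passing tests demonstrate statistic and
threshold behaviour, not robustness to cryptic relatedness in real panels.
Because the study design guaranteed informative chip markers bounding the
core, `ensure_informative_flanks` (default on) makes the two markers adjacent
to the planted core variable in the case group if a random draw left one
uniform (a few percent of seeds); without it the extracted interval would
occasionally extend one marker further.

The published genome-wide threshold of the original 50K-chip scan (3.315) is a
property of that unreleased panel; thresholds here are properties of the
synthetic panels.

## Variant tables and the concordance filter

Causal events are drawn with VAF from a truncated normal around 1.0 (PP) or
0.5 (Pp) on [0, 1]; depths are Poisson with mean 40 (the study's coverage);
`alt_count = round(vaf × depth)` and the stored VAF is `alt_count/depth`.
The noise default is sd 0.01: with the 95–100% acceptance band, a truncated
normal around 1.0 has tail mass below 0.95 of ~2(1−Φ(0.05/sd)); at sd 0.02
that is ~1.2% per PP sample, enough to lose one of seven causals across four
PP samples in a third of replicates, while at sd 0.01 the band is five
standard deviations wide and planted causals survive essentially always.
Passenger variants segregate Hardy-Weinberg at a random frequency,
independent of POLLED class; homozygous-reference samples have no record,
matching caller semantics (detection floor VAF 0.01, minimum depth 20).

Filter semantics: "undetected in pp" means no record at any VAF ≥ the caller
floor — any control record disqualifies the site. Sites covered below depth 20
in any required PP/Pp sample are *inconclusive* and dropped rather than
failed: a calling threshold is not evidence of absence. The large duplication
is not expected to pass the point-variant filter; it is represented by its
typable junction SNV and otherwise handled by the CNV stage.

`sixteen_sire_fixture()` is a deterministic synthetic stand-in for the
sequenced-sire call set (the real calls are not public): 8 + 8 samples, the
seven Friesian candidates concordant only within the HF subgroup, the Celtic
InDel only within the non-HF subgroup, and 20 decoys each violating exactly
one rule. Heterogeneity is declared when the pooled filter yields nothing but
≥2 subgroups yield disjoint survivor sets; cross-subgroup exclusivity
additionally checks each subgroup's survivors are undetected in the other
subgroups' PP samples (replacing the study's genome-browser inspection).

## CNV detection

Bins are sized on the reference group: every 400th read start closes a bin, a
trailing partial bin is flagged incomplete. Ratios are
log2((target_count/target_total)/(ref_count/ref_total)); bins with a zero
count get a 0.5 pseudocount on both sides, keeping ratios finite without
masking deletions. Because a large event itself distorts one group's library
size (an 80 kb ratio-2 duplication in a 547 kb target inflates the target
library ~15%, shifting all raw ratios by ~−0.2), the track is re-centred by
its median log2 ratio by default — the standard move in read-depth CNV
analysis; `center=None` restores raw ratios.

Segmentation is circular binary segmentation: recursively find the arc
maximising the |t| statistic between arc and complement (pooled within-segment
variance), accept the split if the statistic is extreme against 1000
within-segment value permutations at α 0.01, minimum segment 3 bins. These
parameters are conventional defaults; the method is named in the source
material but not parameterised there. Segments with mean log2 ≥ 0.4 spanning
≥ the configured minimum are emitted as duplication candidates. Which group is
the log2 reference is explicit (`reference` = the horned group throughout).

At the default simulation settings (0.15–0.2 reads/bp, ~400 reads per
reference bin, bin width ~2–3 kb) the planted duplication is recovered with
segment mean within ±0.1 of 1 and boundaries within about one bin.

## Population analysis

Perfect association holds iff every carrier of ≥1 copy of either allele is
polled, every polled animal carries ≥1 copy, and every horned animal carries
none; horned animals with untyped candidate genotypes are excluded rather than
imputed. Compound heterozygotes are animals with exactly one copy of each
allele; under dominance all their offspring from horned mates are predicted
polled. The recombination check flags animals whose per-variant copy numbers
differ across the P_F block members. Progeny declaration uses n_required = 12
consecutive polled offspring from horned mates (the stated organisational
range is 12–15; 12 is the default and configurable), with misclassification
probability 0.5^n — the chance a true carrier shows such a record.

The genotype cross-tabulation reproduces 78.03% wild-type homozygotes on the
default population table. The published percentage together with 1,261
wild-type homozygotes implies ~1,616 genotyped animals, a total that matches
no single published group count; the generator's default Friesian-allele
counts (50 het, 24 hom, plus 3 compound and the published 86/192 Celtic
counts) are an artifact choice made once so that the implied total and the
percentage are reproduced. Breed labels are plausible assignments, not data.

## Conservation ranking

Categories, in order: large events are always retained as most plausible
(element-level conservation does not capture what an 80 kb duplication may
do); a variant whose window is conserved among bovids (mean ≥ τ_hi = 0.8) but
not among unhorned mammals (mean ≤ τ_lo = 0.3) is most plausible; a variant
allele equal to another bovid's base at the position is least likely;
repeat-masked positions are unlikely and unrankable (no score can be
computed); anything else is intermediate. The numeric thresholds and the 25 bp
window are artifact decisions (the source ranking is qualitative; the window
covers the 24-nt bovid-identical block around the top SNV) and are echoed in
the output so rankings are auditable. The profiles shipped for the demo are
synthetic encodings of the published qualitative descriptions; real phastCons
tracks are inputs the ranker consumes, never computes.

## Orchestration and problem sizes

`RunConfig`/`run_pipeline` derive per-stage seeds from one root seed via
`numpy` seed sequences, write per-stage text outputs (PED/MAP, TSV, BED,
bedGraph, JSON) and are byte-deterministic given config. Default problem
sizes — 500-marker panels with 500 permutations, ~70-site variant tables over
16 samples, ~100–270 read-depth bins, a 1,616-animal population table — were
chosen so a full run takes seconds while every statistical mechanism
(permutation nulls, CBS significance, band filtering) is genuinely exercised;
the test suite's calibration checks (200 null panels, 100 recovery replicates,
50 CNV seeds) complete in about a minute on one CPU.

## Known limitations

No LD, recombination or pedigree structure in the panel generator; no
base-pair breakpoint refinement for CNV calls (junctions are typed as ordinary
variants); the filter consumes caller output and does not model alignment or
duplicate-marking artefacts; conservation inputs are precomputed scores, not
alignments. Published whole-dataset tallies that depend on the unreleased real
data (total variant counts per comparison, nucleotide diversities, the 3.315
threshold) are out of scope; the pipeline reproduces the published
coordinate arithmetic, filter counts, event recovery and population summaries
on its synthetic designs.
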