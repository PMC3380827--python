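# polledmap

Hornlessness (polledness) in cattle is a dominant trait of high welfare and
economic value: breeding naturally hornless animals replaces routine dehorning.
The trait maps to the proximal end of bovine chromosome 1 (the *POLLED* locus)
and is genetically heterogeneous — two independent mutant alleles segregate in
European breeds: a complex 202 bp insertion-deletion of "Celtic" origin
(P<sub>C</sub>, allele P_202ID) and a ~260 kb "Friesian" haplotype
(P<sub>F</sub>) of five candidate variants including an 80,128 bp duplication.

`polledmap` re-implements, as a tested Python library plus a set of analysis
drivers, the computational chain that locates such a locus and demonstrates its
allelic heterogeneity:

1. **Homozygosity mapping** (`polledmap.mapping`) — a shared-homozygosity
   association statistic: for case *i* and marker *m*, the run score is
   s<sub>i</sub>(m) = Σ<sub>k∈run(i,m)</sub> −log₁₀ p<sub>hom</sub>(k) with
   p<sub>hom</sub>(k) = f<sub>k</sub>² + (1−f<sub>k</sub>)² from control allele
   frequencies, and the per-marker statistic is the harmonic mean
   S(m) = N / Σ<sub>i</sub> 1/s<sub>i</sub>(m), which is positive iff **every**
   case is homozygous at *m*. Genome-wide significance comes from permuting
   whole marker columns along the chromosomes and taking the per-permutation
   genome-wide maximum; the candidate interval runs between the informative
   markers flanking the homozygous core.
2. **Concordance filtering** (`polledmap.filtering`) — under a dominant
   biallelic model with a horned-derived reference genome, a causative variant
   must show VAF 95–100% in every PP sire, 40–60% in every Pp sire, be
   undetected in every pp sire, and differ from the reference (minimum calling
   depth 20, detection floor VAF 0.01). Running the filter pooled and per breed
   subgroup detects allelic heterogeneity as disjoint subgroup survivor sets
   with no pooled survivor.
3. **Read-depth CNV detection** (`polledmap.cnv`) — dynamic bins closed at
   every 400th reference read start, median-centred log2 coverage ratios, and
   circular binary segmentation (recursive maximal-t arc search with
   permutation significance).
4. **Conservation ranking** (`polledmap.conservation`) — rule-based
   prioritisation from per-base conservation scores of bovid ruminants vs
   unhorned mammals, repeat masking and cross-species alleles.
5. **Population association** (`polledmap.association`) — perfect-association
   testing, compound-heterozygote scans, within-block recombination checks,
   genotype cross-tabulation, and progeny-based PP/Pp declaration (PP after
   ≥12 consecutive polled offspring from horned mates, misclassification
   probability 0.5ⁿ).

All inputs are produced by `polledmap.simulate`, a first-class synthetic-data
module that plants the structures the study design assumes (shared case
haplotype, genotype-class-concordant causal VAFs, a copy-ratio-2 duplication,
compound heterozygotes) so the whole pipeline runs with no external data.

## Worked example

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_map_locus.py --seed 1
python analysis/03_filter_variants.py
python analysis/04_detect_cnv.py --seed 1
```

prints, among other things:

```
genome-wide threshold (alpha=0.01, 500 permutations): 1.216
homozygous core: 9 markers (1,680,000-2,000,000)
candidate interval: 1,640,000-2,040,000 (400 kb)
pooled sample set: 0 survivors
HF subgroup: 7 survivors (P_5ID, P_G1654405A, P_C1655463T, P_T1671849G, P_T1680646C, P_C1768587A, P_T1909354A)
nonHF subgroup: 1 survivors (P_202ID)
allelic heterogeneity detected: True
duplication call: 1,908,943-1,989,642 (80,700 bp); planted event 1,909,352-1,989,480 (80,128 bp)
```

The mapping scan recovers the planted nine-marker homozygous core and bounds it
by the nearest case-variable markers; the subgroup filter finds seven
candidates private to the Holstein-Friesian subgroup and a single candidate in
the other breeds while the pooled filter finds none — the signature of allelic
heterogeneity; and segmentation of the read-depth ratios recovers the planted
80 kb duplication with a segment mean near log₂ 2 = 1.
`analysis/05_rank_candidates.py` and `analysis/06_population_association.py`
then rank the Friesian candidates (duplication and the bovid-only-conserved
SNV on top) and verify perfect association, three compound-heterozygous
P<sub>C</sub>/P<sub>F</sub> bulls and 78.03% wild-type homozygotes in the
population table.

`polledmap.pipeline.run_pipeline(RunConfig(seed=1))` runs all stages in one
call and writes per-stage outputs plus a JSON summary.

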