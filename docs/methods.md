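# Methods

This note records the models, conventions and numerical choices behind
`cnvassoc`, and what the synthetic cohorts do and do not emulate.

## Coordinates and domain model

All intervals are 1-based inclusive; length = end − start + 1. Published
CNV tables in this field print positions in 1-based style, so BED inputs
(0-based half-open) are shifted once at the I/O boundary and never again.
Only autosomes 1–22 are accepted (the loci of interest are autosomal);
a leading `chr` is stripped. A call with copy number 2 is rejected at parse
time rather than silently dropped — it indicates an upstream caller error,
not a variant.

## Quality control

- **Sample QC**: exclude samples with log R ratio s.d. strictly above 0.29
  (the conventional Affymetrix 6.0 array-quality cut). The inequality is
  strict: 0.29 is kept, 0.30 is excluded.
- **Call floor**: keep calls with ≥ 3 markers *and* ≥ 1000 bp, the floor
  below which array segmentations are unreliable.
- **Consensus**: a caller-A call is high-confidence iff a same-sample,
  same-chromosome caller-B call on the same side of copy number 2 overlaps
  it by ≥ 50%. The overlap fraction's denominator is the *shorter* call
  (`consensus_overlap_mode="min"`): this reading is symmetric and the
  strictest of the common conventions ("A-relative" and "reciprocal" are
  selectable). State matching requires the same direction, not the same
  integer copy number, because callers disagree on 0-vs-1 and 3-vs-4 far
  more often than on direction. The emitted consensus call carries caller
  A's boundaries, copy number and marker count, keeping discovery
  geometrically comparable with the single-caller replication arm.
- **Call-count outliers**: within an analysis group, exclude samples whose
  consensus-call count exceeds mean + 3 s.d. (sample s.d., ddof = 1),
  computed in a single pass — not iteratively re-estimated — with samples
  at zero calls included in the mean.
- **Stringent re-test**: identified CNVRs are re-tested with only ≥ 10
  marker calls; the flag records whether the association survives at
  p < 0.05 with the same direction.

## CNVR aggregation and stratification

A CNVR is a connected component of the overlap graph whose nodes are calls
and whose edges join same-chromosome calls sharing ≥ 1 bp, iterated to a
fixpoint; since calls are intervals, a sorted sweep per chromosome computes
exactly these components, making the result independent of input order.
Duplications and deletions merge into one region (the state is recorded per
member) because dup and del frequencies are reported for the same CNVR.
Aggregation deliberately uses the ≥ 1 bp rule, not 50%: the 50% rule is
reserved for caller consensus and cross-cohort counterpart matching.

Size class (500 kb) is assigned per *call* before aggregation and the CNVR
inherits its members' class, even when the merged span crosses 500 kb.
Carrier frequency uses the pooled (cases + controls) analysis-group
denominator; a sample carrying both a dup and a del counts once as a
carrier and once in each state-specific frequency. Small CNVRs below 1%
carrier frequency are dropped (high false-positive risk at desk-accessible
sample sizes); singleton CNVRs (one carrier) are flagged untestable.
CNVRs that overlap no reference-catalogue interval are excluded; the
overlap ratio is the fraction of the CNVR covered by the union of
overlapping reference intervals, so it lies in [0, 1] and equals 1 only
under full coverage.

## Statistics

- **Fisher exact tests** are computed by full enumeration of the
  hypergeometric support in exact integer arithmetic (`math.comb`); the
  shared denominator cancels, so two-sided ties (tables whose point
  probability equals the observed one) are resolved exactly rather than in
  floating point, and the returned float is the correctly rounded value of
  the exact rational p. One-tailed means carrier enrichment in cases; the
  two-tailed rule is the point-probability convention (sum of tables at
  most as probable), the dominant convention in genetics software.
  Degenerate margins (no carriers anywhere) give p = 1, direction none.
- **The blind scan** is a one-way two-group ANOVA on the coded state
  (deletion = −1, normal = 0, duplication = +1); for two groups this equals
  the squared-t test and is sensitive to net dup/del shifts. A 2×3
  chi-square on state counts is emitted alongside as a robustness
  companion (`extra["chi2_2x3_p"]`); neither is corrected for multiple
  testing — the scan threshold is p < 0.01 uncorrected, candidate and
  replication thresholds p < 0.05, by design.
- **Cross-disorder contrasts** are two-tailed Fisher tests on carriers of
  one state, SZ patients vs BD patients.
- **Burden** is a one-tailed label-permutation test (default 10 000
  permutations, add-one p, bit-reproducible per seed) on the case−control
  difference in mean per-sample counts of calls ≥ the size threshold whose
  CNVR carrier frequency is < 1%. A permutation test was chosen because
  CNV counts are overdispersed and no distributional form is assumed.
- **Replication**: counterpart = the other-cohort CNVR covering ≥ 50% of
  the *discovery* CNVR (discovery-anchored, hence deliberately asymmetric;
  ≥ is inclusive at exactly 50%, consistently with consensus matching).
  Replicated requires counterpart p < 0.05 *and* the same direction;
  "consistent direction, not significant" is reported distinctly. Batch
  consistency gates only on direction (per-batch p-values are descriptive),
  since batch-level significance is underpowered by construction.
- **SNP tagging**: r² is the squared Pearson correlation between the
  trichotomous CNVR dosage and SNP dosage, pairwise-complete over missing
  genotypes. Neighbors are SNPs within 2 Mb of the CNVR boundary (0 bp
  inside). Classification precedence: tagged if best neighbor r² > 0.2;
  else distant-better if the best distant r² exceeds the best neighbor r²;
  else untagged — the one ordering that yields a disjoint three-way
  partition. r² is invariant to affine recoding, so for single-state CNVRs
  the trichotomous and carrier-indicator codings agree.

## Synthetic cohorts

The generator emulates: two diagnosis groups plus controls across batches;
per-group Bernoulli carrier draws (or exact counts, for hand-checkable
fixtures); caller-A boundary jitter up to ±10% of the planted length;
caller B derived from caller A with Gaussian boundary jitter and dropout;
Poisson background calls (default 37.5 calls/sample, the overall burden
typical of dense-array consensus callsets) with a 1 kb–1 Mb log-uniform
size mixture, placed outside planted territory, a configurable fraction
violating the marker/length floors to exercise the filters; lrr-sd draws
with a configurable outlier fraction above 0.29 and an optional 20×-rate
excess-call sample; a reference set covering planted regions (unless
`in_dgv=False`) plus random intervals; and tag SNPs built by copying the
carrier indicator and swapping entries until the realized r² reaches the
target, which preserves allele frequency and converges within ±0.1 of the
target at n ≥ 2000.

Not emulated: raw intensity tracks, LD blocks beyond single tag SNPs,
correlated caller errors, batch effects on call rates, and sex
chromosomes. Passing tests therefore demonstrate the *pipeline logic* —
filters, aggregation, test calibration, replication bookkeeping — not
robustness to platform artifacts in real intensity data.

## Experiment sizes and seeds

The reference experiments (`cnvassoc.experiments`) use: the published
cohort sizes (2416/2393, replication 2127/2491) with a background rate of
2 calls/sample and 50 seeded replicates for the two-cohort recovery run;
1000 null CNVRs at 500/500 for scan calibration (acceptance band: the
exact binomial 95% interval around the 1% nominal rate); and n = 2000 for
tagging recovery. In the tagging partition experiment the unlinked SNP
count is set to zero and the untagged CNVR receives a linkage-equilibrium
neighbor SNP, so the planted tagged/distant/untagged classes are
identifiable ground truth rather than accidents of random SNP placement.
All experiment randomness flows from a single seed through
`numpy.random.default_rng`.

## Known limitations

- The ANOVA response coding treats a deletion and a duplication as
  opposite-sign doses; a CNVR where cases gain duplications and lose
  deletions in equal measure is invisible to the F-test (the chi-square
  companion catches it).
- Exact Fisher enumeration is O(support × big-int cost); for very common
  CNVRs (thousands of carriers) it is slower than asymptotic tests but
  still sub-second at the cohort sizes used here.
- Frequencies reported from printed tables are rounded to 5 decimals;
  reconstructing counts as round(freq × N) can be off by one carrier when
  the underlying denominator differed slightly from the printed group
  size, which shifts a p-value in its third significant figure.
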