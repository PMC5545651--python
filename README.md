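# cnvassoc

Case–control association analysis of copy number variant regions (CNVRs),
for array-based psychiatric genetics studies that compare schizophrenia
(SZ) and bipolar disorder (BD) cases against healthy controls.

Copy number variants (CNVs) are duplicated or deleted chromosomal segments
(≥ 1 kb; integer copy numbers 0–4, where 2 is normal). Association studies
of CNVs face two practical problems this package addresses as a tested,
reusable pipeline:

1. **Call quality.** Array CNV callers disagree; single-caller callsets are
   noisy. `cnvassoc` applies the standard QC cascade — exclude samples with
   log R ratio s.d. > 0.29, ignore calls below 3 markers or 1 kb, keep only
   calls confirmed by a second caller at ≥ 50% fractional overlap with the
   same direction, and drop per-group samples with an excess call count
   (> mean + 3 s.d.).
2. **The unit of testing.** Individual calls have fuzzy boundaries, so
   overlapping calls (≥ 1 shared bp, iterated to a fixpoint) are aggregated
   into CNV regions. CNVRs are stratified by size (500 kb) and carrier
   frequency (1%): large CNVRs are tested regardless of frequency, small
   common CNVRs are tested, and small rare CNVRs are skipped as
   false-positive-prone. CNVRs absent from a reference catalogue of known
   variation (DGV-style) are excluded.

Statistics, per CNVR, on the trichotomous carrier state (copy numbers 0/1 →
deletion, 2 → normal, 3/4 → duplication):

- **Candidate loci**: exact Fisher tests on the 2×2 carrier table, computed
  by full integer enumeration of the hypergeometric support (one-tailed for
  a priori case-enrichment hypotheses, point-probability two-tailed
  otherwise). A bundled table of 15 large CNV loci previously implicated in
  SZ ships with hg18 coordinates and published cohort frequencies.
- **Blind scan**: one-way ANOVA on the −1/0/+1 coding (p < 0.01,
  uncorrected), with a supplementary 2×3 chi-square.
- **Cross-disorder**: two-tailed Fisher, SZ patients vs BD patients.
- **Burden**: one-tailed label-permutation test on the per-sample count of
  rare (< 1%) large (≥ 100 kb or ≥ 500 kb) calls.
- **Replication**: a discovery CNVR is replicated when a counterpart region
  in a second, single-caller cohort — covering ≥ 50% of the discovery CNVR —
  shows p < 0.05 with the same direction of effect; batch consistency and a
  stringent ≥ 10-marker re-test complete the robustness screen.
- **SNP tagging**: squared Pearson correlation between CNVR dosage and SNP
  dosages within a 2 Mb window (and beyond), classifying each common CNVR
  as tagged (r² > 0.2), distant-better, or untagged.

A synthetic-cohort generator (`cnvassoc.simulate`) produces complete
bundles — manifest, two caller outputs with boundary jitter and dropout,
planted CNVRs at specified per-group carrier frequencies, background calls,
reference regions, genes, and SNPs in partial LD with chosen CNVRs — with
the planted ground truth, so every stage is testable fully offline.

## Worked example

Candidate-locus testing from the bundled reference table
(`examples/04_candidate_loci.py`): carrier counts are reconstructed as
`round(freq × N)` from the reported frequencies (2416 SZ, 2393 controls)
and tested one-tailed:

```
locus           SZ carriers HC carriers p (one-tailed)
1q21.1 dup                5           0       3.19E-02
3q29 del                  4           0       6.36E-02
15q13.3 del               7           1       3.61E-02
16p11.2 dup               9           0       2.02E-03
22q11.2 del              16           0       1.61E-05
...
```

The 22q11.2 deletion row reads: 16 deletion carriers among 2416 cases and
none among 2393 controls; under the hypergeometric null the probability of
an allocation at least this case-skewed is 1.61 × 10⁻⁵.

End-to-end discovery on a simulated cohort (`examples/03_discovery.py`)
prints the gate accounting and flagged regions, e.g.:

```
SZ vs controls: 3 testable CNVRs
  SZ_S_00048 chr2:88870187-89229982 case 0.3220 vs control 0.1212 p=1.95E-03 (case_enriched)
```

i.e. the planted common duplication is recovered with the right direction.
Other examples cover simulation (`01`), QC/consensus (`02`), two-cohort
replication (`05`) and SNP tagging (`06`). A thin CLI wraps the same
library calls: `cnvassoc simulate|qc|consensus|cnvr|run-all|tag`.

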