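"""Sample QC, call filtering and dual-caller consensus.

Samples with noisy intensity signal (log R ratio s.d. > 0.29) are dropped,
calls below 3 markers or 1 kb are ignored, and only calls confirmed by the
second caller at >= 50% fractional overlap (same direction) survive.
"""

from cnvassoc import (
    QcThresholds, SimConfig, simulate_cohort,
    consensus_calls, filter_calls_basic, filter_samples_by_lrr_sd,
)

bundle = simulate_cohort(SimConfig(n_cases_sz=200, n_cases_bd=50, n_controls=200,
                                   background_call_rate=10.0, seed=11))
thr = QcThresholds()

kept, excluded = filter_samples_by_lrr_sd(bundle.manifest, thr)
print(f"sample QC: kept {len(kept)}, excluded {len(excluded)} (lrr_sd > {thr.lrr_sd_max})")

a = filter_calls_basic(bundle.calls_a, thr)
b = filter_calls_basic(bundle.calls_b, thr)
print(f"call filter: {len(bundle.calls_a)} -> {len(a)} caller-A calls "
      f"(>= {thr.min_markers} markers and >= {thr.min_length_bp} bp)")

consensus = consensus_calls(a, b, thr)
print(f"consensus: {len(consensus)} of {len(a)} caller-A calls confirmed by caller B")
# The consensus rate reflects caller-B dropout plus jitter pushing the
# fractional overlap below one half on short calls.
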