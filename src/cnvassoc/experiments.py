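"""Reference experiments: reproducibility surfaces computed by the package.

These functions re-run the package's own code on defined inputs — the
bundled candidate-locus table, simulated null cohorts, and two-cohort
simulations with planted effects — and return the summary quantities.
They are used by the acceptance checks and by examples; nothing in here
hard-codes an expected outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .association import anova_scan, fisher_locus_test
from .loci import EA_N_HC, EA_N_SZ, IMPLICATED_SZ_LOCI, reconstruct_counts
from .pipeline import RunConfig, run_discovery, run_replication
from .qc import QcThresholds
from .regions import build_cnvrs
from .simulate import PlantedCNVR, SimConfig, simulate_cohort
from .tagging import cnvr_dosage, tagging_scan
from .types import (
    Ancestry,
    Diagnosis,
    SampleRecord,
    SampleState,
    State,
    Tail,
)


def _dummy_groups(n_cases: int, n_controls: int) -> tuple[list[SampleRecord], list[SampleRecord]]:
    cases = [
        SampleRecord(f"CASE{i:05d}", Diagnosis.SZ, Ancestry.EA, "batch1", 0.1)
        for i in range(n_cases)
    ]
    controls = [
        SampleRecord(f"CTRL{i:05d}", Diagnosis.HC, Ancestry.EA, "batch1", 0.1)
        for i in range(n_controls)
    ]
    return cases, controls


def candidate_locus_tests() -> dict[str, float]:
    """One-tailed Fisher p for each captured candidate locus.

    Carrier counts are reconstructed from the bundled reported frequencies
    (count = round(freq x N), N_SZ = 2416, N_HC = 2393) and pushed through
    the full carrier-state -> Fisher path.
    """
    cases, controls = _dummy_groups(EA_N_SZ, EA_N_HC)
    out: dict[str, float] = {}
    for locus in IMPLICATED_SZ_LOCI:
        counts = reconstruct_counts(locus.name)
        if counts is None:
            continue
        n_sz, n_hc = counts
        states = [
            SampleState(s.sample_id, locus.name, locus.state_tested)
            for s in cases[:n_sz]
        ] + [
            SampleState(s.sample_id, locus.name, locus.state_tested)
            for s in controls[:n_hc]
        ]
        res = fisher_locus_test(
            states, cases, controls,
            tail=locus.tail, state_tested=locus.state_tested, cnvr_id=locus.name,
        )
        out[locus.name] = res.p_value
    return out


def scan_calibration(
    n_cnvrs: int = 1000,
    n_cases: int = 500,
    n_controls: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Null calibration of the blind ANOVA scan.

    Simulates CNVRs with identical state distributions in cases and
    controls (carrier frequency drawn once per CNVR from U(0.01, 0.10),
    carriers split evenly into deletions and duplications) and reports the
    fraction flagged at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    cases, controls = _dummy_groups(n_cases, n_controls)
    sample_ids = [s.sample_id for s in cases + controls]
    n_sig = 0
    for i in range(n_cnvrs):
        freq = rng.uniform(0.01, 0.10)
        states = []
        for sid in sample_ids:
            if rng.random() < freq:
                state = State.DELETION if rng.random() < 0.5 else State.DUPLICATION
                states.append(SampleState(sid, f"null{i}", state))
        res = anova_scan(states, cases, controls, cnvr_id=f"null{i}")
        if res.p_value < alpha:
            n_sig += 1
    return {"n_cnvrs": n_cnvrs, "n_significant": n_sig, "rate": n_sig / n_cnvrs}


# planted effects patterned on the strongest candidate-locus frequencies
# (a rare 22q11.2-like deletion, a rare 16p11.2-like duplication) plus one
# small common CNVR
def _discovery_planted() -> list[PlantedCNVR]:
    return [
        PlantedCNVR("del_22q", "22", 17_028_880, 20_058_138, "del",
                    freq_control=0.0, freq_sz=0.00662),
        PlantedCNVR("dup_16p", "16", 29_158_416, 30_134_444, "dup",
                    freq_control=0.0, freq_sz=0.00373),
        PlantedCNVR("small_common", "2", 88_900_000, 89_200_000, "dup",
                    freq_control=0.02, freq_sz=0.05),
    ]


def _replication_planted() -> list[PlantedCNVR]:
    # same 22q effect (should replicate), 16p direction-flipped (must not),
    # small_common absent (no counterpart expected)
    return [
        PlantedCNVR("del_22q", "22", 17_028_880, 20_058_138, "del",
                    freq_control=0.0, freq_sz=0.00662),
        PlantedCNVR("dup_16p", "16", 29_158_416, 30_134_444, "dup",
                    freq_control=0.00373, freq_sz=0.0),
    ]


@dataclass
class RecoveryReplicate:
    detected: dict[str, bool]
    detected_p: dict[str, float]
    replicated: dict[str, bool]
    false_replications: int


def _overlapping_cnvr(cnvrs, planted: PlantedCNVR):
    best, best_ov = None, 0
    for r in cnvrs:
        if r.chrom != planted.chrom:
            continue
        ov = min(r.end, planted.end) - max(r.start, planted.start) + 1
        if ov > best_ov and ov / planted.length >= 0.5:
            best, best_ov = r, ov
    return best


def end_to_end_recovery(
    n_replicates: int = 50,
    seed: int = 0,
    detect_p: float = 0.05,
) -> dict:
    """Two-cohort recovery of planted effects.

    Each replicate simulates a discovery cohort at the reference cohort's
    group sizes (2416 SZ / 2393 HC) with the planted effects above, runs
    the full discovery arm, checks each planted CNVR is flagged at
    ``detect_p`` with the right direction, then simulates a single-caller
    replication cohort (2127 SZ / 2491 HC) in which only the 22q deletion
    recurs with the same direction, and verifies the replication flags.
    The background call rate is reduced to 2 calls/sample to keep each
    replicate small.
    """
    rng = np.random.default_rng(seed)
    config = RunConfig(n_permutations=200)
    per_planted_detect = {p.name: 0 for p in _discovery_planted()}
    n_all_detected = 0
    n_true_replicated = 0
    n_false_replicated = 0
    for rep in range(n_replicates):
        s1, s2 = int(rng.integers(2**31 - 1)), int(rng.integers(2**31 - 1))
        disc_bundle = simulate_cohort(
            SimConfig(
                n_cases_sz=2416, n_cases_bd=50, n_controls=2393,
                background_call_rate=2.0, planted_cnvrs=_discovery_planted(),
                seed=s1,
            )
        )
        discovery = run_discovery(
            disc_bundle.manifest, disc_bundle.calls_a, disc_bundle.calls_b,
            disc_bundle.dgv, config=config,
        )
        g = discovery.groups["SZ"]
        scan_by_id = {r.cnvr_id: r for r in g.scan_results}
        all_detected = True
        for planted in _discovery_planted():
            cnvr = _overlapping_cnvr(
                g.strata["small_common"] + g.strata["large"], planted
            )
            res = scan_by_id.get(cnvr.cnvr_id) if cnvr is not None else None
            ok = (
                res is not None
                and res.p_value < detect_p
                and res.direction.value == "case_enriched"
            )
            per_planted_detect[planted.name] += ok
            all_detected &= ok
        n_all_detected += all_detected

        repl_bundle = simulate_cohort(
            SimConfig(
                n_cases_sz=2127, n_cases_bd=50, n_controls=2491,
                background_call_rate=2.0, planted_cnvrs=_replication_planted(),
                seed=s2,
            )
        )
        repl = run_replication(
            discovery, repl_bundle.manifest, repl_bundle.calls_a, config=config
        )
        disc_cnvrs = {r.cnvr_id: r for r in g.cnvrs_tested}
        planted_22q = _discovery_planted()[0]
        for cnvr_id, outcome in repl.outcomes.items():
            is_22q = False
            cnvr = disc_cnvrs.get(cnvr_id)
            if cnvr is not None and cnvr.chrom == planted_22q.chrom:
                ov = min(cnvr.end, planted_22q.end) - max(cnvr.start, planted_22q.start) + 1
                is_22q = ov > 0
            if outcome.replicated:
                if is_22q:
                    n_true_replicated += 1
                else:
                    n_false_replicated += 1
    return {
        "n_replicates": n_replicates,
        "recovery_rate": n_all_detected / n_replicates,
        "per_planted_detection": {
            k: v / n_replicates for k, v in per_planted_detect.items()
        },
        "true_replication_rate": n_true_replicated / n_replicates,
        "false_replications": n_false_replicated,
    }


def tagging_recovery(
    n_samples: int = 2000,
    targets: Sequence[float] = (0.0, 0.3, 0.5, 0.9),
    seed: int = 0,
) -> dict:
    """Recovery of planted CNVR-SNP linkage.

    Plants one common CNVR per target r^2 (plus one distant-tagged and one
    untagged CNVR for the three-way classification), simulates a cohort of
    ``n_samples``, rebuilds CNVRs from the consensus calls and reports the
    best-neighbor r^2 the tagging scan recovers, and each classification.
    """
    chroms = ["1", "2", "3", "4"]
    planted = [
        PlantedCNVR(
            f"tag_{t:g}", chroms[i], 60_000_000, 60_300_000, "dup" if i % 2 else "del",
            freq_control=0.2, freq_sz=0.2, freq_bd=0.2,
            linked_snp_target_r2=t,
        )
        for i, t in enumerate(targets)
    ]
    planted.append(
        PlantedCNVR("distant_tag", "5", 60_000_000, 60_300_000, "del",
                    freq_control=0.2, freq_sz=0.2, freq_bd=0.2,
                    linked_snp_target_r2=0.5, linked_snp_beyond_window=True)
    )
    # the untagged CNVR gets a neighbor SNP in linkage equilibrium, so its
    # class is identifiable (an empty neighbor set would make any stray
    # distant correlation win by default)
    planted.append(
        PlantedCNVR("untagged", "6", 60_000_000, 60_300_000, "del",
                    freq_control=0.2, freq_sz=0.2, freq_bd=0.2,
                    linked_snp_target_r2=0.0)
    )
    config = SimConfig(
        n_cases_sz=n_samples // 2, n_cases_bd=50,
        n_controls=n_samples - n_samples // 2 - 50,
        background_call_rate=1.0, n_unlinked_snps=0,
        caller_b_dropout_prob=0.0, caller_b_jitter_sd_bp=200.0,
        lrr_sd_outlier_frac=0.0, snp_missing_rate=0.01,
        planted_cnvrs=planted, seed=seed,
    )
    bundle = simulate_cohort(config)
    from .qc import consensus_calls, filter_calls_basic

    thr = QcThresholds()
    calls = consensus_calls(
        filter_calls_basic(bundle.calls_a, thr),
        filter_calls_basic(bundle.calls_b, thr),
        thr,
    )
    cnvrs = build_cnvrs(calls)
    recovered_r2: dict[str, float] = {}
    classifications: dict[str, str] = {}
    for p in planted:
        cnvr = _overlapping_cnvr(cnvrs, p)
        assert cnvr is not None, f"planted CNVR {p.name} not rebuilt"
        dosage = cnvr_dosage(cnvr, bundle.manifest)
        res = tagging_scan(cnvr, dosage, bundle.snps)
        recovered_r2[p.name] = res.best_neighbor_r2
        classifications[p.name] = res.classification
    return {
        "targets": {f"tag_{t:g}": t for t in targets},
        "recovered_r2": recovered_r2,
        "classifications": classifications,
    }
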