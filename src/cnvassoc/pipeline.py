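"""End-to-end discovery and replication workflow.

Discovery: sample QC -> call filters -> dual-caller consensus -> per-group
call-count outlier exclusion -> per-size-class CNVR aggregation ->
frequency stratification -> reference (DGV-style) confirmation -> gene
annotation -> candidate-locus Fisher tests -> blind ANOVA scans ->
cross-disorder contrasts -> burden analysis. Replication: the second
cohort is processed with single-caller calls and the same thresholds;
discovery hits are matched to counterpart CNVRs and re-tested.

Every gate appends a (stage, n_in, n_kept, n_dropped) record to the run
log, which always reconciles: n_in == n_kept + n_dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as cio
from .association import (
    anova_scan,
    burden_analysis,
    categorize_states,
    cross_disorder_test,
    fisher_locus_test,
    match_implicated_locus,
    mean_calls_per_sample,
)
from .loci import IMPLICATED_SZ_LOCI
from .qc import (
    QcThresholds,
    consensus_calls,
    exclude_call_count_outliers,
    filter_calls_basic,
    filter_samples_by_lrr_sd,
    stringent_refilter,
)
from .regions import (
    annotate_genes,
    build_cnvrs,
    classify_call_size,
    dgv_confirm,
    fill_frequencies,
    stratify_cnvrs,
)
from .replication import batch_consistency, evaluate_replication, match_counterpart
from .types import (
    AssociationResult,
    CNVCall,
    CNVRegion,
    Diagnosis,
    ImplicatedLocus,
    RegionSet,
    SampleRecord,
    SizeClass,
    State,
    Tail,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    thresholds: QcThresholds = QcThresholds()
    scan_p: float = 0.01
    replication_p: float = 0.05
    common_freq: float = 0.01
    size_split_bp: int = 500_000
    burden_size_bp: tuple[int, ...] = (100_000, 500_000)
    burden_freq_max: float = 0.01
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scan_p", "replication_p", "common_freq", "size_split_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GateRecord:
    stage: str
    n_in: int
    n_kept: int

    @property
    def n_dropped(self) -> int:
        return self.n_in - self.n_kept


@dataclass
class GroupResult:
    """Per-diagnosis-group discovery output."""

    diagnosis: Diagnosis
    cases: list[SampleRecord]
    controls: list[SampleRecord]
    calls: list[CNVCall]
    strata: dict[str, list[CNVRegion]]
    cnvrs_tested: list[CNVRegion]
    scan_results: list[AssociationResult]
    significant: list[AssociationResult]
    locus_results: dict[str, Optional[AssociationResult]] = field(default_factory=dict)
    batch_consistency: dict[str, bool] = field(default_factory=dict)
    stringent_pass: dict[str, bool] = field(default_factory=dict)
    burden: dict[int, AssociationResult] = field(default_factory=dict)


@dataclass
class DiscoveryResult:
    samples: list[SampleRecord]
    consensus: list[CNVCall]
    groups: dict[str, GroupResult]
    cross_disorder: list[AssociationResult]
    mean_calls_per_sample: float
    run_log: list[GateRecord]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


def _restrict(calls: Sequence[CNVCall], sample_ids: set[str]) -> list[CNVCall]:
    return [c for c in calls if c.sample_id in sample_ids]


def _dominant_state(cnvr: CNVRegion) -> State:
    n_dup = sum(1 for c in cnvr.member_calls if c.state is State.DUPLICATION)
    n_del = len(cnvr.member_calls) - n_dup
    return State.DUPLICATION if n_dup > n_del else State.DELETION


def _build_group_cnvrs(
    calls: Sequence[CNVCall],
    samples: Sequence[SampleRecord],
    config: RunConfig,
    dgv: Optional[RegionSet],
    genes: Optional[RegionSet],
    prefix: str,
    log: list[GateRecord],
) -> tuple[dict[str, list[CNVRegion]], list[CNVRegion]]:
    """Size-stratified aggregation, frequency stratification, DGV gate, genes."""
    small = [c for c in calls if classify_call_size(c, config.size_split_bp) is SizeClass.SMALL]
    large = [c for c in calls if classify_call_size(c, config.size_split_bp) is SizeClass.LARGE]
    small_cnvrs = build_cnvrs(small, SizeClass.SMALL, id_prefix=f"{prefix}_S")
    large_cnvrs = build_cnvrs(large, SizeClass.LARGE, id_prefix=f"{prefix}_L")
    in_group = {s.sample_id for s in samples}
    for r in small_cnvrs + large_cnvrs:
        fill_frequencies(r, in_group, common_freq=config.common_freq)
    strata = stratify_cnvrs(small_cnvrs + large_cnvrs, common_freq=config.common_freq)
    log.append(
        GateRecord(
            f"{prefix}:stratify_small_rare_drop",
            len(small_cnvrs) + len(large_cnvrs),
            len(strata["small_common"]) + len(strata["large"]),
        )
    )

    candidates = strata["small_common"] + strata["large"]
    if dgv is not None:
        try:
            confirmed, _ = dgv_confirm(candidates, dgv)
        except Exception as exc:
            raise StageError(f"dgv_confirm: {exc}") from exc
        log.append(GateRecord(f"{prefix}:dgv_confirm", len(candidates), len(confirmed)))
    else:
        confirmed = candidates
    if genes is not None:
        annotate_genes(confirmed, genes)
    testable = [r for r in confirmed if not r.singleton]
    log.append(GateRecord(f"{prefix}:skip_singletons", len(confirmed), len(testable)))
    return strata, testable


def run_discovery(
    manifest: Sequence[SampleRecord],
    calls_a: Sequence[CNVCall],
    calls_b: Optional[Sequence[CNVCall]],
    dgv: Optional[RegionSet],
    genes: Optional[RegionSet] = None,
    config: RunConfig = RunConfig(),
    implicated_loci: Sequence[ImplicatedLocus] = tuple(IMPLICATED_SZ_LOCI),
    outdir=None,
) -> DiscoveryResult:
    """Run the full discovery arm. ``calls_b=None`` skips consensus
    (single-caller mode, as used for the replication cohort)."""
    log: list[GateRecord] = []

    kept, excluded = filter_samples_by_lrr_sd(list(manifest), config.thresholds)
    log.append(GateRecord("lrr_sd_filter", len(manifest), len(kept)))
    kept_ids = {s.sample_id for s in kept}

    fa = filter_calls_basic(_restrict(calls_a, kept_ids), config.thresholds)
    log.append(GateRecord("basic_call_filter_A", len(_restrict(calls_a, kept_ids)), len(fa)))
    if calls_b is not None:
        fb = filter_calls_basic(_restrict(calls_b, kept_ids), config.thresholds)
        consensus = consensus_calls(fa, fb, config.thresholds)
        log.append(GateRecord("consensus", len(fa), len(consensus)))
    else:
        consensus = fa

    overall_burden = mean_calls_per_sample(consensus, kept)

    groups: dict[str, GroupResult] = {}
    controls_all = [s for s in kept if s.diagnosis is Diagnosis.HC]
    for dx in (Diagnosis.SZ, Diagnosis.BD):
        cases = [s for s in kept if s.diagnosis is dx]
        if not cases or not controls_all:
            continue
        group_samples = cases + controls_all
        g_kept, g_excl, _ = exclude_call_count_outliers(
            group_samples, consensus, config.thresholds
        )
        log.append(GateRecord(f"{dx.value}:call_count_outliers", len(group_samples), len(g_kept)))
        g_ids = {s.sample_id for s in g_kept}
        g_cases = [s for s in g_kept if s.diagnosis is dx]
        g_controls = [s for s in g_kept if s.diagnosis is Diagnosis.HC]
        g_calls = _restrict(consensus, g_ids)

        strata, testable = _build_group_cnvrs(
            g_calls, g_kept, config, dgv, genes, prefix=dx.value, log=log
        )

        scan_results: list[AssociationResult] = []
        for r in testable:
            states = categorize_states(r, g_kept)
            res = anova_scan(states, g_cases, g_controls, cnvr_id=r.cnvr_id)
            scan_results.append(res)
        significant = [r for r in scan_results if r.p_value < config.scan_p]
        log.append(GateRecord(f"{dx.value}:scan_significant", len(scan_results), len(significant)))

        locus_results: dict[str, Optional[AssociationResult]] = {}
        if dx is Diagnosis.SZ:
            all_cnvrs = strata["large"]
            for locus in implicated_loci:
                cnvr = match_implicated_locus(locus, all_cnvrs)
                if cnvr is None:
                    locus_results[locus.name] = None
                    continue
                states = categorize_states(cnvr, g_kept)
                locus_results[locus.name] = fisher_locus_test(
                    states, g_cases, g_controls,
                    tail=locus.tail, state_tested=locus.state_tested,
                    cnvr_id=cnvr.cnvr_id,
                )

        by_id = {r.cnvr_id: r for r in testable}
        batch_flags: dict[str, bool] = {}
        stringent_flags: dict[str, bool] = {}
        if significant:
            stringent = stringent_refilter(g_calls, config.thresholds)
            for res in significant:
                cnvr = by_id[res.cnvr_id]
                ok, _table = batch_consistency(cnvr, g_cases, g_controls)
                batch_flags[res.cnvr_id] = ok
                member_ids = {id(c) for c in cnvr.member_calls}
                s_members = [c for c in stringent if id(c) in member_ids]
                if not s_members:
                    stringent_flags[res.cnvr_id] = False
                    continue
                s_cnvr = CNVRegion(
                    cnvr_id=res.cnvr_id + "_stringent", chrom=cnvr.chrom,
                    start=min(c.start for c in s_members),
                    end=max(c.end for c in s_members),
                    member_calls=s_members, size_class=cnvr.size_class,
                )
                s_res = anova_scan(
                    categorize_states(s_cnvr, g_kept), g_cases, g_controls,
                    cnvr_id=s_cnvr.cnvr_id,
                )
                stringent_flags[res.cnvr_id] = (
                    s_res.p_value < config.replication_p
                    and s_res.direction is res.direction
                )

        burden: dict[int, AssociationResult] = {}
        if len(g_cases) >= 10 and len(g_controls) >= 10:
            for size_bp in config.burden_size_bp:
                burden[size_bp] = burden_analysis(
                    g_calls, g_cases, g_controls,
                    size_min_bp=size_bp, freq_max=config.burden_freq_max,
                    n_permutations=config.n_permutations, seed=config.seed,
                )

        groups[dx.value] = GroupResult(
            diagnosis=dx, cases=g_cases, controls=g_controls, calls=g_calls,
            strata=strata, cnvrs_tested=testable, scan_results=scan_results,
            significant=significant, locus_results=locus_results,
            batch_consistency=batch_flags, stringent_pass=stringent_flags,
            burden=burden,
        )

    # cross-disorder: CNVRs significant in either scan, SZ patients vs BD patients
    cross: list[AssociationResult] = []
    if "SZ" in groups and "BD" in groups:
        sz, bd = groups["SZ"], groups["BD"]
        sz_by_id = {r.cnvr_id: r for r in sz.cnvrs_tested}
        for res in sz.significant + bd.significant:
            source = sz if res in sz.significant else bd
            cnvr = {r.cnvr_id: r for r in source.cnvrs_tested}[res.cnvr_id]
            states = categorize_states(cnvr, sz.cases + bd.cases)
            cross.append(
                cross_disorder_test(
                    states, sz.cases, bd.cases,
                    state_tested=_dominant_state(cnvr), cnvr_id=res.cnvr_id,
                )
            )

    result = DiscoveryResult(
        samples=kept,
        consensus=consensus,
        groups=groups,
        cross_disorder=cross,
        mean_calls_per_sample=overall_burden,
        run_log=log,
    )
    if outdir is not None:
        _write_discovery_reports(result, outdir)
    return result


@dataclass
class ReplicationResult:
    cohort_cnvrs: list[CNVRegion]
    outcomes: dict[str, "object"]  # discovery cnvr_id -> ReplicationOutcome
    run_log: list[GateRecord]


def run_replication(
    discovery: DiscoveryResult,
    repl_manifest: Sequence[SampleRecord],
    repl_calls: Sequence[CNVCall],
    config: RunConfig = RunConfig(),
    diagnosis: Diagnosis = Diagnosis.SZ,
) -> ReplicationResult:
    """Test discovery hits in a second cohort called with a single caller."""
    if diagnosis.value not in discovery.groups:
        raise StageError(f"replication: no discovery group {diagnosis.value}")
    g = discovery.groups[diagnosis.value]
    log: list[GateRecord] = []

    kept, _ = filter_samples_by_lrr_sd(list(repl_manifest), config.thresholds)
    log.append(GateRecord("repl:lrr_sd_filter", len(repl_manifest), len(kept)))
    kept_ids = {s.sample_id for s in kept}
    calls = filter_calls_basic(_restrict(repl_calls, kept_ids), config.thresholds)
    r_kept, _, _ = exclude_call_count_outliers(kept, calls, config.thresholds)
    log.append(GateRecord("repl:call_count_outliers", len(kept), len(r_kept)))
    r_ids = {s.sample_id for s in r_kept}
    calls = _restrict(calls, r_ids)
    cases = [s for s in r_kept if s.diagnosis is diagnosis]
    controls = [s for s in r_kept if s.diagnosis is Diagnosis.HC]

    strata, _testable = _build_group_cnvrs(
        calls, r_kept, config, dgv=None, genes=None, prefix="REPL", log=log
    )
    cohort_cnvrs = strata["small_common"] + strata["large"]

    by_id = {r.cnvr_id: r for r in g.cnvrs_tested}
    outcomes = {}
    for res in g.significant:
        cnvr = by_id[res.cnvr_id]
        counterpart = match_counterpart(cnvr, cohort_cnvrs)
        if counterpart is None:
            outcomes[res.cnvr_id] = evaluate_replication(res, None)
            continue
        states = categorize_states(counterpart, r_kept)
        c_res = anova_scan(states, cases, controls, cnvr_id=counterpart.cnvr_id)
        outcomes[res.cnvr_id] = evaluate_replication(
            res, c_res, counterpart, alpha=config.replication_p
        )
    return ReplicationResult(cohort_cnvrs=cohort_cnvrs, outcomes=outcomes, run_log=log)


def _write_discovery_reports(result: DiscoveryResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, g in result.groups.items():
        cio.write_cnvr_report(
            g.strata["small_common"] + g.strata["large"],
            outdir / f"cnvrs_{name}.tsv",
        )
        cio.write_association_report(g.scan_results, outdir / f"scan_{name}.tsv")
        locus_res = [r for r in g.locus_results.values() if r is not None]
        if locus_res:
            cio.write_association_report(locus_res, outdir / f"loci_{name}.tsv")
        if g.burden:
            cio.write_association_report(
                list(g.burden.values()), outdir / f"burden_{name}.tsv"
            )
    if result.cross_disorder:
        cio.write_association_report(result.cross_disorder, outdir / "cross_disorder.tsv")
    with open(outdir / "run_log.tsv", "w") as fh:
        fh.write("stage\tn_in\tn_kept\tn_dropped\n")
        for rec in result.run_log:
            fh.write(f"{rec.stage}\t{rec.n_in}\t{rec.n_kept}\t{rec.n_dropped}\n")


def write_replication_report(repl: ReplicationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cnvr_id\tcounterpart_id\tcounterpart_freq\tcounterpart_p\t"
            "consistent_direction\treplicated\treason\n"
        )
        for cnvr_id in sorted(repl.outcomes):
            o = repl.outcomes[cnvr_id]
            fh.write(
                f"{cnvr_id}\t{o.counterpart_id or 'NA'}\t{o.counterpart_freq:.5f}\t"
                f"{o.counterpart_p:.3E}\t{int(o.consistent_direction)}\t"
                f"{int(o.replicated)}\t{o.reason}\n"
            )
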