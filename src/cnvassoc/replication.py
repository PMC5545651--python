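"""Cross-cohort counterpart matching and the robustness screen.

A discovery CNVR is replicated when a counterpart CNVR in the second
cohort — one covering at least half of the discovery CNVR's span — shows a
significant association (p < 0.05) in the same direction. Consistent
direction without significance is reported distinctly. Batch consistency
(same direction of effect in every batch with carriers) and survival of a
stringent >= 10-marker re-filter complete the screen.
"""

from __future__ import annotations

from typing import Sequence

from .types import (
    AssociationResult,
    CNVRegion,
    Direction,
    ReplicationOutcome,
    SampleRecord,
)

REPLICATION_P = 0.05


def match_counterpart(
    cnvr: CNVRegion,
    other_cohort_cnvrs: Sequence[CNVRegion],
    min_overlap: float = 0.5,
) -> CNVRegion | None:
    """Other-cohort CNVR covering >= ``min_overlap`` of the discovery CNVR.

    The denominator is the discovery CNVR's length (discovery-anchored, so
    matching is deliberately asymmetric); the largest coverage wins ties.
    """
    best: CNVRegion | None = None
    best_ov = -1
    for r in other_cohort_cnvrs:
        if r.chrom != cnvr.chrom:
            continue
        ov = min(r.end, cnvr.end) - max(r.start, cnvr.start) + 1
        if ov <= 0:
            continue
        if ov / cnvr.length >= min_overlap and ov > best_ov:
            best, best_ov = r, ov
    return best


def evaluate_replication(
    discovery_result: AssociationResult,
    counterpart_result: AssociationResult | None,
    counterpart: CNVRegion | None = None,
    alpha: float = REPLICATION_P,
) -> ReplicationOutcome:
    """Replicated iff a counterpart exists with p < alpha and the same direction."""
    if counterpart_result is None:
        return ReplicationOutcome(
            cnvr_id=discovery_result.cnvr_id,
            counterpart_id=None,
            counterpart_freq=float("nan"),
            counterpart_p=float("nan"),
            consistent_direction=False,
            replicated=False,
            reason="no counterpart",
        )
    consistent = (
        discovery_result.direction is not Direction.NONE
        and counterpart_result.direction is discovery_result.direction
    )
    significant = counterpart_result.p_value < alpha
    if consistent and significant:
        reason = "replicated"
    elif consistent:
        reason = "consistent direction, not significant"
    else:
        reason = "direction inconsistent"
    return ReplicationOutcome(
        cnvr_id=discovery_result.cnvr_id,
        counterpart_id=counterpart.cnvr_id if counterpart is not None
        else counterpart_result.cnvr_id,
        counterpart_freq=counterpart.carrier_frequency if counterpart is not None
        else float("nan"),
        counterpart_p=counterpart_result.p_value,
        consistent_direction=consistent,
        replicated=consistent and significant,
        reason=reason,
    )


def batch_consistency(
    cnvr: CNVRegion,
    case_group: Sequence[SampleRecord],
    control_group: Sequence[SampleRecord],
) -> tuple[bool, list[dict]]:
    """Direction of the case-control carrier-fraction difference, per batch.

    Consistent iff every batch with at least one carrier agrees with the
    pooled direction. With a single batch the flag is trivially true and
    the table marks it untestable. Per-batch p-values are reported
    descriptively (they do not gate the flag).
    """
    from .association import fisher_exact_carriers

    carriers = cnvr.carrier_ids
    batches = sorted({s.batch for s in case_group} | {s.batch for s in control_group})

    def _fracs(case_s, control_s):
        nc = sum(1 for s in case_s if s.sample_id in carriers)
        nh = sum(1 for s in control_s if s.sample_id in carriers)
        fc = nc / len(case_s) if case_s else 0.0
        fh = nh / len(control_s) if control_s else 0.0
        return nc, nh, fc, fh

    nc, nh, fc, fh = _fracs(case_group, control_group)
    pooled_dir = 0 if fc == fh else (1 if fc > fh else -1)

    table: list[dict] = []
    consistent = True
    for b in batches:
        bc = [s for s in case_group if s.batch == b]
        bh = [s for s in control_group if s.batch == b]
        bnc, bnh, bfc, bfh = _fracs(bc, bh)
        bdir = 0 if bfc == bfh else (1 if bfc > bfh else -1)
        p = (
            fisher_exact_carriers(bnc, bnh, len(bc), len(bh), "two-sided")
            if bc and bh
            else float("nan")
        )
        table.append(
            {
                "batch": b,
                "case_carriers": bnc,
                "control_carriers": bnh,
                "case_freq": bfc,
                "control_freq": bfh,
                "direction": bdir,
                "p_value": p,
            }
        )
        if (bnc + bnh) > 0 and bdir != 0 and bdir != pooled_dir:
            consistent = False
    untestable = len(batches) < 2
    if untestable:
        for row in table:
            row["untestable"] = True
    return consistent, table
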