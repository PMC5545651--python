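"""Sample- and call-level quality control and dual-caller consensus.

The QC sequence mirrors standard array-CNV practice: noisy samples are
dropped on log R ratio variability, tiny calls are dropped on marker count
and physical length, the two callers' segmentations are intersected into
high-confidence consensus calls, and samples with grossly excessive call
counts are removed as outliers within each analysis group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .types import Caller, CNVCall, SampleRecord, State

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """QC constants.

    lrr_sd_max: samples with log R ratio s.d. strictly above this are excluded.
    min_markers / min_length_bp: calls below either are ignored.
    stringent_min_markers: marker floor for the sensitivity re-test of
        identified CNVRs (low experimentally validated false-positive rate).
    outlier_sd_k: per-group call-count outlier cut at mean + k * sd.
    consensus_min_overlap: fractional overlap (relative to the shorter call)
        required for a call to be confirmed by the second caller.
    """

    lrr_sd_max: float = 0.29
    min_markers: int = 3
    min_length_bp: int = 1000
    stringent_min_markers: int = 10
    outlier_sd_k: float = 3.0
    consensus_min_overlap: float = 0.5
    # denominator of the consensus overlap fraction: "min" (shorter call,
    # symmetric and strictest), "a" (first caller's length) or "reciprocal"
    consensus_overlap_mode: str = "min"

    def __post_init__(self) -> None:
        if not (0 < self.consensus_min_overlap <= 1):
            raise ValueError("consensus_min_overlap must lie in (0, 1]")
        for name in ("lrr_sd_max", "min_markers", "min_length_bp",
                     "stringent_min_markers", "outlier_sd_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.consensus_overlap_mode not in ("min", "a", "reciprocal"):
            raise ValueError(f"unknown consensus_overlap_mode {self.consensus_overlap_mode!r}")


@dataclass
class ExclusionRecord:
    sample_id: str
    reason: str
    value: float
    threshold: float


def filter_samples_by_lrr_sd(
    samples: Sequence[SampleRecord], thresholds: QcThresholds = QcThresholds()
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Partition samples into (kept, excluded) on lrr_sd > lrr_sd_max (strict)."""
    kept: list[SampleRecord] = []
    excluded: list[SampleRecord] = []
    for s in samples:
        if s.lrr_sd is None or np.isnan(s.lrr_sd):
            raise ValueError(f"sample {s.sample_id}: missing lrr_sd")
        if s.lrr_sd > thresholds.lrr_sd_max:
            s.excluded = True
            s.exclusion_reason = (
                f"lrr_sd {s.lrr_sd:.4g} > {thresholds.lrr_sd_max:.4g}"
            )
            excluded.append(s)
        else:
            kept.append(s)
    logger.info("lrr_sd filter: kept %d, excluded %d", len(kept), len(excluded))
    return kept, excluded


def filter_calls_basic(
    calls: Iterable[CNVCall], thresholds: QcThresholds = QcThresholds()
) -> list[CNVCall]:
    """Keep calls with n_markers >= min_markers AND length >= min_length_bp."""
    return [
        c
        for c in calls
        if c.n_markers >= thresholds.min_markers
        and c.length >= thresholds.min_length_bp
    ]


def stringent_refilter(
    calls: Iterable[CNVCall], thresholds: QcThresholds = QcThresholds()
) -> list[CNVCall]:
    """Keep calls spanning at least ``stringent_min_markers`` markers."""
    return [c for c in calls if c.n_markers >= thresholds.stringent_min_markers]


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def overlap_fraction(a: CNVCall, b: CNVCall, mode: str = "min") -> float:
    """Fractional overlap between two calls under the chosen denominator."""
    ov = _overlap_bp(a.start, a.end, b.start, b.end)
    if ov == 0:
        return 0.0
    if mode == "min":
        return ov / min(a.length, b.length)
    if mode == "a":
        return ov / a.length
    if mode == "reciprocal":
        return min(ov / a.length, ov / b.length)
    raise ValueError(f"unknown overlap mode {mode!r}")


def consensus_calls(
    calls_a: Sequence[CNVCall],
    calls_b: Sequence[CNVCall],
    thresholds: QcThresholds = QcThresholds(),
) -> list[CNVCall]:
    """High-confidence calls detected by both callers with overlap >= 50%.

    A caller-A call is emitted (once, with caller-A boundaries, copy number
    and marker count) iff some same-sample, same-chromosome caller-B call of
    the same direction (both deletion or both duplication) overlaps it by at
    least ``consensus_min_overlap`` of the shorter call. Output order follows
    (sample, chrom, start, end), independent of input order.
    """
    by_key: dict[tuple[str, str, State], list[CNVCall]] = {}
    for b in calls_b:
        by_key.setdefault((b.sample_id, b.chrom, b.state), []).append(b)

    out: list[CNVCall] = []
    for a in sorted(calls_a, key=lambda c: (c.sample_id, c.chrom, c.start, c.end, c.copy_number)):
        candidates = by_key.get((a.sample_id, a.chrom, a.state), ())
        for b in candidates:
            if (
                overlap_fraction(a, b, thresholds.consensus_overlap_mode)
                >= thresholds.consensus_min_overlap
            ):
                out.append(
                    CNVCall(
                        sample_id=a.sample_id,
                        chrom=a.chrom,
                        start=a.start,
                        end=a.end,
                        copy_number=a.copy_number,
                        n_markers=a.n_markers,
                        caller=Caller.CONSENSUS,
                    )
                )
                break
    return out


def exclude_call_count_outliers(
    samples: Sequence[SampleRecord],
    calls: Sequence[CNVCall],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[list[SampleRecord], list[SampleRecord], list[ExclusionRecord]]:
    """Exclude samples whose call count exceeds mean + k*sd of their group.

    Mean and (sample) s.d. are computed once over the per-sample counts of
    the given samples — samples with no calls count zero — and the cut is
    strict. Returns (kept, excluded, exclusion log).
    """
    if len(samples) < 2:
        raise ValueError("call-count outlier exclusion needs at least 2 samples")
    counts = {s.sample_id: 0 for s in samples}
    for c in calls:
        if c.sample_id in counts:
            counts[c.sample_id] += 1
    values = np.array([counts[s.sample_id] for s in samples], dtype=float)
    mean = values.mean()
    sd = values.std(ddof=1)
    cutoff = mean + thresholds.outlier_sd_k * sd
    kept, excluded, log = [], [], []
    for s, v in zip(samples, values):
        if v > cutoff:
            s.excluded = True
            s.exclusion_reason = f"call count {int(v)} > {cutoff:.2f} (mean+{thresholds.outlier_sd_k:g}sd)"
            excluded.append(s)
            log.append(ExclusionRecord(s.sample_id, "excess_cnv_count", v, cutoff))
        else:
            kept.append(s)
    logger.info(
        "call-count outlier filter: mean %.2f sd %.2f cutoff %.2f -> excluded %d",
        mean, sd, cutoff, len(excluded),
    )
    return kept, excluded, log


def write_exclusion_log(records: Sequence[ExclusionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\treason\tvalue\tthreshold\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.reason}\t{r.value:.6g}\t{r.threshold:.6g}\n")
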