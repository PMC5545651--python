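"""CNV-region (CNVR) aggregation, stratification, reference confirmation
and gene annotation.

A CNVR is the connected component of the call-overlap graph: any two
same-chromosome calls sharing at least one base pair are joined, iterated
to a fixpoint, so the result is independent of input order. Because calls
are intervals, the connected components equal the clusters found by a
single sorted sweep per chromosome, which is how they are computed here.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence

from .types import (
    CNVCall,
    CNVRegion,
    FreqClass,
    RegionSet,
    SampleRecord,
    SizeClass,
    State,
)

logger = logging.getLogger(__name__)

SIZE_SPLIT_BP = 500_000
COMMON_FREQ = 0.01


def classify_call_size(call: CNVCall, size_split_bp: int = SIZE_SPLIT_BP) -> SizeClass:
    """Large iff length >= size_split_bp (default 500 kb)."""
    return SizeClass.LARGE if call.length >= size_split_bp else SizeClass.SMALL


def build_cnvrs(
    calls: Sequence[CNVCall],
    size_class: SizeClass | None = None,
    id_prefix: str = "CNVR",
) -> list[CNVRegion]:
    """Aggregate overlapping calls into CNVRs (>= 1 shared bp joins).

    ``calls`` should already be restricted to one size class and one
    analysis group (cases and controls pooled). Output is sorted by
    (chrom, start) with deterministic ids; identical up to relabeling under
    any permutation of the input.
    """
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    cnvrs: list[CNVRegion] = []
    for chrom in sorted(by_chrom, key=int):
        chrom_calls = sorted(
            by_chrom[chrom],
            key=lambda c: (c.start, c.end, c.sample_id, c.copy_number),
        )
        cluster: list[CNVCall] = []
        cluster_end = -1
        for c in chrom_calls:
            if cluster and c.start > cluster_end:
                cnvrs.append(_make_region(cluster, chrom, size_class))
                cluster = []
                cluster_end = -1
            cluster.append(c)
            cluster_end = max(cluster_end, c.end)
        if cluster:
            cnvrs.append(_make_region(cluster, chrom, size_class))

    for i, r in enumerate(cnvrs, start=1):
        r.cnvr_id = f"{id_prefix}_{i:05d}"
    return cnvrs


def _make_region(
    members: list[CNVCall], chrom: str, size_class: SizeClass | None
) -> CNVRegion:
    start = min(c.start for c in members)
    end = max(c.end for c in members)
    return CNVRegion(
        cnvr_id="",
        chrom=chrom,
        start=start,
        end=end,
        member_calls=list(members),
        size_class=size_class,
        carrier_count=len({c.sample_id for c in members}),
    )


GroupFilter = Callable[[SampleRecord], bool]


def compute_frequencies(
    cnvr: CNVRegion,
    samples: Sequence[SampleRecord],
    group_filter: GroupFilter | None = None,
    common_freq: float = COMMON_FREQ,
) -> CNVRegion:
    """Fill carrier/dup/del frequencies over the selected denominator.

    The denominator is the samples passing ``group_filter`` (all samples if
    None) — typically one analysis group with cases and controls pooled. A
    sample carrying both a duplication and a deletion counts once toward the
    carrier frequency and once in each of the dup/del frequencies.
    """
    in_group = {
        s.sample_id for s in samples if group_filter is None or group_filter(s)
    }
    return fill_frequencies(cnvr, in_group, common_freq=common_freq)


def fill_frequencies(
    cnvr: CNVRegion, in_group: set[str], common_freq: float = COMMON_FREQ
) -> CNVRegion:
    """As :func:`compute_frequencies`, with a precomputed denominator id set."""
    denom = len(in_group)
    if denom == 0:
        raise ValueError(f"{cnvr.cnvr_id}: empty denominator population")

    carriers: set[str] = set()
    dup_carriers: set[str] = set()
    del_carriers: set[str] = set()
    for c in cnvr.member_calls:
        if c.sample_id not in in_group:
            continue
        carriers.add(c.sample_id)
        if c.state is State.DUPLICATION:
            dup_carriers.add(c.sample_id)
        else:
            del_carriers.add(c.sample_id)

    cnvr.carrier_count = len(carriers)
    cnvr.carrier_frequency = len(carriers) / denom
    cnvr.dup_frequency = len(dup_carriers) / denom
    cnvr.del_frequency = len(del_carriers) / denom
    cnvr.freq_class = (
        FreqClass.COMMON if cnvr.carrier_frequency >= common_freq else FreqClass.RARE
    )
    cnvr.singleton = cnvr.carrier_count == 1
    return cnvr


def stratify_cnvrs(
    cnvrs: Iterable[CNVRegion], common_freq: float = COMMON_FREQ
) -> dict[str, list[CNVRegion]]:
    """Route CNVRs into the testable strata.

    small_common: small CNVRs at carrier frequency >= 1% (pooled denominator);
    large: all large CNVRs regardless of frequency (rare large loci are the
    classic candidates); dropped_small_rare: small rare CNVRs, skipped for
    their high false-positive risk. Singleton CNVRs are flagged untestable
    but retained in their stratum lists.
    """
    out: dict[str, list[CNVRegion]] = {
        "small_common": [],
        "large": [],
        "dropped_small_rare": [],
    }
    for r in cnvrs:
        if r.freq_class is None:
            raise ValueError(f"{r.cnvr_id}: frequencies not computed")
        if r.size_class is SizeClass.LARGE:
            out["large"].append(r)
        elif r.carrier_frequency >= common_freq:
            out["small_common"].append(r)
        else:
            out["dropped_small_rare"].append(r)
    return out


def _union_coverage_bp(start: int, end: int, hits: Sequence) -> int:
    """bp of [start, end] covered by the union of hit intervals (inclusive)."""
    clipped = sorted(
        (max(start, h.start), min(end, h.end)) for h in hits
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return covered


def dgv_confirm(
    cnvrs: Iterable[CNVRegion], dgv: RegionSet
) -> tuple[list[CNVRegion], list[CNVRegion]]:
    """Split CNVRs into (confirmed, unconfirmed) against a reference region set.

    A CNVR is confirmed iff it shares >= 1 bp with any reference interval;
    its overlap ratio is the fraction of the CNVR covered by the union of
    overlapping reference intervals. Unconfirmed CNVRs are excluded from
    association testing as likely artifacts.
    """
    if len(dgv) == 0:
        raise ValueError("reference region set is empty")
    confirmed, unconfirmed = [], []
    for r in cnvrs:
        hits = dgv.overlapping(r.chrom, r.start, r.end)
        if hits:
            r.dgv_confirmed = True
            r.dgv_overlap_ratio = _union_coverage_bp(r.start, r.end, hits) / r.length
            confirmed.append(r)
        else:
            r.dgv_confirmed = False
            r.dgv_overlap_ratio = 0.0
            unconfirmed.append(r)
    logger.info("DGV confirmation: %d confirmed, %d excluded", len(confirmed), len(unconfirmed))
    return confirmed, unconfirmed


def annotate_genes(cnvrs: Iterable[CNVRegion], genes: RegionSet) -> list[CNVRegion]:
    """Attach labels of all gene intervals overlapping each CNVR by >= 1 bp."""
    out = []
    for r in cnvrs:
        hits = genes.overlapping(r.chrom, r.start, r.end)
        seen: set[str] = set()
        labels: list[str] = []
        for h in hits:
            if h.label and h.label not in seen:
                seen.add(h.label)
                labels.append(h.label)
        r.genes = labels
        out.append(r)
    return out
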