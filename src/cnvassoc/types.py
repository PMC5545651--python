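"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout the package; an interval's
length is ``end - start + 1``. BED inputs (0-based half-open) are converted
at the I/O boundary and never re-shifted afterwards.

Copy-number states follow the standard trichotomy: copy numbers 0 and 1 are
deletions, 2 is normal (not a CNV), 3 and 4 are duplications.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

VALID_CHROMS = tuple(str(c) for c in range(1, 23))


class Caller(str, enum.Enum):
    A = "callerA"
    B = "callerB"
    CONSENSUS = "consensus"


class Diagnosis(str, enum.Enum):
    SZ = "SZ"
    BD = "BD"
    HC = "HC"


class Ancestry(str, enum.Enum):
    EA = "EA"
    AA = "AA"


class State(enum.IntEnum):
    """Trichotomous CNV state used for coding and carrier counting."""

    DELETION = -1
    NORMAL = 0
    DUPLICATION = 1


def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' and validate an autosome label ('1'..'22')."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in VALID_CHROMS:
        raise ValueError(
            f"unsupported chromosome {label!r}: only autosomes 1-22 are accepted"
        )
    return c


def state_of_copy_number(copy_number: int) -> State:
    if copy_number < 2:
        return State.DELETION
    if copy_number > 2:
        return State.DUPLICATION
    return State.NORMAL


@dataclass(frozen=True)
class CNVCall:
    """One caller-emitted CNV segment for one sample.

    ``copy_number`` must be in {0, 1, 3, 4}: a segment at copy number 2 is
    not a variant and is rejected when call files are parsed.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_markers: int
    caller: Caller = Caller.A

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for call {self}")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError(
                f"copy_number must be in {{0,1,3,4}}, got {self.copy_number}"
            )
        if self.n_markers < 1:
            raise ValueError(f"n_markers must be positive, got {self.n_markers}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> State:
        return state_of_copy_number(self.copy_number)


@dataclass
class SampleRecord:
    """Sample metadata, QC measures and group labels."""

    sample_id: str
    diagnosis: Diagnosis
    ancestry: Ancestry
    batch: str
    lrr_sd: float
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.lrr_sd < 0:
            raise ValueError(f"lrr_sd must be non-negative, got {self.lrr_sd}")
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded samples must carry a non-empty reason")


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for region {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class RegionSet:
    """A labelled set of 1-based inclusive genomic intervals.

    Backed by per-chromosome interval trees for overlap queries.
    """

    def __init__(self, regions: Sequence[Region]):
        from intervaltree import IntervalTree

        self.regions = list(regions)
        self._trees: dict[str, "IntervalTree"] = {}
        for r in self.regions:
            tree = self._trees.setdefault(r.chrom, IntervalTree())
            # intervaltree is half-open; +1 converts from inclusive ends
            tree.addi(r.start, r.end + 1, r)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Region]:
        """All regions sharing >= 1 bp with [start, end] on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end + 1)
        return sorted((h.data for h in hits), key=lambda r: (r.start, r.end, r.label))


class SizeClass(str, enum.Enum):
    SMALL = "small"
    LARGE = "large"


class FreqClass(str, enum.Enum):
    COMMON = "common"
    RARE = "rare"


@dataclass
class CNVRegion:
    """An aggregated CNV region: the span of a connected set of overlapping calls.

    Boundaries are min start / max end over member calls. Frequencies are
    filled in by :func:`cnvassoc.regions.compute_frequencies` and are carrier
    fractions of the analysis-group denominator.
    """

    cnvr_id: str
    chrom: str
    start: int
    end: int
    member_calls: list[CNVCall] = field(default_factory=list)
    size_class: Optional[SizeClass] = None
    carrier_count: int = 0
    carrier_frequency: float = 0.0
    dup_frequency: float = 0.0
    del_frequency: float = 0.0
    case_frequency: float = 0.0
    control_frequency: float = 0.0
    freq_class: Optional[FreqClass] = None
    singleton: bool = False
    dgv_confirmed: Optional[bool] = None
    dgv_overlap_ratio: float = 0.0
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def carrier_ids(self) -> set[str]:
        return {c.sample_id for c in self.member_calls}


@dataclass(frozen=True)
class SampleState:
    sample_id: str
    cnvr_id: str
    state: State


class Direction(str, enum.Enum):
    CASE_ENRICHED = "case_enriched"
    CONTROL_ENRICHED = "control_enriched"
    NONE = "none"


@dataclass
class AssociationResult:
    """Outcome of one case-control test at one CNVR or locus."""

    cnvr_id: str
    test: str  # fisher_1tail | fisher_2tail | anova_scan | cross_disorder | burden
    state_tested: str  # del | dup | any
    table: Optional[np.ndarray]
    statistic: float
    p_value: float
    direction: Direction
    case_frequency: float = float("nan")
    control_frequency: float = float("nan")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


class Tail(str, enum.Enum):
    ONE = "one"
    TWO = "two"


@dataclass(frozen=True)
class ImplicatedLocus:
    """A candidate CNV locus with an a priori hypothesis (state and tail)."""

    name: str
    chrom: str
    start: int
    end: int
    state_tested: State
    tail: Tail = Tail.ONE

    def __post_init__(self) -> None:
        if self.state_tested not in (State.DELETION, State.DUPLICATION):
            raise ValueError("state_tested must be deletion or duplication")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SnpDosageMatrix:
    """Per-sample SNP dosages in {0, 1, 2}, NaN for missing.

    ``dosages`` has shape (n_snps, n_samples) aligned to ``sample_ids``.
    Positions are sorted within each chromosome.
    """

    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray  # int, shape (n_snps,)
    sample_ids: list[str]
    dosages: np.ndarray  # float, shape (n_snps, n_samples)

    def __post_init__(self) -> None:
        n_snps = len(self.snp_ids)
        if self.dosages.shape != (n_snps, len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{n_snps} SNPs x {len(self.sample_ids)} samples"
            )
        self.positions = np.asarray(self.positions, dtype=np.int64)
        order_ok = all(
            np.all(np.diff(self.positions[[i for i, c in enumerate(self.chroms) if c == chrom]]) >= 0)
            for chrom in set(self.chroms)
        )
        if not order_ok:
            raise ValueError("SNP positions must be sorted within chromosome")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or NaN")

    def on_chrom(self, chrom: str) -> np.ndarray:
        """Indices of SNPs on ``chrom``."""
        return np.array([i for i, c in enumerate(self.chroms) if c == chrom], dtype=int)


@dataclass
class ReplicationOutcome:
    cnvr_id: str
    counterpart_id: Optional[str]
    counterpart_freq: float
    counterpart_p: float
    consistent_direction: bool
    replicated: bool
    reason: str = ""
    stringent_pass: Optional[bool] = None
    batch_consistent: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.replicated:
            assert self.counterpart_id is not None
            assert self.counterpart_p < 0.05 and self.consistent_direction


@dataclass
class TaggingResult:
    cnvr_id: str
    best_neighbor_r2: float
    best_neighbor_snp: Optional[str]
    best_neighbor_distance: Optional[int]
    best_distant_r2: float
    best_distant_snp: Optional[str]
    classification: str  # tagged | distant_better | untagged | monomorphic
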