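"""Synthetic case-control CNV cohorts with known ground truth.

The generator emulates the structure of an array-based psychiatric CNV
study: a manifest with two patient groups (SZ, BD) plus controls split
over genotyping batches, two caller outputs per sample (the second caller
re-segments the first's calls with boundary jitter and occasional
dropout), planted CNVRs with specified per-group carrier frequencies,
Poisson background calls, a reference region set covering real variation,
a gene interval set, and SNPs in partial LD with selected CNVRs. The
planted ground truth is returned alongside, so every pipeline stage can be
checked against what was actually put in.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .types import (
    Ancestry,
    Caller,
    CNVCall,
    Diagnosis,
    Region,
    RegionSet,
    SampleRecord,
    SnpDosageMatrix,
)

# approximate autosome lengths, bp (build hg18 scale)
AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 247_249_719, "2": 242_951_149, "3": 199_501_827, "4": 191_273_063,
    "5": 180_857_866, "6": 170_899_992, "7": 158_821_424, "8": 146_274_826,
    "9": 140_273_252, "10": 135_374_737, "11": 134_452_384, "12": 132_349_534,
    "13": 114_142_980, "14": 106_368_585, "15": 100_338_915, "16": 88_827_254,
    "17": 78_774_742, "18": 76_117_153, "19": 63_811_651, "20": 62_435_964,
    "21": 46_944_323, "22": 49_691_432,
}


@dataclass
class PlantedCNVR:
    """One ground-truth CNV region with per-group carrier frequencies."""

    name: str
    chrom: str
    start: int
    end: int
    state: str  # "del" | "dup" | "mixed"
    freq_control: float = 0.0
    freq_sz: float = 0.0
    freq_bd: float = 0.0
    in_dgv: bool = True
    linked_snp_target_r2: Optional[float] = None
    linked_snp_beyond_window: bool = False
    # exact carrier counts override the Bernoulli frequencies when set
    n_control: Optional[int] = None
    n_sz: Optional[int] = None
    n_bd: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"planted CNVR {self.name}: end < start")
        for f in (self.freq_control, self.freq_sz, self.freq_bd):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"planted CNVR {self.name}: frequency {f} outside [0,1]")
        if self.state not in ("del", "dup", "mixed"):
            raise ValueError(f"planted CNVR {self.name}: unknown state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimConfig:
    n_cases_sz: int = 2416
    n_cases_bd: int = 592
    n_controls: int = 2393
    n_batches: int = 3
    ancestry: Ancestry = Ancestry.EA
    # mean background calls per sample; the default matches the overall CNV
    # burden typical of dense-array consensus callsets (~37.5 calls/sample)
    background_call_rate: float = 37.5
    planted_cnvrs: list[PlantedCNVR] = field(default_factory=list)
    planted_jitter_frac: float = 0.1  # per-boundary uniform jitter, x length
    caller_b_jitter_sd_bp: float = 500.0
    caller_b_dropout_prob: float = 0.05
    marker_density_bp: float = 1250.0
    lrr_sd_mean: float = 0.12
    lrr_sd_sd: float = 0.04
    lrr_sd_outlier_frac: float = 0.01  # fraction pushed above the 0.29 QC cut
    background_tiny_frac: float = 0.05  # fraction violating the 3-marker/1-kb floor
    plant_excess_call_sample: bool = False  # one sample at 20x background rate
    n_unlinked_snps: int = 50
    snp_missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases_sz, self.n_cases_bd, self.n_controls, self.n_batches) <= 0:
            raise ValueError("sample and batch counts must be positive")
        for p in (self.caller_b_dropout_prob, self.lrr_sd_outlier_frac,
                  self.background_tiny_frac, self.snp_missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        by_chrom: dict[str, list[PlantedCNVR]] = {}
        for p in self.planted_cnvrs:
            by_chrom.setdefault(p.chrom, []).append(p)
        for chrom, group in by_chrom.items():
            ordered = sorted(group, key=lambda g: g.start)
            for u, v in zip(ordered, ordered[1:]):
                if v.start <= u.end:
                    raise ValueError(
                        f"planted CNVRs {u.name} and {v.name} overlap on chrom {chrom}; "
                        "truth would be ambiguous"
                    )


@dataclass
class SimTruth:
    """Ground truth emitted with each simulated bundle."""

    carriers: dict[str, set[str]]  # planted name -> carrier sample ids
    carrier_states: dict[str, dict[str, str]]  # name -> sample -> del|dup
    expected_direction: dict[str, str]  # name -> case_enriched|control_enriched|none
    linked_snps: dict[str, str]  # planted name -> snp id


@dataclass
class Bundle:
    manifest: list[SampleRecord]
    calls_a: list[CNVCall]
    calls_b: list[CNVCall]
    dgv: RegionSet
    genes: RegionSet
    snps: SnpDosageMatrix
    truth: SimTruth
    config: SimConfig


def _draw_carriers(
    rng: np.random.Generator, ids: Sequence[str], freq: float, exact: Optional[int]
) -> list[str]:
    if exact is not None:
        if exact > len(ids):
            raise ValueError("exact carrier count exceeds group size")
        return list(rng.choice(np.asarray(ids, dtype=object), size=exact, replace=False))
    mask = rng.random(len(ids)) < freq
    return [sid for sid, m in zip(ids, mask) if m]


def _jitter_interval(
    rng: np.random.Generator, start: int, end: int, frac: float
) -> tuple[int, int]:
    length = end - start + 1
    span = int(frac * length)
    if span > 0:
        start = start + int(rng.integers(-span, span + 1))
        end = end + int(rng.integers(-span, span + 1))
    if end < start:
        start, end = end, start
    return max(1, start), max(1, end)


def _markers_for(length: int, density: float) -> int:
    return max(1, round(length / density))


def simulate_cohort(config: SimConfig) -> Bundle:
    """Generate a full cohort bundle; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)

    # --- manifest ---------------------------------------------------------
    manifest: list[SampleRecord] = []
    groups = (
        [(f"SZ{i:05d}", Diagnosis.SZ) for i in range(config.n_cases_sz)]
        + [(f"BD{i:05d}", Diagnosis.BD) for i in range(config.n_cases_bd)]
        + [(f"HC{i:05d}", Diagnosis.HC) for i in range(config.n_controls)]
    )
    n = len(groups)
    batches = rng.integers(0, config.n_batches, size=n)
    lrr = np.clip(rng.normal(config.lrr_sd_mean, config.lrr_sd_sd, size=n), 0.01, 0.29)
    outliers = rng.random(n) < config.lrr_sd_outlier_frac
    lrr[outliers] = rng.uniform(0.30, 0.45, size=outliers.sum())
    for (sid, dx), b, v in zip(groups, batches, lrr):
        manifest.append(
            SampleRecord(
                sample_id=sid, diagnosis=dx, ancestry=config.ancestry,
                batch=f"batch{int(b)+1}", lrr_sd=float(v),
            )
        )
    sz_ids = [s.sample_id for s in manifest if s.diagnosis is Diagnosis.SZ]
    bd_ids = [s.sample_id for s in manifest if s.diagnosis is Diagnosis.BD]
    hc_ids = [s.sample_id for s in manifest if s.diagnosis is Diagnosis.HC]

    calls_a: list[CNVCall] = []
    calls_b: list[CNVCall] = []
    truth_carriers: dict[str, set[str]] = {}
    truth_states: dict[str, dict[str, str]] = {}
    expected_dir: dict[str, str] = {}

    def emit_pair(sample_id: str, chrom: str, start: int, end: int, cn: int) -> None:
        """One caller-A call plus its jittered/dropped caller-B counterpart."""
        markers = _markers_for(end - start + 1, config.marker_density_bp)
        calls_a.append(
            CNVCall(sample_id, chrom, start, end, cn, markers, Caller.A)
        )
        if rng.random() < config.caller_b_dropout_prob:
            return
        if config.caller_b_jitter_sd_bp > 0:
            b_start = start + int(round(rng.normal(0, config.caller_b_jitter_sd_bp)))
            b_end = end + int(round(rng.normal(0, config.caller_b_jitter_sd_bp)))
            if b_end < b_start:
                b_start, b_end = b_end, b_start
            b_start, b_end = max(1, b_start), max(1, b_end)
        else:
            b_start, b_end = start, end
        calls_b.append(
            CNVCall(
                sample_id, chrom, b_start, b_end, cn,
                _markers_for(b_end - b_start + 1, config.marker_density_bp), Caller.B,
            )
        )

    # --- planted CNVRs ----------------------------------------------------
    for planted in config.planted_cnvrs:
        carriers: list[str] = []
        carriers += _draw_carriers(rng, sz_ids, planted.freq_sz, planted.n_sz)
        carriers += _draw_carriers(rng, bd_ids, planted.freq_bd, planted.n_bd)
        carriers += _draw_carriers(rng, hc_ids, planted.freq_control, planted.n_control)
        truth_carriers[planted.name] = set(carriers)
        states: dict[str, str] = {}
        for sid in carriers:
            if planted.state == "mixed":
                state = "del" if rng.random() < 0.5 else "dup"
            else:
                state = planted.state
            states[sid] = state
            cn = int(rng.choice((0, 1))) if state == "del" else int(rng.choice((3, 4)))
            start, end = _jitter_interval(
                rng, planted.start, planted.end, config.planted_jitter_frac
            )
            end = min(end, AUTOSOME_LENGTHS[planted.chrom])
            emit_pair(sid, planted.chrom, start, end, cn)
        truth_states[planted.name] = states
        case_f = max(planted.freq_sz, planted.freq_bd)
        if case_f > planted.freq_control:
            expected_dir[planted.name] = "case_enriched"
        elif case_f < planted.freq_control:
            expected_dir[planted.name] = "control_enriched"
        else:
            expected_dir[planted.name] = "none"

    # --- background calls -------------------------------------------------
    chrom_names = list(AUTOSOME_LENGTHS)
    chrom_lens = np.array([AUTOSOME_LENGTHS[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    planted_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in config.planted_cnvrs:
        pad = max(10_000, p.length // 5)
        planted_by_chrom.setdefault(p.chrom, []).append((p.start - pad, p.end + pad))

    rates = np.full(n, config.background_call_rate)
    if config.plant_excess_call_sample:
        rates[-1] *= 20.0  # last control sample becomes the call-count outlier
    n_calls = rng.poisson(rates)
    for (sid, _), k in zip(groups, n_calls):
        for _ in range(int(k)):
            for _attempt in range(20):
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                # size mixture spanning 1 kb - 1 Mb (log-uniform)
                length = int(10 ** rng.uniform(3, 6))
                start = int(rng.integers(1, AUTOSOME_LENGTHS[chrom] - length))
                end = start + length - 1
                blocked = any(
                    start <= e and end >= s
                    for s, e in planted_by_chrom.get(chrom, ())
                )
                if not blocked:
                    break
            else:
                continue
            cn = int(rng.choice((0, 1, 3, 4)))
            u = rng.random()
            if u < config.background_tiny_frac / 2:
                # violates the marker floor
                markers = int(rng.integers(1, 3))
                calls_a.append(CNVCall(sid, chrom, start, end, cn, markers, Caller.A))
                continue
            if u < config.background_tiny_frac:
                # violates the length floor
                end = start + int(rng.integers(100, 999))
                emit_pair(sid, chrom, start, end, cn)
                continue
            emit_pair(sid, chrom, start, end, cn)

    # --- reference regions and genes -------------------------------------
    dgv_regions: list[Region] = []
    for i, p in enumerate(config.planted_cnvrs):
        if p.in_dgv:
            pad = p.length // 5
            dgv_regions.append(
                Region(p.chrom, max(1, p.start - pad),
                       min(AUTOSOME_LENGTHS[p.chrom], p.end + pad), f"dgv_planted_{i}")
            )
    for i in range(400):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        length = int(10 ** rng.uniform(4, 6.3))
        start = int(rng.integers(1, AUTOSOME_LENGTHS[chrom] - length))
        dgv_regions.append(Region(chrom, start, start + length - 1, f"dgv_{i}"))

    gene_regions: list[Region] = []
    for i, p in enumerate(config.planted_cnvrs):
        mid = (p.start + p.end) // 2
        gene_regions.append(
            Region(p.chrom, max(1, mid - 5_000),
                   min(AUTOSOME_LENGTHS[p.chrom], mid + 5_000), f"GENE_{p.name}")
        )
    for i in range(300):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        length = int(rng.integers(5_000, 200_000))
        start = int(rng.integers(1, AUTOSOME_LENGTHS[chrom] - length))
        gene_regions.append(Region(chrom, start, start + length - 1, f"GENE{i:04d}"))

    # --- SNPs -------------------------------------------------------------
    sample_ids = [s.sample_id for s in manifest]
    id_index = {sid: i for i, sid in enumerate(sample_ids)}
    snp_rows: list[tuple[str, str, int, np.ndarray]] = []
    linked: dict[str, str] = {}
    for p in config.planted_cnvrs:
        if p.linked_snp_target_r2 is None:
            continue
        carrier_vec = np.zeros(n)
        for sid in truth_carriers[p.name]:
            carrier_vec[id_index[sid]] = 1.0
        snp = _linked_snp(rng, carrier_vec, p.linked_snp_target_r2)
        if p.linked_snp_beyond_window:
            # safely outside the 2 Mb window even after boundary jitter
            offset = int(rng.integers(2_500_000, 3_000_000))
        else:
            offset = int(rng.integers(10_000, 500_000))
        pos = min(p.end + offset, AUTOSOME_LENGTHS[p.chrom])
        snp_id = f"rs_{p.name}"
        snp_rows.append((snp_id, p.chrom, pos, snp))
        linked[p.name] = snp_id
    for i in range(config.n_unlinked_snps):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        pos = int(rng.integers(1, AUTOSOME_LENGTHS[chrom]))
        maf = rng.uniform(0.05, 0.5)
        snp_rows.append(
            (f"rs_bg{i:04d}", chrom, pos, rng.binomial(2, maf, size=n).astype(float))
        )
    snp_rows.sort(key=lambda t: (int(t[1]), t[2], t[0]))
    dosages = np.array([row[3] for row in snp_rows]) if snp_rows else np.empty((0, n))
    if len(snp_rows) and config.snp_missing_rate > 0:
        missing = rng.random(dosages.shape) < config.snp_missing_rate
        dosages[missing] = np.nan
    snps = SnpDosageMatrix(
        snp_ids=[r[0] for r in snp_rows],
        chroms=[r[1] for r in snp_rows],
        positions=np.array([r[2] for r in snp_rows], dtype=np.int64),
        sample_ids=sample_ids,
        dosages=dosages,
    )

    truth = SimTruth(
        carriers=truth_carriers,
        carrier_states=truth_states,
        expected_direction=expected_dir,
        linked_snps=linked,
    )
    return Bundle(
        manifest=manifest,
        calls_a=calls_a,
        calls_b=calls_b,
        dgv=RegionSet(dgv_regions),
        genes=RegionSet(gene_regions),
        snps=snps,
        truth=truth,
        config=config,
    )


def _linked_snp(
    rng: np.random.Generator, carrier: np.ndarray, target_r2: float
) -> np.ndarray:
    """A 0/1 dosage vector with r^2 to ``carrier`` close to ``target_r2``.

    Starts from a copy of the carrier indicator (r^2 = 1) and repeatedly
    swaps one concordant carrier 1 with one non-carrier 0, which preserves
    the allele frequency while walking the correlation down; stops at the
    first step at or below the target. With target 0 an independent draw of
    the same frequency is returned.
    """
    n = len(carrier)
    k = int(carrier.sum())
    if target_r2 <= 0 or k == 0 or k == n:
        snp = np.zeros(n)
        snp[rng.choice(n, size=max(k, 1), replace=False)] = 1.0
        return snp
    snp = carrier.copy()

    def r2() -> float:
        c = np.corrcoef(snp, carrier)[0, 1]
        return 0.0 if np.isnan(c) else c * c

    while r2() > target_r2:
        ones = np.flatnonzero((snp == 1) & (carrier == 1))
        zeros = np.flatnonzero((snp == 0) & (carrier == 0))
        if len(ones) == 0 or len(zeros) == 0:
            break
        snp[int(rng.choice(ones))] = 0.0
        snp[int(rng.choice(zeros))] = 1.0
    return snp


def fixture_small(seed: int = 12345) -> Bundle:
    """A small, hand-checkable bundle used throughout the unit tests.

    200 samples (60 SZ, 40 BD, 100 HC) in two batches, four planted CNVRs
    with exact carrier counts — notably CNVR "cnvr1" with exactly 4 SZ
    carriers and 1 control carrier — light background noise, and one linked
    SNP.
    """
    planted = [
        PlantedCNVR(
            name="cnvr1", chrom="22", start=17_000_000, end=20_000_000,
            state="del", n_sz=4, n_bd=0, n_control=1,
        ),
        PlantedCNVR(
            name="cnvr2_common_small", chrom="2", start=88_900_000, end=89_200_000,
            state="dup", freq_sz=0.30, freq_bd=0.10, freq_control=0.10,
            linked_snp_target_r2=0.5,
        ),
        PlantedCNVR(
            name="cnvr3_large", chrom="14", start=105_000_000, end=106_300_000,
            state="mixed", freq_sz=0.10, freq_bd=0.10, freq_control=0.02,
        ),
        PlantedCNVR(
            name="cnvr4_not_in_dgv", chrom="5", start=50_000_000, end=50_200_000,
            state="del", freq_sz=0.05, freq_bd=0.05, freq_control=0.05, in_dgv=False,
        ),
    ]
    config = SimConfig(
        n_cases_sz=60, n_cases_bd=40, n_controls=100, n_batches=2,
        background_call_rate=3.0, planted_cnvrs=planted,
        caller_b_jitter_sd_bp=200.0, caller_b_dropout_prob=0.03,
        lrr_sd_outlier_frac=0.02, n_unlinked_snps=20, seed=seed,
    )
    return simulate_cohort(config)


def write_bundle(bundle: Bundle, outdir) -> None:
    """Write a bundle in the exact file formats the readers consume."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_sample_manifest(bundle.manifest, outdir / "manifest.tsv")
    cio.write_cnv_calls(bundle.calls_a, outdir / "calls_callerA.tsv")
    cio.write_cnv_calls(bundle.calls_b, outdir / "calls_callerB.tsv")
    cio.write_region_set(bundle.dgv, outdir / "dgv.bed", dialect="bed0")
    cio.write_region_set(bundle.genes, outdir / "genes.bed", dialect="bed0")
    cio.write_snp_dosages(bundle.snps, outdir / "snps.tsv")
    cfg = asdict(bundle.config)
    cfg["ancestry"] = bundle.config.ancestry.value
    with open(outdir / "bundle.json", "w") as fh:
        json.dump({"config": cfg}, fh, indent=2, default=str)
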