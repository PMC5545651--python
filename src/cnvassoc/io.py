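"""Readers and writers for the pipeline's tabular and interval artifacts.

All tables are TSV with a header row; region sets are BED-like (a dialect
flag selects 0-based half-open vs 1-based inclusive input). Parsing is
strict: a malformed row raises ``ParseError`` naming the offending line.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    Ancestry,
    AssociationResult,
    Caller,
    CNVCall,
    CNVRegion,
    Diagnosis,
    Region,
    RegionSet,
    SampleRecord,
    SnpDosageMatrix,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_number", "n_markers"]
MANIFEST_COLUMNS = ["sample_id", "diagnosis", "ancestry", "batch", "lrr_sd"]


class ParseError(ValueError):
    """Raised when an input file fails validation; message names the line."""


def _check_header(got: Sequence[str], expected: Sequence[str], path: PathLike) -> None:
    if list(got[: len(expected)]) != list(expected):
        raise ParseError(
            f"{path}: expected header columns {expected}, got {list(got)}"
        )


def read_cnv_calls(path: PathLike, caller: Caller = Caller.A) -> list[CNVCall]:
    """Read a PennCNV-rawcnv-style call TSV into CNVCall records.

    Rows with copy number 2, non-positive marker counts or inverted
    coordinates are parse errors, not silent drops.
    """
    calls: list[CNVCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, CALL_COLUMNS, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                call = CNVCall(
                    sample_id=fields[0],
                    chrom=normalize_chrom(fields[1]),
                    start=int(fields[2]),
                    end=int(fields[3]),
                    copy_number=int(fields[4]),
                    n_markers=int(fields[5]),
                    caller=caller,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            calls.append(call)
    return calls


def write_cnv_calls(calls: Iterable[CNVCall], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                f"{c.copy_number}\t{c.n_markers}\n"
            )


def read_sample_manifest(path: PathLike) -> list[SampleRecord]:
    """Read the sample manifest; duplicate ids and unknown labels are errors."""
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, MANIFEST_COLUMNS, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            sid = fields[0]
            if sid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                rec = SampleRecord(
                    sample_id=sid,
                    diagnosis=Diagnosis(fields[1]),
                    ancestry=Ancestry(fields[2]),
                    batch=fields[3],
                    lrr_sd=float(fields[4]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if not records:
        warnings.warn(f"{path}: empty sample manifest", stacklevel=2)
    return records


def write_sample_manifest(samples: Iterable[SampleRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.diagnosis.value}\t{s.ancestry.value}\t"
                f"{s.batch}\t{s.lrr_sd:.6g}\n"
            )


def read_region_set(path: PathLike, dialect: str = "bed0") -> RegionSet:
    """Read a BED-like interval file into the internal 1-based inclusive form.

    dialect="bed0": standard BED, 0-based half-open -> (start+1, end).
    dialect="onebased": coordinates taken as-is.
    """
    if dialect not in ("bed0", "onebased"):
        raise ValueError(f"unknown dialect {dialect!r}")
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom = normalize_chrom(fields[0])
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if dialect == "bed0":
                start += 1
            if start > end:
                raise ParseError(
                    f"{path}:{lineno}: start > end after normalization ({start} > {end})"
                )
            label = fields[3] if len(fields) > 3 else ""
            regions.append(Region(chrom=chrom, start=start, end=end, label=label))
    return RegionSet(regions)


def write_region_set(regions: RegionSet, path: PathLike, dialect: str = "bed0") -> None:
    if dialect not in ("bed0", "onebased"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for r in regions:
            start = r.start - 1 if dialect == "bed0" else r.start
            fh.write(f"{r.chrom}\t{start}\t{r.end}\t{r.label}\n")


def read_snp_dosages(path: PathLike, sample_ids: Sequence[str] | None = None) -> SnpDosageMatrix:
    """Read a SNP dosage TSV (snp_id, chrom, pos, one column per sample).

    Missing dosages are encoded "NA". If ``sample_ids`` is given, the file's
    sample columns must match it exactly (manifest alignment check).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    file_samples = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    if sample_ids is not None and list(sample_ids) != file_samples:
        raise ParseError(
            f"{path}: dosage sample columns do not match the manifest "
            f"({len(file_samples)} vs {len(sample_ids)} samples)"
        )
    chroms = [normalize_chrom(c) for c in df["chrom"]]
    return SnpDosageMatrix(
        snp_ids=df["snp_id"].astype(str).tolist(),
        chroms=chroms,
        positions=df["pos"].to_numpy(dtype=np.int64),
        sample_ids=file_samples,
        dosages=df[file_samples].to_numpy(dtype=float),
    )


def write_snp_dosages(snps: SnpDosageMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\t" + "\t".join(snps.sample_ids) + "\n")
        for i, sid in enumerate(snps.snp_ids):
            row = snps.dosages[i]
            vals = "\t".join("NA" if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{sid}\t{snps.chroms[i]}\t{snps.positions[i]}\t{vals}\n")


def _fmt_p(p: float) -> str:
    """Scientific notation with 3 significant digits, e.g. 1.61E-05."""
    if np.isnan(p):
        return "NA"
    return f"{p:.2E}"


def write_cnvr_report(cnvrs: Sequence[CNVRegion], path: PathLike) -> None:
    """CNVR report: one row per region, sorted by (chrom, start)."""
    cols = [
        "cnvr_id", "chrom", "region_start", "region_end", "size_class",
        "n_calls", "carrier_count", "cnv_freq", "dup_freq", "del_freq",
        "freq_class", "singleton", "dgv_confirmed", "dgv_overlap_ratio", "genes",
    ]
    ordered = sorted(cnvrs, key=lambda r: (int(r.chrom), r.start, r.end, r.cnvr_id))
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in ordered:
            genes = ", ".join(r.genes) if r.genes else "Intergenic"
            fh.write(
                f"{r.cnvr_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                f"{r.size_class.value if r.size_class else 'NA'}\t"
                f"{len(r.member_calls)}\t{r.carrier_count}\t"
                f"{r.carrier_frequency:.5f}\t{r.dup_frequency:.5f}\t{r.del_frequency:.5f}\t"
                f"{r.freq_class.value if r.freq_class else 'NA'}\t"
                f"{int(r.singleton)}\t"
                f"{'NA' if r.dgv_confirmed is None else int(r.dgv_confirmed)}\t"
                f"{r.dgv_overlap_ratio:.5f}\t{genes}\n"
            )


def write_association_report(results: Sequence[AssociationResult], path: PathLike) -> None:
    """Association report: frequencies to 5 decimals, p in 3-sig-digit sci notation."""
    cols = [
        "cnvr_id", "test", "state_tested", "case_freq", "control_freq",
        "statistic", "p_value", "direction",
    ]
    ordered = sorted(results, key=lambda r: (r.cnvr_id, r.test, r.state_tested))
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in ordered:
            cf = "NA" if np.isnan(r.case_frequency) else f"{r.case_frequency:.5f}"
            hf = "NA" if np.isnan(r.control_frequency) else f"{r.control_frequency:.5f}"
            stat = "NA" if np.isnan(r.statistic) else f"{r.statistic:.6g}"
            fh.write(
                f"{r.cnvr_id}\t{r.test}\t{r.state_tested}\t{cf}\t{hf}\t"
                f"{stat}\t{_fmt_p(r.p_value)}\t{r.direction.value}\n"
            )
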