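"""How well are common CNVRs tagged by nearby SNPs?

For each common CNVR, the squared Pearson correlation (r^2) between the
per-sample trichotomous CNVR dosage (-1/0/+1) and each same-chromosome SNP
dosage is computed, with missing SNP genotypes dropped pairwise. SNPs
within a window (default 2 Mb) of the CNVR boundary are "neighbors"; the
rest of the chromosome is "distant". A CNVR is tagged when its best
neighbor r^2 exceeds 0.2; otherwise, if some distant SNP correlates better
than every neighbor, tagging is attributed to long-range structure
(distant_better); otherwise the CNVR is untagged.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .association import categorize_states
from .types import CNVRegion, SampleRecord, SnpDosageMatrix, TaggingResult

TAG_R2 = 0.2
WINDOW_BP = 2_000_000


def cnvr_dosage(cnvr: CNVRegion, samples: Sequence[SampleRecord]) -> np.ndarray:
    """Per-sample coded state (-1/0/+1) aligned to manifest order."""
    states = categorize_states(cnvr, samples)
    return np.array([int(s.state) for s in states], dtype=float)


def pairwise_r2(dosage: np.ndarray, snp: np.ndarray) -> float:
    """Squared Pearson correlation with pairwise-complete observations.

    NaN if either vector is constant on the complete pairs (r^2 undefined).
    """
    mask = ~np.isnan(snp) & ~np.isnan(dosage)
    x, y = dosage[mask], snp[mask]
    if len(x) < 2 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _distance_to_region(pos: int, start: int, end: int) -> int:
    """bp from a point to the nearest CNVR boundary; 0 inside the region."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def tagging_scan(
    cnvr: CNVRegion,
    dosage: np.ndarray,
    snps: SnpDosageMatrix,
    window_bp: int = WINDOW_BP,
    tag_r2: float = TAG_R2,
) -> TaggingResult:
    """Best neighbor / distant SNP r^2 for one CNVR and its classification.

    Classification precedence: tagged (neighbor r^2 > tag_r2), else
    distant_better (best distant r^2 > best neighbor r^2), else untagged.
    A CNVR monomorphic among analyzed samples is flagged instead.
    """
    if np.all(dosage == dosage[0]):
        return TaggingResult(
            cnvr_id=cnvr.cnvr_id,
            best_neighbor_r2=float("nan"),
            best_neighbor_snp=None,
            best_neighbor_distance=None,
            best_distant_r2=float("nan"),
            best_distant_snp=None,
            classification="monomorphic",
        )
    idx = snps.on_chrom(cnvr.chrom)
    best_nb, best_nb_snp, best_nb_dist = 0.0, None, None
    best_far, best_far_snp = 0.0, None
    for i in idx:
        r2 = pairwise_r2(dosage, snps.dosages[i])
        if np.isnan(r2):
            continue
        dist = _distance_to_region(int(snps.positions[i]), cnvr.start, cnvr.end)
        if dist <= window_bp:
            if r2 > best_nb:
                best_nb, best_nb_snp, best_nb_dist = r2, snps.snp_ids[i], dist
        else:
            if r2 > best_far:
                best_far, best_far_snp = r2, snps.snp_ids[i]

    if best_nb > tag_r2:
        classification = "tagged"
    elif best_far > best_nb:
        classification = "distant_better"
    else:
        classification = "untagged"
    return TaggingResult(
        cnvr_id=cnvr.cnvr_id,
        best_neighbor_r2=best_nb,
        best_neighbor_snp=best_nb_snp,
        best_neighbor_distance=best_nb_dist,
        best_distant_r2=best_far,
        best_distant_snp=best_far_snp,
        classification=classification,
    )


def write_tagging_report(results: Sequence[TaggingResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cnvr_id\tbest_neighbor_snp\tbest_neighbor_r2\tbest_neighbor_distance\t"
            "best_distant_snp\tbest_distant_r2\tclassification\n"
        )
        for r in sorted(results, key=lambda t: t.cnvr_id):
            fh.write(
                f"{r.cnvr_id}\t{r.best_neighbor_snp or 'NA'}\t"
                f"{'NA' if np.isnan(r.best_neighbor_r2) else f'{r.best_neighbor_r2:.5f}'}\t"
                f"{r.best_neighbor_distance if r.best_neighbor_distance is not None else 'NA'}\t"
                f"{r.best_distant_snp or 'NA'}\t"
                f"{'NA' if np.isnan(r.best_distant_r2) else f'{r.best_distant_r2:.5f}'}\t"
                f"{r.classification}\n"
            )
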