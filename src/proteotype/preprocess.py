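"""Probe QC, median signal normalization, log2 transform and the
storage-time artifact scan.

Median signal normalization rescales each sample so the median of its
probe-wise ratios to a per-probe reference (the across-sample median) is 1.
The scaling is iterated to a fixed point so the operation is idempotent:
after one rescaling the per-probe medians move, so a single pass leaves
residual factors slightly off 1; iteration converges in a handful of steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ClinicalTable, DataError, ProbeAnnotation, ProteomeMatrix


@dataclass
class QCReport:
    n_probes_in: int
    n_failed_qc: int
    n_retained: int
    failed_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_probes_in != self.n_failed_qc + self.n_retained:
            raise ValueError("QC counts are inconsistent")

    def to_dict(self) -> dict:
        return {
            "n_probes_in": self.n_probes_in,
            "n_failed_qc": self.n_failed_qc,
            "n_retained": self.n_retained,
            "failed_probes": list(self.failed_probes),
        }


def qc_filter(
    matrix: ProteomeMatrix, annotation: ProbeAnnotation
) -> tuple[ProteomeMatrix, ProbeAnnotation, QCReport]:
    """Drop probes flagged qc_pass=False; probe and subject order preserved."""
    missing = [p for p in matrix.probe_ids if p not in annotation.table.index]
    if missing:
        raise DataError(f"probes absent from annotation: {missing}")
    qc_pass = annotation.table.loc[matrix.probe_ids, "qc_pass"]
    keep = [p for p in matrix.probe_ids if qc_pass[p]]
    failed = [p for p in matrix.probe_ids if not qc_pass[p]]
    if not keep:
        raise DataError("all probes fail QC")
    report = QCReport(len(matrix.probe_ids), len(failed), len(keep), failed)
    filtered = ProteomeMatrix(matrix.values.loc[keep], matrix.log_transformed)
    ann = ProbeAnnotation(annotation.table.loc[keep])
    return filtered, ann, report


def median_normalize(
    matrix: ProteomeMatrix, max_iter: int = 1000, tol: float = 1e-13
) -> tuple[ProteomeMatrix, pd.Series]:
    """Median signal normalization of a raw RFU matrix.

    Returns the normalized matrix and the multiplicative per-sample scale
    factors applied (normalized sample = original sample x factor, so a
    sample inflated 2x gets factor 0.5; an already-normalized matrix
    yields factors of 1).
    """
    if matrix.log_transformed:
        raise DataError("median normalization expects raw (non-log) RFU")
    values = matrix.values.to_numpy(dtype=float).copy()
    if (values <= 0).any():
        raise DataError("median normalization requires strictly positive RFU")
    total = np.ones(values.shape[1])
    prev_d = prev_norm = None
    for _ in range(max_iter):
        ref = np.median(values, axis=1, keepdims=True)  # per-probe reference
        factors = np.median(values / ref, axis=0)
        values /= factors
        total *= factors
        if np.max(np.abs(factors - 1.0)) < tol:
            break
        # geometric-series extrapolation: when successive corrections decay
        # at a stable rate in a stable direction, jump to the series limit
        d = np.log(factors)
        nd = float(np.linalg.norm(d))
        if prev_d is not None and prev_norm > 0 and nd > 0:
            rho = nd / prev_norm
            cos = float(d @ prev_d) / (nd * prev_norm)
            if 0.5 < rho < 0.999 and cos > 0.9:
                jump = np.exp(d * rho / (1.0 - rho))
                values /= jump
                total *= jump
                prev_d = prev_norm = None
                continue
        prev_d, prev_norm = d, nd
    # anchor the global scale: the median cumulative correction is 1, so
    # rescaling a minority of samples leaves the majority untouched exactly
    anchor = np.median(total)
    values *= anchor
    total /= anchor
    out = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    return ProteomeMatrix(out), pd.Series(
        1.0 / total, index=matrix.values.columns, name="scale_factor"
    )


def log2_transform(matrix: ProteomeMatrix) -> ProteomeMatrix:
    if matrix.log_transformed:
        raise DataError("matrix is already log2 transformed")
    return ProteomeMatrix(np.log2(matrix.values), log_transformed=True)


def inverse_log2(matrix: ProteomeMatrix) -> ProteomeMatrix:
    if not matrix.log_transformed:
        raise DataError("matrix is not log2 transformed")
    return ProteomeMatrix(2.0 ** matrix.values, log_transformed=False)


@dataclass
class StorageScanResult:
    """Per-disease storage-time correlation scan.

    ``per_disease`` maps disease -> DataFrame (probe, rho, p); counts are
    taken at unadjusted p <= alpha, and ``overlap`` is the intersection of
    the per-disease significant probe sets.
    """

    per_disease: dict[str, pd.DataFrame]
    significant: dict[str, list[str]]
    alpha: float

    @property
    def counts(self) -> dict[str, int]:
        return {d: len(v) for d, v in self.significant.items()}

    @property
    def overlap(self) -> list[str]:
        sets = [set(v) for v in self.significant.values()]
        if not sets:
            return []
        return sorted(set.intersection(*sets))


def storage_time_scan(
    matrix: ProteomeMatrix, clinical: ClinicalTable, alpha: float = 0.05
) -> StorageScanResult:
    """Spearman correlation of every probe with sample storage time, within
    each disease separately; reports counts significant at unadjusted p
    <= alpha and the overlap between diseases."""
    if "storage_days" not in clinical.subjects.columns:
        raise DataError("clinical table has no storage_days column")
    per_disease: dict[str, pd.DataFrame] = {}
    significant: dict[str, list[str]] = {}
    X = matrix.values
    for disease, grp in clinical.subjects.groupby("disease", sort=False):
        sids = [s for s in grp.index if s in X.columns]
        if not sids:
            continue
        storage = grp.loc[sids, "storage_days"].to_numpy(dtype=float)
        if np.isnan(storage).any():
            raise DataError(f"storage_days missing for some {disease} subjects")
        if np.ptp(storage) == 0:
            raise DataError("degenerate covariate: storage_days is constant")
        sub = X[sids].to_numpy(dtype=float)
        rho, p = _spearman_vs_vector(sub, storage)
        df = pd.DataFrame({"rho": rho, "p": p}, index=matrix.probe_ids)
        per_disease[disease] = df
        significant[disease] = list(df.index[df["p"] <= alpha])
    return StorageScanResult(per_disease, significant, alpha)


def _spearman_vs_vector(rows: np.ndarray, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p (t approximation) of each row of
    ``rows`` against ``vec``; vectorized via rank transform."""
    n = len(vec)
    rv = stats.rankdata(vec)
    rr = stats.rankdata(rows, axis=1)
    rv_c = rv - rv.mean()
    rr_c = rr - rr.mean(axis=1, keepdims=True)
    denom = np.sqrt((rr_c**2).sum(axis=1) * (rv_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rr_c @ rv_c) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 1.0, np.where(np.isinf(t), 0.0, p))
    rho = np.where(np.isnan(rho), 0.0, rho)
    return rho, p
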