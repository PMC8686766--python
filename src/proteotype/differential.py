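"""Two-group differential abundance on log2 RFU with Benjamini-Hochberg
control, covariate-adjusted variants, confounder scans, and cross-platform
validation.

The per-probe test is Welch's two-sample t on log2 values; with covariates
a per-probe ordinary linear model ``log2RFU ~ group + covariates`` is fit
and the group coefficient tested.  Constant probes get p = 1 with a flag
(never dropped) so probe universes stay stable for enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ClinicalTable, DataError, ProteomeMatrix
from .preprocess import _spearman_vs_vector


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order
    preserved, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    """Per-probe two-group comparison.

    ``table`` columns: mean_a, mean_b, diff (a - b), stat, p, q, constant.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    covariates: tuple[str, ...] = ()

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q"] <= alpha])


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t across rows; constant rows -> (nan, nan)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    denom = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom)
        df = denom**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return t, p


def differential_abundance(
    matrix: ProteomeMatrix,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> DifferentialResult:
    """Per-probe two-group differential abundance with BH adjustment.

    ``labels`` maps subject id -> group label (exactly two levels).  With
    ``covariates`` (subjects x covariates, complete for included subjects)
    the group effect is tested in an OLS model per probe.
    """
    if not matrix.log_transformed:
        raise DataError("differential abundance expects log2-transformed values")
    labels = labels.loc[[s for s in matrix.subject_ids if s in labels.index]]
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise DataError(f"labels must have exactly two levels, got {levels}")
    ga, gb = levels
    a_ids = list(labels.index[labels == ga])
    b_ids = list(labels.index[labels == gb])
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise DataError("each group needs at least 2 subjects")
    X = matrix.values
    A = X[a_ids].to_numpy(dtype=float)
    B = X[b_ids].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    constant = np.concatenate([A, B], axis=1).std(axis=1) == 0

    cov_names: tuple[str, ...] = ()
    if covariates is None:
        t, p = _welch_rows(A, B)
    else:
        cov = covariates.loc[a_ids + b_ids]
        if cov.isna().any().any():
            raise DataError("covariates must be complete for included subjects")
        cov_names = tuple(cov.columns)
        group = np.array([1.0] * len(a_ids) + [0.0] * len(b_ids))
        design = np.column_stack(
            [np.ones(len(group)), group, cov.to_numpy(dtype=float)]
        )
        Y = np.concatenate([A, B], axis=1).T  # subjects x probes
        t, p = _ols_coef_test(design, Y, coef_index=1)

    p = np.where(constant | np.isnan(p), 1.0, p)
    t = np.where(constant, 0.0, t)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": mean_a - mean_b,
            "stat": t,
            "p": p,
            "q": q,
            "constant": constant,
        },
        index=matrix.probe_ids,
    )
    return DifferentialResult(table, ga, gb, len(a_ids), len(b_ids), cov_names)


def _ols_coef_test(design: np.ndarray, Y: np.ndarray, coef_index: int):
    """t test of one coefficient of a shared OLS design fit to every column
    of Y at once."""
    n, k = design.shape
    if n <= k:
        raise DataError("more model parameters than subjects")
    pinv = np.linalg.pinv(design)
    beta = pinv @ Y  # k x probes
    resid = Y - design @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[coef_index] / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return t, p


@dataclass
class ConfounderScanResult:
    covariate: str
    n_associated: int
    associated_probes: list[str]
    overlap: int
    expected_overlap: float
    enrichment_p: float


def confounder_scan(
    matrix: ProteomeMatrix,
    clinical: ClinicalTable,
    covariate: str,
    selected_probes,
    alpha: float = 0.05,
) -> ConfounderScanResult:
    """Count probes associated with a clinical covariate and test whether
    those probes are over-represented in ``selected_probes`` (one-sided
    hypergeometric against the whole probe universe).

    Continuous covariates use Spearman correlation; binary covariates
    (exactly two observed levels) use Welch's t.
    """
    if covariate not in clinical.subjects.columns:
        raise DataError(f"unknown covariate {covariate!r}")
    selected = set(selected_probes)
    unknown = selected - set(matrix.probe_ids)
    if unknown:
        raise DataError(f"selected probes outside the matrix: {sorted(unknown)}")
    col = clinical.subjects[covariate]
    sids = [s for s in matrix.subject_ids if s in col.index and not pd.isna(col[s])]
    vals = col.loc[sids]
    sub = matrix.values[sids].to_numpy(dtype=float)
    uniq = pd.unique(vals)
    if len(uniq) < 2:
        raise DataError(f"degenerate covariate {covariate!r}")
    if len(uniq) == 2:
        mask = (vals == uniq[0]).to_numpy()
        _, p = _welch_rows(sub[:, mask], sub[:, ~mask])
        p = np.where(np.isnan(p), 1.0, p)
    else:
        _, p = _spearman_vs_vector(sub, vals.to_numpy(dtype=float))
    associated = [pid for pid, pv in zip(matrix.probe_ids, p) if pv <= alpha]
    overlap = len(selected & set(associated))
    M = len(matrix.probe_ids)
    expected = len(associated) * len(selected) / M if M else 0.0
    # one-sided upper tail: P(overlap >= observed)
    enrich_p = float(stats.hypergeom.sf(overlap - 1, M, len(associated), len(selected))) if associated else 1.0
    return ConfounderScanResult(
        covariate, len(associated), associated, overlap, expected, min(enrich_p, 1.0)
    )


@dataclass
class CrossPlatformResult:
    table: pd.DataFrame  # analyte, rho, p, n
    n_significant: int
    p_threshold: float
    skipped: list[str]


def cross_platform_validation(
    platform_a: pd.DataFrame,
    platform_b: pd.DataFrame,
    pairs: list[tuple[str, str]],
    p_threshold: float = 0.01,
) -> CrossPlatformResult:
    """Spearman correlation per analyte between two measurement platforms.

    ``pairs`` lists (row in platform_a, row in platform_b); subjects are
    matched on shared column names.  Analytes with fewer than 4 complete
    pairs are skipped with a warning.
    """
    rows, skipped = [], []
    for name_a, name_b in pairs:
        shared = [c for c in platform_a.columns if c in platform_b.columns]
        x = platform_a.loc[name_a, shared].astype(float)
        y = platform_b.loc[name_b, shared].astype(float)
        ok = ~(x.isna() | y.isna())
        x, y = x[ok], y[ok]
        if len(x) < 4:
            warnings.warn(f"analyte {name_a!r}: fewer than 4 paired observations, skipped")
            skipped.append(name_a)
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"analyte": name_a, "rho": float(rho), "p": float(p), "n": len(x)})
    table = pd.DataFrame(rows).set_index("analyte") if rows else pd.DataFrame(
        columns=["rho", "p", "n"]
    )
    n_sig = int((table["p"] <= p_threshold).sum()) if len(table) else 0
    return CrossPlatformResult(table, n_sig, p_threshold, skipped)
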