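"""Clinical statistics: group comparison tests (from raw data or printed
summary statistics), Fisher's exact test, Kaplan-Meier / log-rank survival,
and annual-change slope estimation.

Annual change is estimated by a per-subject ordinary least squares slope of
the variable on visit time (a documented simplification of a mixed-effects
model: unbiased for balanced visit schedules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .data import ClinicalTable, DataError


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p: float
    df: float | None = None
    summaries: dict = field(default_factory=dict)
    degenerate: bool = False


def _as_summary(x) -> tuple[int, float, float]:
    """Accept raw values or an (n, mean, sd) triple."""
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        n, mean, sd = int(x[0]), float(x[1]), float(x[2])
    else:
        arr = np.asarray(x, dtype=float)
        n, mean, sd = len(arr), float(arr.mean()), float(arr.std(ddof=1))
    if n < 2:
        raise DataError("each group needs n >= 2")
    return n, mean, sd


def two_sample_t(a, b, variant: str = "pooled") -> GroupTestResult:
    """Two-sample t test from raw values or (n, mean, sd) summaries.

    ``variant='pooled'`` is classical Student's t (the convention of the
    clinical tables this mirrors); ``'welch'`` drops the equal-variance
    assumption.
    """
    (na, ma, sa), (nb, mb, sb) = _as_summary(a), _as_summary(b)
    equal_var = variant == "pooled"
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    t, p = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=equal_var)
    if equal_var:
        df = na + nb - 2.0
    else:
        va, vb = sa**2 / na, sb**2 / nb
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return GroupTestResult(
        f"t ({variant})",
        float(t),
        float(p),
        float(df),
        {"a": (na, ma, sa), "b": (nb, mb, sb)},
    )


def fisher_exact(table) -> GroupTestResult:
    """Two-sided Fisher's exact test on a 2x2 count table (p = sum of
    fixed-margin tables with probability <= observed)."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.allclose(tab, tab.astype(int)):
        raise DataError("fisher_exact needs a 2x2 table of non-negative integers")
    tab = tab.astype(int)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return GroupTestResult("fisher", float("nan"), 1.0, None, degenerate=True)
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return GroupTestResult("fisher", float(odds), float(p))


def group_compare(values, groups, test: str) -> GroupTestResult:
    """Classical multi-group comparison: 'anova', 'mann_whitney' (2 groups;
    exact when both n <= 20 and no ties, normal approximation with tie
    correction otherwise) or 'kruskal_wallis'."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise DataError("need at least two groups")
    if any(len(s) == 0 for s in samples):
        raise DataError("each group must be non-empty")
    if test == "anova":
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = stats.f_oneway(*samples)
        if np.isnan(f):  # all values identical
            f, p = 0.0, 1.0
        return GroupTestResult("anova", float(f), float(p), float(len(samples) - 1))
    if test == "mann_whitney":
        if len(samples) != 2:
            raise DataError("mann_whitney requires exactly two groups")
        method = "exact" if max(len(s) for s in samples) <= 20 else "asymptotic"
        u, p = stats.mannwhitneyu(
            samples[0],
            samples[1],
            alternative="two-sided",
            method=method,
            use_continuity=False,
        )
        return GroupTestResult("mann_whitney", float(u), float(p))
    if test == "kruskal_wallis":
        h, p = stats.kruskal(*samples)
        return GroupTestResult("kruskal_wallis", float(h), float(p), float(len(samples) - 1))
    raise ValueError(f"unknown test {test!r}")


@dataclass
class SurvivalResult:
    curves: dict[str, pd.DataFrame]  # group -> time, survival, at_risk
    chi2: float
    p: float
    df: int


def km_logrank(times, events, groups) -> SurvivalResult:
    """Kaplan-Meier product-limit curves per group and the log-rank test
    (ties aggregated at event times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise DataError("event times must be non-negative")
    if len(pd.unique(groups)) < 2:
        raise DataError("log-rank requires at least two non-empty groups")
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise DataError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        curves[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    res = multivariate_logrank_test(times, groups, events)
    return SurvivalResult(
        curves, float(res.test_statistic), float(res.p_value), int(res.degrees_of_freedom)
    )


@dataclass
class SlopeEstimate:
    per_subject: pd.DataFrame  # subject: slope, intercept, n_visits
    excluded: list[str]
    group_stats: pd.DataFrame | None = None  # group: mean_slope, sd_slope, n


def annual_change(
    clinical: ClinicalTable,
    variable: str = "kco",
    groups: pd.Series | None = None,
) -> SlopeEstimate:
    """Per-subject OLS slope of a visit variable on visit time (years).

    Subjects with fewer than 2 visits are excluded and listed.  With a
    ``groups`` series (subject -> group) per-group mean/SD of the slopes is
    reported.
    """
    if variable not in ("kco", "fev1"):
        raise DataError(f"unknown visit variable {variable!r}")
    rows, excluded = [], []
    visits = clinical.visits.dropna(subset=["time_years", variable])
    for sid in clinical.subject_ids:
        grp = visits[visits["subject_id"] == sid]
        if len(grp) < 2:
            excluded.append(sid)
            continue
        t = grp["time_years"].to_numpy(dtype=float)
        y = grp[variable].to_numpy(dtype=float)
        slope, intercept = np.polyfit(t, y, 1)
        rows.append(
            {"subject_id": sid, "slope": float(slope), "intercept": float(intercept), "n_visits": len(grp)}
        )
    if not rows:
        raise DataError("no subject has at least 2 visits")
    per_subject = pd.DataFrame(rows).set_index("subject_id")
    group_stats = None
    if groups is not None:
        joined = per_subject.join(groups.rename("group"), how="inner")
        group_stats = (
            joined.groupby("group")["slope"]
            .agg(mean_slope="mean", sd_slope=lambda s: s.std(ddof=1), n="count")
        )
    return SlopeEstimate(per_subject, excluded, group_stats)
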