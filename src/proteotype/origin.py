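"""Tissue/cell-of-origin z-score analysis against an expression atlas, and
per-probe association of abundance with continuous clinical traits.

The atlas is z-scored within each tissue across genes, so each tissue's
profile is on a common scale regardless of absolute expression; a gene
group's putative source tissues are those where the group's z-scores sit
significantly above the background genes (one-sided Mann-Whitney, BH
across tissues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, TissueExpression
from .differential import bh_adjust
from .data import ProteomeMatrix


@dataclass
class OriginProfile:
    """Per-tissue comparison of group vs background z-scores."""

    table: pd.DataFrame  # tissue, group_mean_z, background_mean_z, diff, p, q
    group_genes: list[str]
    background_genes: list[str]

    def flagged(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q"] <= alpha])


def zscore_by_tissue(atlas: TissueExpression) -> pd.DataFrame:
    """z-score expression within each tissue (column) across genes."""
    X = atlas.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return X.sub(mu, axis=1).div(sd.replace(0.0, 1.0), axis=1)


def tissue_origin_zscores(
    atlas: TissueExpression, group_genes, background_genes=None
) -> OriginProfile:
    """Compare a gene group's within-tissue z-scores to background genes,
    per tissue (one-sided Mann-Whitney, group > background; BH across
    tissues)."""
    group = [g for g in group_genes]
    missing = [g for g in group if g not in atlas.values.index]
    if missing:
        raise DataError(f"group genes absent from atlas: {missing}")
    if background_genes is None:
        background = [g for g in atlas.genes if g not in set(group)]
    else:
        background = [g for g in background_genes]
        if set(background) & set(group):
            raise DataError("background genes must be disjoint from the group")
        missing_b = [g for g in background if g not in atlas.values.index]
        if missing_b:
            raise DataError(f"background genes absent from atlas: {missing_b}")
    if not group or not background:
        raise DataError("group and background must be non-empty")
    Z = zscore_by_tissue(atlas)
    gz = Z.loc[group]
    bz = Z.loc[background]
    rows = []
    for tissue in atlas.tissues:
        u, p = stats.mannwhitneyu(gz[tissue], bz[tissue], alternative="greater")
        rows.append(
            {
                "tissue": tissue,
                "group_mean_z": float(gz[tissue].mean()),
                "background_mean_z": float(bz[tissue].mean()),
                "diff": float(gz[tissue].mean() - bz[tissue].mean()),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows).set_index("tissue")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return OriginProfile(table, group, background)


@dataclass
class TraitAssociation:
    """Per-probe simple linear regression of a trait on log2 abundance."""

    table: pd.DataFrame  # probe: r, slope, p, n
    trait: str

    def strongest(self) -> str:
        return self.table["p"].idxmin()


def trait_association(matrix: ProteomeMatrix, trait: pd.Series, name: str | None = None) -> TraitAssociation:
    """Correlation r, regression slope (trait per log2 unit) and two-sided
    p for every probe against a continuous per-subject trait."""
    sids = [s for s in matrix.subject_ids if s in trait.index and not pd.isna(trait[s])]
    if len(sids) < 4:
        raise DataError("trait present for fewer than 4 subjects")
    y = trait.loc[sids].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DataError("degenerate trait: constant values")
    X = matrix.values[sids].to_numpy(dtype=float)
    n = len(y)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=1)
    syy = (yc**2).sum()
    sxy = xc @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
        slope = sxy / sxx
    r = np.clip(np.where(np.isnan(r), 0.0, r), -1.0, 1.0)
    slope = np.where(np.isnan(slope), 0.0, slope)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 1.0, p)
    p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]
    table = pd.DataFrame(
        {"r": r, "slope": slope, "p": p, "n": n}, index=matrix.probe_ids
    )
    return TraitAssociation(table, name or (trait.name or "trait"))


@dataclass
class AssociationComparison:
    abs_r: dict[str, np.ndarray]
    p_values: dict[tuple[str, str], float]


def compare_association_distributions(
    assoc: TraitAssociation, group_a, group_b, other=None
) -> AssociationComparison:
    """Compare |r| distributions between probe groups: one-sided
    Mann-Whitney that group_a |r| stochastically dominates each comparator."""
    groups = {"a": list(group_a), "b": list(group_b)}
    if other is not None:
        groups["other"] = list(other)
    for name, g in groups.items():
        if not g:
            raise DataError(f"group {name!r} is empty")
    seen = [set(g) for g in groups.values()]
    for i in range(len(seen)):
        for j in range(i + 1, len(seen)):
            if seen[i] & seen[j]:
                raise DataError("probe groups must be disjoint")
    abs_r = {
        name: np.abs(assoc.table.loc[g, "r"].to_numpy()) for name, g in groups.items()
    }
    p_values = {}
    for comp in [k for k in groups if k != "a"]:
        _, p = stats.mannwhitneyu(abs_r["a"], abs_r[comp], alternative="greater")
        p_values[("a", comp)] = float(p)
    return AssociationComparison(abs_r, p_values)
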