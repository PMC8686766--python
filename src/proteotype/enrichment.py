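"""Protein-set enrichment statistics and overlap analyses.

Two complementary set scores are computed against a per-probe statistic
(e.g. the signed t from a disease contrast):

* a *directional* normalized enrichment score (NES): probes are ranked by
  the statistic and a weighted Kolmogorov-Smirnov running sum is walked
  down the ranking (hits weighted by |stat|^exponent, misses by a uniform
  decrement); the signed extremum is the enrichment score ES, normalized
  by the mean |ES| of a random-set permutation null of matching sign;

* a *non-directional* earth mover's distance (EMD) score: the 1-D
  Wasserstein-1 distance between in-set and out-of-set statistic
  distributions, reported as observed / mean(random-set null).

Both nulls permute probe-set membership (R random sets of identical size),
with permutation p = (1 + #{null at least as extreme}) / (R + 1).

Enrichment networks connect enriched sets sharing more than a fraction of
members (denominator: the smaller set); hypergeometric over-representation,
cellular-location composition and marker correlation density support the
exosome and cell-of-origin analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CELLULAR_LOCATIONS,
    DataError,
    ProbeAnnotation,
    ProteinSetCollection,
    ProteomeMatrix,
)
from .differential import bh_adjust


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the permutation settings used.

    Directional runs fill columns size, es, nes, p, q; EMD runs fill size,
    emd_obs, emd_null_mean, emd_ratio, p, q.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int
    excluded: list[str] = field(default_factory=list)

    def significant(self, alpha: float) -> list[str]:
        return list(self.table.index[self.table["p"] <= alpha])


def _set_membership(
    stats_index, sets: ProteinSetCollection, symbol_map: dict | None
) -> dict[str, np.ndarray]:
    """Boolean membership vector per set over the probes carrying stats.

    A probe belongs to a set if any of its protein symbols is a member;
    without a symbol map the probe id itself is the symbol.
    """
    probes = list(stats_index)
    if symbol_map is None:
        symbols = [(p,) for p in probes]
    else:
        symbols = [tuple(symbol_map.get(p, (p,))) for p in probes]
    out = {}
    for name in sets.names():
        members = sets[name]
        out[name] = np.array([any(s in members for s in syms) for syms in symbols])
    return out


def _running_sum_es(order_stats: np.ndarray, member: np.ndarray, exponent: float) -> float:
    """Signed extremum of the weighted KS running sum over ranked probes."""
    n_hit = int(member.sum())
    n = len(order_stats)
    absw = np.abs(order_stats) ** exponent
    hit_total = absw[member].sum()
    if hit_total == 0:
        hit_steps = member / n_hit
    else:
        hit_steps = np.where(member, absw / hit_total, 0.0)
    miss = 1.0 / (n - n_hit)
    running = np.cumsum(hit_steps - np.where(member, 0.0, miss))
    return float(running[np.argmax(np.abs(running))])


def _null_es_matrix(
    order_stats: np.ndarray, set_size: int, n_perm: int, exponent: float, rng
) -> np.ndarray:
    """ES of n_perm random memberships of the given size (vectorized)."""
    n = len(order_stats)
    member = np.zeros((n_perm, n), dtype=bool)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :set_size]
    np.put_along_axis(member, idx, True, axis=1)
    absw = np.abs(order_stats) ** exponent
    hit_total = (member * absw).sum(axis=1, keepdims=True)
    zero = hit_total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        steps = np.where(member, absw / hit_total, -1.0 / (n - set_size))
    if zero.any():
        flat = np.where(member, 1.0 / set_size, -1.0 / (n - set_size))
        steps = np.where(zero, flat, steps)
    running = np.cumsum(steps, axis=1)
    pick = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), pick]


def directional_enrichment(
    probe_stats: pd.Series,
    sets: ProteinSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 3,
    symbol_map: dict | None = None,
) -> EnrichmentResult:
    """Directional (GSEA-style) enrichment with a random-set null.

    NES = ES / mean(|null ES| of matching sign);
    p = (1 + #{matching-sign null with |ES_null| >= |ES|}) / (R + 1).
    """
    if n_perm < 10:
        raise DataError("n_perm must be at least 10")
    vals = probe_stats.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise DataError("probe statistics must be finite")
    order = np.lexsort((probe_stats.index.astype(str), -vals))
    order_stats = vals[order]
    membership = _set_membership(probe_stats.index, sets, symbol_map)
    rng = np.random.default_rng(seed)
    rows, excluded, null_cache = [], [], {}
    for name in sets.names():
        member = membership[name][order]
        n_hit = int(member.sum())
        if n_hit < min_size or n_hit == len(member):
            warnings.warn(f"set {name!r} excluded (size {n_hit} among probes)")
            excluded.append(name)
            continue
        es = _running_sum_es(order_stats, member, weight_exponent)
        if n_hit not in null_cache:
            null_cache[n_hit] = _null_es_matrix(
                order_stats, n_hit, n_perm, weight_exponent, rng
            )
        null = null_cache[n_hit]
        same_sign = null * np.sign(es) > 0 if es != 0 else np.ones_like(null, bool)
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        extreme = same_sign & (np.abs(null) >= abs(es))
        p = (1 + int(extreme.sum())) / (n_perm + 1)
        rows.append({"set": name, "size": n_hit, "es": es, "nes": nes, "p": p})
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = []
    return EnrichmentResult(table, n_perm, seed, excluded)


def emd_enrichment(
    probe_stats: pd.Series,
    sets: ProteinSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
    symbol_map: dict | None = None,
) -> EnrichmentResult:
    """Non-directional enrichment: 1-D Wasserstein-1 (earth mover's)
    distance between in-set and out-of-set statistics, normalized as
    observed / mean(random-set null); p = (1 + #{null >= observed}) / (R+1).
    """
    if n_perm < 10:
        raise DataError("n_perm must be at least 10")
    vals = probe_stats.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise DataError("probe statistics must be finite")
    membership = _set_membership(probe_stats.index, sets, symbol_map)
    rng = np.random.default_rng(seed)
    n = len(vals)
    rows, excluded, null_cache = [], [], {}
    for name in sets.names():
        member = membership[name]
        n_hit = int(member.sum())
        if n_hit < min_size or n_hit == n:
            warnings.warn(f"set {name!r} excluded (size {n_hit} among probes)")
            excluded.append(name)
            continue
        obs = stats.wasserstein_distance(vals[member], vals[~member])
        if n_hit not in null_cache:
            null = np.empty(n_perm)
            for r in range(n_perm):
                idx = rng.choice(n, size=n_hit, replace=False)
                m = np.zeros(n, dtype=bool)
                m[idx] = True
                null[r] = stats.wasserstein_distance(vals[m], vals[~m])
            null_cache[n_hit] = null
        null = null_cache[n_hit]
        null_mean = float(null.mean())
        ratio = obs / null_mean if null_mean > 0 else np.inf
        p = (1 + int((null >= obs).sum())) / (n_perm + 1)
        rows.append(
            {
                "set": name,
                "size": n_hit,
                "emd_obs": float(obs),
                "emd_null_mean": null_mean,
                "emd_ratio": float(ratio),
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "emd_obs", "emd_null_mean", "emd_ratio", "p"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = []
    return EnrichmentResult(table, n_perm, seed, excluded)


@dataclass
class EnrichmentNetwork:
    graph: nx.Graph
    components: dict[str, int]  # set name -> component id
    representatives: dict[int, str]  # component id -> representative set

    @property
    def n_components(self) -> int:
        return len(self.representatives)


def enrichment_network(
    results: EnrichmentResult,
    sets: ProteinSetCollection,
    p_threshold: float = 0.001,
    overlap_threshold: float = 0.5,
    score_column: str | None = None,
) -> EnrichmentNetwork:
    """Network of enriched sets: nodes pass p <= p_threshold, edges connect
    sets with |intersection| / min(sizes) > overlap_threshold; clusters are
    connected components, labelled by their lowest-p member."""
    nodes = results.significant(p_threshold)
    score_column = score_column or (
        "emd_ratio" if "emd_ratio" in results.table.columns else "nes"
    )
    g = nx.Graph()
    for name in nodes:
        g.add_node(
            name,
            score=float(results.table.loc[name, score_column]),
            size=int(results.table.loc[name, "size"]),
            p=float(results.table.loc[name, "p"]),
        )
    ordered = sorted(nodes)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            sa, sb = sets[a], sets[b]
            frac = len(sa & sb) / min(len(sa), len(sb))
            if frac > overlap_threshold:
                g.add_edge(a, b, overlap=frac)
    components: dict[str, int] = {}
    representatives: dict[int, str] = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        rep = min(comp, key=lambda nm: (results.table.loc[nm, "p"], nm))
        representatives[cid] = rep
        for nm in comp:
            components[nm] = cid
    return EnrichmentNetwork(g, components, representatives)


@dataclass
class OverlapResult:
    overlap: int
    expected: float
    log2_fold: float
    p: float
    n_a: int
    n_b: int
    n_universe: int


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """One-sided (upper tail) hypergeometric over-representation of the
    overlap between two symbol sets within a universe."""
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise DataError("sets must be subsets of the universe")
    k = len(a & b)
    M, nA, nB = len(universe), len(a), len(b)
    expected = nA * nB / M
    p = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    log2_fold = np.log2(k / expected) if k > 0 and expected > 0 else -np.inf
    return OverlapResult(k, expected, float(log2_fold), min(p, 1.0), nA, nB, M)


@dataclass
class LocationComposition:
    table: pd.DataFrame  # per location: group_n, group_pct, background_pct
    chi2: float
    p: float
    low_count: bool


def location_composition(
    group_probes, annotation: ProbeAnnotation, background_probes
) -> LocationComposition:
    """Cellular-location composition of a probe group versus a background,
    with a chi-squared goodness-of-fit test of group counts against
    background proportions."""
    group = list(group_probes)
    background = list(background_probes)
    if not group or not background:
        raise DataError("group and background must be non-empty")
    loc = annotation.table["cellular_location"]
    g_counts = loc.loc[group].value_counts().reindex(CELLULAR_LOCATIONS, fill_value=0)
    b_counts = loc.loc[background].value_counts().reindex(CELLULAR_LOCATIONS, fill_value=0)
    table = pd.DataFrame(
        {
            "group_n": g_counts,
            "group_pct": 100.0 * g_counts / g_counts.sum(),
            "background_pct": 100.0 * b_counts / b_counts.sum(),
        }
    )
    present = b_counts > 0
    if (g_counts[~present] > 0).any():
        raise DataError("group has probes in locations absent from the background")
    f_obs = g_counts[present].to_numpy(dtype=float)
    f_exp = (b_counts[present] / b_counts[present].sum()).to_numpy() * f_obs.sum()
    chi2, p = stats.chisquare(f_obs, f_exp)
    low_count = bool(len(group) < 5 or (f_exp < 5).any())
    return LocationComposition(table, float(chi2), float(p), low_count)


@dataclass
class MarkerCorrelationResult:
    marker_rhos: np.ndarray
    background_rhos: np.ndarray
    statistic: float
    p: float  # one-sided: markers shifted upward


def marker_correlation_density(
    matrix: ProteomeMatrix,
    marker_probes,
    max_background_pairs: int = 50000,
    seed: int = 0,
) -> MarkerCorrelationResult:
    """Pairwise Spearman correlations among marker probes versus among all
    probes, with a one-sided Mann-Whitney test that marker pairs are more
    strongly correlated."""
    markers = [p for p in marker_probes]
    if len(markers) < 2:
        raise DataError("need at least 2 marker probes")
    missing = set(markers) - set(matrix.probe_ids)
    if missing:
        raise DataError(f"marker probes absent from matrix: {sorted(missing)}")
    ranks = stats.rankdata(matrix.values.to_numpy(dtype=float), axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.nan_to_num(corr, nan=0.0)
    probe_pos = {p: i for i, p in enumerate(matrix.probe_ids)}
    m_idx = np.array([probe_pos[p] for p in markers])
    sub = corr[np.ix_(m_idx, m_idx)]
    iu = np.triu_indices(len(markers), k=1)
    marker_rhos = sub[iu]
    iu_all = np.triu_indices(len(matrix.probe_ids), k=1)
    background = corr[iu_all]
    if len(background) > max_background_pairs:
        rng = np.random.default_rng(seed)
        background = rng.choice(background, size=max_background_pairs, replace=False)
    u, p = stats.mannwhitneyu(marker_rhos, background, alternative="greater")
    return MarkerCorrelationResult(marker_rhos, background, float(u), float(p))
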