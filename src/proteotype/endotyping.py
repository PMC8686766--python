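"""Endotype discovery: PCA embedding, whole-proteome k-means with
deterministic relabeling, any-pairwise signature extraction, and protein
block definition by hierarchical clustering of signature probes.

Probes are z-scored (per probe across subjects) before PCA and k-means, so
every probe contributes on a common scale; block clustering runs on the
same z-scored profiles with (1 - Pearson correlation) distance, average
linkage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .data import DataError, ProteomeMatrix
from .differential import DifferentialResult, differential_abundance


def standardize_probes(matrix: ProteomeMatrix) -> pd.DataFrame:
    """z-score each probe across subjects; constant probes map to 0."""
    X = matrix.values
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    Z = X.sub(mu, axis=0).div(sd.replace(0.0, 1.0), axis=0)
    return Z


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # subjects x components
    pct_variance: np.ndarray


def pca_embed(matrix: ProteomeMatrix, n_components: int = 2) -> PCAResult:
    """Centered PCA of subjects over z-scored probes; components ordered by
    variance explained."""
    n_sub = len(matrix.subject_ids)
    if n_sub < 2 or len(matrix.probe_ids) < 2:
        raise DataError("PCA requires at least 2 subjects and 2 probes")
    if n_components > min(n_sub, len(matrix.probe_ids)):
        raise DataError("more components requested than the data supports")
    Z = standardize_probes(matrix).to_numpy(dtype=float).T  # subjects x probes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Z)
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        pd.DataFrame(coords, index=matrix.subject_ids, columns=cols),
        pca.explained_variance_ratio_ * 100.0,
    )


@dataclass
class EndotypeResult:
    k: int
    labels: pd.Series  # subject id -> cluster label in 1..k
    inertia: float
    n_restarts: int
    seed: int
    silhouette: float | None = None
    k_selection: dict[int, float] = field(default_factory=dict)
    signature: list[str] = field(default_factory=list)
    contrasts: dict[tuple[int, int], DifferentialResult] = field(default_factory=dict)

    def cluster_subjects(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size; ties broken by the lowest
    member index, so seeded runs reproduce labeled output exactly."""
    uniq = np.unique(labels)
    order = sorted(
        uniq, key=lambda c: (-(labels == c).sum(), int(np.argmax(labels == c)))
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def kmeans_endotypes(
    matrix: ProteomeMatrix,
    k: int | None = None,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    n_restarts: int = 25,
    seed: int = 0,
) -> EndotypeResult:
    """Euclidean k-means on subjects over all z-scored probes, best of
    ``n_restarts`` by within-cluster sum of squares.  When ``k`` is absent
    it is chosen from ``k_range`` by maximal mean silhouette.
    """
    Z = standardize_probes(matrix).to_numpy(dtype=float).T
    n = Z.shape[0]
    if k is not None and k > n:
        raise DataError(f"k={k} exceeds the number of subjects ({n})")
    k_scores: dict[int, float] = {}
    if k is None:
        for kk in k_range:
            if kk < 2 or kk >= n:
                continue
            km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed).fit(Z)
            k_scores[kk] = float(silhouette_score(Z, km.labels_))
        if not k_scores:
            raise DataError("no feasible k in k_range")
        k = max(k_scores, key=lambda kk: (k_scores[kk], -kk))
    if k == 1:
        labels = np.ones(n, dtype=int)
        inertia = float(((Z - Z.mean(axis=0)) ** 2).sum())
        return EndotypeResult(
            1, pd.Series(labels, index=matrix.subject_ids), inertia, n_restarts, seed, None, k_scores
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(Z)
    labels = _relabel_by_size(km.labels_)
    sil = float(silhouette_score(Z, km.labels_)) if k >= 2 and k < n else None
    return EndotypeResult(
        k,
        pd.Series(labels, index=matrix.subject_ids),
        float(km.inertia_),
        n_restarts,
        seed,
        sil,
        k_scores,
    )


def pairwise_cluster_signature(
    matrix: ProteomeMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
) -> tuple[list[str], dict[tuple[int, int], DifferentialResult]]:
    """Signature probes: union over all cluster pairs of probes with BH
    q <= alpha (Welch's t per probe, BH within each pairwise contrast).

    Clusters with a single member cannot be tested; their contrasts are
    skipped with a warning.
    """
    labels = labels.loc[[s for s in matrix.subject_ids if s in labels.index]]
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise DataError("need at least two clusters for a signature")
    contrasts: dict[tuple[int, int], DifferentialResult] = {}
    signature: set[str] = set()
    for ci, cj in itertools.combinations(clusters, 2):
        ni = int((labels == ci).sum())
        nj = int((labels == cj).sum())
        if ni < 2 or nj < 2:
            warnings.warn(f"contrast ({ci}, {cj}) skipped: singleton cluster")
            continue
        pair = labels[labels.isin([ci, cj])]
        res = differential_abundance(
            ProteomeMatrix(matrix.values[pair.index], matrix.log_transformed),
            pair.astype(str),
        )
        contrasts[(ci, cj)] = res
        signature.update(res.significant(alpha))
    ordered = [p for p in matrix.probe_ids if p in signature]
    return ordered, contrasts


@dataclass
class ProteinBlock:
    block_id: str
    probes: list[str]
    profile: pd.DataFrame | None = None  # per-cluster median z profile

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("protein block must be non-empty")


_BLOCK_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def define_protein_blocks(
    matrix: ProteomeMatrix,
    signature,
    n_blocks: int | None = None,
    labels: pd.Series | None = None,
    max_blocks: int = 8,
) -> list[ProteinBlock]:
    """Partition signature probes into co-varying blocks.

    Hierarchical clustering on (1 - Pearson correlation) distance between
    per-probe z-scored profiles, average linkage; the tree is cut into
    ``n_blocks`` or, if absent, at the cut (2..max_blocks) with maximal
    mean silhouette on the precomputed distance.  With ``labels`` given,
    each block carries its per-cluster median z-score profile.
    """
    signature = list(signature)
    if not signature:
        raise DataError("signature is empty")
    if len(signature) == 1:
        warnings.warn("single-probe signature: returning one block")
        return [ProteinBlock("A", signature, _block_profile(matrix, signature, labels))]
    Z = standardize_probes(matrix).loc[signature].to_numpy(dtype=float)
    corr = np.corrcoef(Z)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    if n_blocks is None and dist.max() < 1e-10:
        # indistinguishable profiles: a single block
        return [ProteinBlock("A", signature, _block_profile(matrix, signature, labels))]
    link = linkage(squareform(dist, checks=False), method="average")
    if n_blocks is not None:
        assign = fcluster(link, t=n_blocks, criterion="maxclust")
    else:
        best, best_score = 1, -np.inf
        for kk in range(2, min(max_blocks, len(signature) - 1) + 1):
            cand = fcluster(link, t=kk, criterion="maxclust")
            if len(np.unique(cand)) < 2:
                continue
            score = silhouette_score(dist, cand, metric="precomputed")
            if score > best_score:
                best, best_score = kk, score
        if best == 1 or best_score <= 0:
            assign = np.ones(len(signature), dtype=int)
        else:
            assign = fcluster(link, t=best, criterion="maxclust")
    blocks = []
    order = sorted(
        np.unique(assign), key=lambda c: (-(assign == c).sum(), int(np.argmax(assign == c)))
    )
    for rank, c in enumerate(order):
        probes = [p for p, a in zip(signature, assign) if a == c]
        blocks.append(
            ProteinBlock(_BLOCK_IDS[rank], probes, _block_profile(matrix, probes, labels))
        )
    return blocks


def _block_profile(matrix, probes, labels) -> pd.DataFrame | None:
    if labels is None:
        return None
    Z = standardize_probes(matrix).loc[probes]
    prof = {c: Z[labels.index[labels == c]].median(axis=1) for c in sorted(pd.unique(labels))}
    return pd.DataFrame(prof)
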