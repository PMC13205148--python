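"""PCA, K-means with data-driven K, and hierarchical bi-clustering.

Dual PCA (genotypic and phenotypic) summarises structure; K-means on
z-scored BLUPs picks K by a dual read of silhouette scores and the elbow
(largest second difference of within-cluster sums of squares); agglomerative
Ward clustering on both lines and traits yields the bi-clustering heatmap
ordering, with the trait dendrogram cut at three groups for comparison with
the a-priori Grain/Plant/Tassel classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .containers import TRAIT_CLASSES


@dataclass
class PcaResult:
    scores: pd.DataFrame         # lines x components
    loadings: pd.DataFrame       # variables x components
    explained_pct: np.ndarray    # per component, sums to 100


def pca(data: pd.DataFrame, standardize: bool = False) -> PcaResult:
    """Centred (optionally z-scored) SVD with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is positive,
    making scores reproducible across runs and variable orderings.
    """
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 lines and >= 2 variables")
    cols = list(data.columns)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"zero-variance variables excluded: {[c for c, k in zip(cols, keep) if not k]}",
                stacklevel=2,
            )
            X = X[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    var = S ** 2
    explained = var / var.sum() * 100.0 if var.sum() > 0 else var
    names = [f"PC{i + 1}" for i in range(S.shape[0])]
    return PcaResult(
        scores=pd.DataFrame(U * S, index=data.index, columns=names),
        loadings=pd.DataFrame(Vt.T, index=cols, columns=names),
        explained_pct=explained,
    )


@dataclass
class KmeansResult:
    k: int
    assignments: pd.Series
    cluster_means: pd.DataFrame
    wss: dict[int, float]
    silhouette: dict[int, float]
    elbow_k: int
    seed: int


def kmeans_select(
    data: pd.DataFrame,
    k_range: range = range(2, 9),
    seed: int = 0,
    n_init: int = 10,
) -> KmeansResult:
    """Lloyd's K-means over a K range; chosen K maximizes mean silhouette.

    The elbow (largest second difference of WSS) is reported alongside.
    Input is used as-is — z-score beforehand for the standard analysis.
    """
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range must contain values in [2, n-1]")
    wss, sil, fits = {}, {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        wss[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, km.labels_))
        fits[k] = km
    best_k = max(ks, key=lambda k: sil[k])
    if len(ks) >= 3:
        second_diff = {
            k: (wss[ks[i - 1]] - wss[k]) - (wss[k] - wss[ks[i + 1]])
            for i, k in enumerate(ks) if 0 < i < len(ks) - 1
        }
        elbow_k = max(second_diff, key=second_diff.get)
    else:
        elbow_k = best_k
    labels = fits[best_k].labels_ + 1
    assignments = pd.Series(labels, index=data.index, name="cluster")
    means = data.groupby(assignments).mean()
    return KmeansResult(
        k=best_k, assignments=assignments, cluster_means=means,
        wss=wss, silhouette=sil, elbow_k=elbow_k, seed=seed,
    )


@dataclass
class BiclusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    ordered: pd.DataFrame
    trait_groups: pd.Series        # column cut into n_trait_groups
    apriori_classes: pd.Series = field(default_factory=pd.Series)


def hierarchical_bicluster(
    blups: pd.DataFrame,
    method: str = "ward",
    n_trait_groups: int = 3,
) -> BiclusterResult:
    """Ward/Euclidean agglomerative clustering of z-scored lines and traits."""
    X = blups.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    row_link = hierarchy.linkage(Z, method=method)
    col_link = hierarchy.linkage(Z.T, method=method)
    row_order = hierarchy.leaves_list(row_link).tolist()
    col_order = hierarchy.leaves_list(col_link).tolist()
    ordered = blups.iloc[row_order, col_order]
    cut = hierarchy.fcluster(col_link, t=n_trait_groups, criterion="maxclust")
    trait_groups = pd.Series(cut, index=blups.columns, name="trait_group")
    apriori = pd.Series(
        {t: TRAIT_CLASSES.get(t, "?") for t in blups.columns}, name="apriori"
    )
    return BiclusterResult(
        row_linkage=row_link, col_linkage=col_link,
        row_order=row_order, col_order=col_order,
        ordered=ordered, trait_groups=trait_groups, apriori_classes=apriori,
    )
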