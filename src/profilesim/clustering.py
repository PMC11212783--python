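"""Clustering measures by behavioural similarity.

Measures are compared through the values they produce over the same profile
pairs: the association between two measure columns is a multilevel Spearman
correlation (rank-transform, then residualize on the grouping structure —
couples or cultures — then correlate the residuals), the distance between
two measures is ``1 - |rho|`` so that strongly negatively associated
similarity/dissimilarity pairs cluster together, and the resulting distance
matrix is clustered agglomeratively with Ward's criterion.  Cutting each
dendrogram at its longest height gap yields the main clusters; comparing
partitions across datasets labels measures whose cluster membership is
unstable as "inconsistent".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "MeasureDendrogram",
    "multilevel_spearman",
    "measure_distance_matrix",
    "ward_cluster",
    "cut_longest",
    "cross_dataset_consistency",
]


def _group_demean(v: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Residuals of v after removing group means (dummy regression on the
    group indicator)."""
    s = pd.Series(v)
    return (s - s.groupby(pd.Series(groups)).transform("mean")).to_numpy()


def multilevel_spearman(u, v, groups) -> float:
    """Multilevel (partial) Spearman correlation of two value columns.

    Mid-ranks both columns over the jointly non-missing observations,
    residualizes each rank vector on the group indicator, and returns the
    product-moment correlation of the residuals.  With a single group this
    reduces to the ordinary Spearman correlation.  Returns NaN when either
    residual vector has no variance.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    groups = np.asarray(groups)
    if not (u.shape == v.shape == groups.shape):
        raise ValueError("u, v and groups must have equal length")
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly non-missing observations")
    ru = stats.rankdata(u[ok])
    rv = stats.rankdata(v[ok])
    eu = _group_demean(ru, groups[ok])
    ev = _group_demean(rv, groups[ok])
    su = np.sqrt((eu * eu).sum())
    sv = np.sqrt((ev * ev).sum())
    if su == 0.0 or sv == 0.0:
        return float("nan")
    return float(np.clip((eu * ev).sum() / (su * sv), -1.0, 1.0))


def measure_distance_matrix(values: pd.DataFrame, groups: Sequence,
                            impute_missing: float = 1.0) -> pd.DataFrame:
    """Symmetric measure-by-measure distance matrix ``1 - |rho|``.

    ``values`` is an observations x measures table (NaN = missing marker),
    ``groups`` one grouping label per observation.  Undefined correlations
    (degenerate columns on the joint support) are imputed as the maximum
    distance with a warning.  Raises if any column is entirely missing.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 measures")
    groups = np.asarray(groups)
    if groups.shape[0] != values.shape[0]:
        raise ValueError("groups length must match observation count")
    cols = list(values.columns)
    dead = [c for c in cols if values[c].isna().all()]
    if dead:
        raise ValueError(f"measure columns entirely missing: {dead}")
    arr = values.to_numpy(dtype=float)
    M = len(cols)
    D = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            rho = multilevel_spearman(arr[:, i], arr[:, j], groups)
            if np.isnan(rho):
                warnings.warn(
                    f"undefined correlation between {cols[i]} and {cols[j]}; "
                    f"imputing distance {impute_missing}")
                d = impute_missing
            else:
                d = 1.0 - abs(rho)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=cols, columns=cols)


@dataclass
class MeasureDendrogram:
    """Agglomerative merge tree over measures.

    ``linkage`` is a scipy linkage matrix (``M - 1`` merges for ``M``
    leaves, nondecreasing heights in column 2); ``labels`` are the leaf
    measure ids in input order.
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self):
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut_at_k(self, k: int) -> dict[str, int]:
        """Partition into exactly k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def cut_at_height(self, h: float) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=h, criterion="distance")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def ward_cluster(D: pd.DataFrame | np.ndarray,
                 labels: Optional[Sequence[str]] = None,
                 dialect: str = "d2") -> MeasureDendrogram:
    """Hierarchical clustering of a precomputed dissimilarity matrix with
    Ward's minimum-variance criterion.

    ``dialect="d2"`` (default) applies the Lance-Williams recurrence on
    squared dissimilarities with square-root back-transform of heights (the
    convention appropriate for a precomputed dissimilarity matrix);
    ``dialect="d1"`` applies the recurrence to the dissimilarities as given.
    """
    if isinstance(D, pd.DataFrame):
        if labels is None:
            labels = list(D.columns)
        D = D.to_numpy(dtype=float)
    else:
        D = np.asarray(D, dtype=float)
        if labels is None:
            labels = [f"m{i}" for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(D, checks=False)
    if dialect == "d2":
        Z = hierarchy.linkage(condensed, method="ward")
    elif dialect == "d1":
        Z = hierarchy.linkage(np.sqrt(condensed), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown ward dialect {dialect!r}")
    return MeasureDendrogram(Z, list(labels))


def cut_longest(dend: MeasureDendrogram) -> dict[str, int]:
    """Cut the dendrogram inside the largest gap between consecutive merge
    heights.

    The gap above the final merge is excluded (it would always give one
    cluster), as is the region below the first merge (every leaf its own
    cluster); ties break toward fewer clusters.  Returns measure -> cluster
    labels.
    """
    if dend.n_leaves < 3:
        raise ValueError("need at least 3 leaves to cut")
    h = np.sort(dend.heights)
    gaps = np.diff(h)  # gaps[j] between merge j and j+1
    # argmax with ties toward the last (later merge => fewer clusters)
    best = len(gaps) - 1 - int(np.argmax(gaps[::-1]))
    cut = (h[best] + h[best + 1]) / 2.0
    return dend.cut_at_height(cut)


def _same_cluster_matrix(partition: Mapping[str, int],
                         order: Sequence[str]) -> np.ndarray:
    lab = np.array([partition[m] for m in order])
    return lab[:, None] == lab[None, :]


def cross_dataset_consistency(partitions: Sequence[Mapping[str, int]],
                              min_agree: int = 4
                              ) -> tuple[list[list[str]], list[str]]:
    """Label measures by the stability of their co-grouping across datasets.

    Two measures are consistently co-grouped when they share a cluster in at
    least ``min_agree`` of the partitions; the consistent groups are the
    connected components of that relation, and a measure belonging to no
    component of size >= 2 is labeled inconsistent.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    order = sorted(partitions[0].keys())
    for p in partitions[1:]:
        if sorted(p.keys()) != order:
            raise ValueError("partitions cover different measure sets")
    agree = np.zeros((len(order), len(order)), dtype=int)
    for p in partitions:
        agree += _same_cluster_matrix(p, order)
    edge = agree >= min_agree
    np.fill_diagonal(edge, False)
    from scipy.sparse.csgraph import connected_components
    n_comp, comp = connected_components(edge, directed=False)
    groups = []
    inconsistent = []
    for c in range(n_comp):
        members = [order[i] for i in np.nonzero(comp == c)[0]]
        # a singleton is only a real component if it has no stable partner
        if len(members) >= 2:
            groups.append(members)
        else:
            inconsistent.extend(members)
    return groups, inconsistent
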