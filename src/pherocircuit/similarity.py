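"""Pairwise neuron similarity score, distance conversion and Ward clustering.

The similarity of a query neuron Q (n points) to a target neuron T is

    S(Q, T) = (1/n) * sum_i |q_i . t_j| * exp(-d_ij^2 / (2 sigma^2))

where point j is the Euclidean nearest neighbour in T of query point i, d_ij is
their distance, and q_i, t_j are the unit tangent vectors at those points.  The
free parameter sigma (default 3 μm) sets how close in space two points must be
to be considered similar, matched to registration accuracy in the fly brain.
S ranges from 1 (identical) down to 0 (completely different) and is not
symmetric in general.  Distances D = 1 - S feed Ward hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .skeletons import DotProps

__all__ = [
    "SimilarityParams",
    "DistanceMatrix",
    "Dendrogram",
    "similarity_score",
    "distance_matrix",
    "cluster_neurons",
    "cut_clusters",
    "to_newick",
]

SYMMETRIZE_MODES = ("mean", "min", "max", "none")
LINKAGE_METHODS = ("ward", "ward.d2", "average", "complete", "single")


@dataclass(frozen=True)
class SimilarityParams:
    """sigma in μm; symmetrize is how the two directed distances are combined."""

    sigma: float = 3.0
    symmetrize: str = "mean"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.symmetrize not in SYMMETRIZE_MODES:
            raise ValueError(f"symmetrize must be one of {SYMMETRIZE_MODES}")


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if np.any(np.abs(np.diag(self.values)) > 1e-9):
            raise ValueError("diagonal entries must be 0")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    labels: list
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list:
        from scipy.cluster.hierarchy import leaves_list

        return [self.labels[i] for i in leaves_list(self.linkage)]


def similarity_score(query: DotProps, target: DotProps,
                     params: SimilarityParams | None = None) -> float:
    """S(Q, T) in [0, 1]; 1 for identical clouds.  Not symmetric in general.

    Equidistant nearest neighbours resolve to the lowest target point index.
    """
    params = params or SimilarityParams()
    d, j = cKDTree(target.points).query(query.points, k=1)
    dots = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[j]))
    score = float(np.mean(dots * np.exp(-d**2 / (2.0 * params.sigma**2))))
    return min(score, 1.0)


def distance_matrix(neurons: list[DotProps],
                    params: SimilarityParams | None = None,
                    labels: list | None = None) -> DistanceMatrix:
    """All-pairs distances 1 - S(a, b), symmetrized per ``params.symmetrize``."""
    params = params or SimilarityParams()
    if len(neurons) < 2:
        raise ValueError("need at least 2 neurons")
    if labels is None:
        labels = [n.source_label or f"neuron_{i}" for i, n in enumerate(neurons)]
    tags = {n.space_tag for n in neurons if n.space_tag}
    if len(tags) > 1:
        warnings.warn(f"neurons carry differing space tags: {sorted(tags)}", stacklevel=2)

    n = len(neurons)
    trees = [cKDTree(x.points) for x in neurons]
    s = np.eye(n)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            d, j = trees[b].query(neurons[a].points, k=1)
            dots = np.abs(np.einsum("ij,ij->i",
                                    neurons[a].tangents, neurons[b].tangents[j]))
            s[a, b] = np.mean(dots * np.exp(-d**2 / (2.0 * params.sigma**2)))
    dvals = 1.0 - s
    if params.symmetrize == "mean":
        dvals = 0.5 * (dvals + dvals.T)
    elif params.symmetrize == "min":
        dvals = np.minimum(dvals, dvals.T)
    elif params.symmetrize == "max":
        dvals = np.maximum(dvals, dvals.T)
    dvals = np.clip(dvals, 0.0, 1.0)
    np.fill_diagonal(dvals, 0.0)
    return DistanceMatrix(labels=list(labels), values=dvals,
                          symmetric=params.symmetrize != "none")


def cluster_neurons(dm: DistanceMatrix, method: str = "ward") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    ``"ward"`` is classic Ward on the distances as given (R hclust ward.D):
    implemented by running scipy's Ward recurrence on sqrt(d) — identical
    Lance-Williams updates — and squaring the merge heights back.  ``"ward.d2"``
    is scipy's native variant; average/complete/single pass through.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}")
    v = dm.values
    if not dm.symmetric or not np.allclose(v, v.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetrized before clustering")
    cond = squareform(v, checks=False)
    if method == "ward":
        z = linkage(np.sqrt(cond), method="ward")
        z = z.copy()
        z[:, 2] **= 2
    elif method == "ward.d2":
        z = linkage(cond, method="ward")
    else:
        z = linkage(cond, method=method)
    return Dendrogram(labels=list(dm.labels), linkage=z)


def cut_clusters(dendro: Dendrogram, k: int) -> np.ndarray:
    """Cut the merge tree into exactly k groups; labels 0..k-1 per leaf."""
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    return cut_tree(dendro.linkage, n_clusters=k).ravel()


def to_newick(dendro: Dendrogram) -> str:
    """Newick string with merge heights encoded as branch lengths."""
    z = dendro.linkage
    n = dendro.n_leaves
    height = {i: 0.0 for i in range(n)}

    def name(i: int) -> str:
        raw = str(dendro.labels[i])
        return raw.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "_")

    node: dict[int, str] = {i: name(i) for i in range(n)}
    for m, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        node[n + m] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
        height[n + m] = h
    return node[n + len(z) - 1] + ";"
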