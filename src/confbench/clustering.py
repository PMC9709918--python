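"""Pooled-ensemble clustering: 2-D embedding, density clustering, composition.

For each catalyst the conformers of every method are pooled, a pairwise
distance matrix on the representative atoms is embedded to 2-D with UMAP
(fixed ``random_state`` for reproducibility), and clusters are found with
HDBSCAN, which labels low-density points as outliers (-1) instead of forcing
an assignment. The cluster-by-method composition table then tells how much of
the pooled conformational space each method explored: a method's participation
is the fraction of (non-outlier) clusters in which it has at least one
conformer.

Clustering hyperparameters were tuned per molecule in manual workflows; here
they are declared config defaults with per-catalyst overrides so every result
is reproducible from the config alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .io_conformers import Conformer, StudyRegistry
from .geometry import DistanceMatrix, pairwise_distance_matrix

__all__ = [
    "EmbeddingParams",
    "ClusterParams",
    "ClusterLabels",
    "ClusterComposition",
    "pool",
    "embed_2d",
    "density_cluster",
    "composition",
    "participation_fraction",
    "cluster_catalyst",
]


@dataclass
class EmbeddingParams:
    """UMAP settings. ``n_components`` is fixed at 2 and ``random_state``
    defaults to 42; only the neighborhood size and packing density are tuned.

    ``n_neighbors`` should be on the order of the smallest cluster occupancy
    expected in the pooled ensemble: neighborhoods much smaller than a
    cluster's population can tear one continuous conformer family into
    fragments in the embedding.
    """

    n_neighbors: int = 30
    min_distance: float = 0.1
    random_state: int = 42
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not 0.0 <= self.min_distance < 1.0:
            raise ValueError("min_distance must lie in [0, 1)")
        if self.n_components != 2:
            raise ValueError("n_components is fixed at 2")


@dataclass
class ClusterParams:
    """HDBSCAN settings: the two knobs that control cluster granularity."""

    min_samples: int = 5
    min_cluster_size: int = 8

    def __post_init__(self) -> None:
        if self.min_samples < 2 or self.min_cluster_size < 2:
            raise ValueError("min_samples and min_cluster_size must be >= 2")


@dataclass
class ClusterLabels:
    """Per-conformer integer labels; -1 marks outliers, clusters are 0..n-1."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        non_outlier = sorted(set(self.labels[self.labels >= 0].tolist()))
        if non_outlier != list(range(self.n_clusters)):
            raise ValueError("non-outlier labels must be contiguous 0..n_clusters-1")

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == -1))


@dataclass
class ClusterComposition:
    """Cluster-by-method conformer counts plus per-method outlier counts."""

    counts: pd.DataFrame  # index: cluster id, columns: method labels
    outliers: pd.Series  # per-method outlier counts

    @property
    def n_clusters(self) -> int:
        return len(self.counts)

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def method_totals(self) -> pd.Series:
        """Clustered + outlier counts per method (= pooled ensemble sizes)."""
        return self.counts.sum(axis=0).add(self.outliers, fill_value=0).astype(int)


def pool(
    registry: StudyRegistry, catalyst_id: str, constrained: bool = False
) -> tuple[list[Conformer], list[str]]:
    """Concatenate every method's ensemble for one catalyst.

    Returns the pooled conformers and a parallel list of method labels
    (the provenance used by :func:`composition`). Methods are taken in sorted
    label order; within a method, file order is preserved.
    """
    methods = registry.methods_for(catalyst_id, constrained)
    if not methods:
        raise KeyError(f"no ensembles for catalyst {catalyst_id!r}")
    if len(methods) < 2:
        raise ValueError(
            f"catalyst {catalyst_id!r} has a single method; pooling needs >= 2"
        )
    conformers: list[Conformer] = []
    provenance: list[str] = []
    for m in methods:
        ens = registry.get(catalyst_id, m, constrained)
        conformers.extend(ens.conformers)
        provenance.extend([m] * len(ens))
    return conformers, provenance


def embed_2d(dist: DistanceMatrix, params: EmbeddingParams | None = None) -> np.ndarray:
    """UMAP 2-D embedding of a precomputed distance matrix.

    Deterministic for a fixed ``random_state``: identical inputs give
    identical coordinates.
    """
    import umap  # deferred: numba compilation makes this import expensive

    params = params or EmbeddingParams()
    n = len(dist)
    if n < params.n_neighbors:
        raise ValueError(
            f"{n} conformers but n_neighbors={params.n_neighbors}; "
            "reduce n_neighbors or pool more conformers"
        )
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        min_dist=params.min_distance,
        n_components=params.n_components,
        random_state=params.random_state,
        metric="precomputed",
    )
    with warnings.catch_warnings():
        # UMAP warns that a fixed random_state disables parallelism; that
        # trade is deliberate here.
        warnings.filterwarnings("ignore", category=UserWarning, module="umap")
        return np.asarray(reducer.fit_transform(dist.values), dtype=float)


def density_cluster(coords: np.ndarray, params: ClusterParams | None = None) -> ClusterLabels:
    """HDBSCAN on embedded coordinates; noise points get label -1."""
    params = params or ClusterParams()
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < params.min_cluster_size:
        warnings.warn(
            f"only {coords.shape[0]} points with min_cluster_size="
            f"{params.min_cluster_size}; all points labeled outliers",
            stacklevel=2,
        )
        return ClusterLabels(labels=np.full(coords.shape[0], -1), n_clusters=0)
    if np.all(coords == coords[0]):
        # fully degenerate input: one infinitely dense cluster
        return ClusterLabels(labels=np.zeros(coords.shape[0], dtype=int), n_clusters=1)
    model = HDBSCAN(
        min_samples=params.min_samples,
        min_cluster_size=params.min_cluster_size,
        copy=True,
    )
    labels = model.fit_predict(coords)
    # relabel to contiguous 0..k-1 in order of first appearance
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab < 0:
            out[i] = -1
        else:
            if lab not in mapping:
                mapping[lab] = len(mapping)
            out[i] = mapping[lab]
    return ClusterLabels(labels=out, n_clusters=len(mapping))


def composition(labels: ClusterLabels, provenance: Sequence[str]) -> ClusterComposition:
    """Cluster-by-method count table from labels and per-conformer method labels."""
    if len(labels.labels) != len(provenance):
        raise ValueError("labels and provenance differ in length")
    methods = sorted(set(provenance))
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(labels.n_clusters, name="cluster"), columns=methods
    )
    outliers = pd.Series(0, index=pd.Index(methods, name="method"))
    for lab, m in zip(labels.labels, provenance):
        if lab < 0:
            outliers[m] += 1
        else:
            counts.loc[lab, m] += 1
    return ClusterComposition(counts=counts, outliers=outliers)


def participation_fraction(comp: ClusterComposition, method_label: str) -> float:
    """Fraction of clusters containing at least one conformer of ``method_label``.

    Outliers count in neither the numerator nor the denominator.
    """
    if method_label not in comp.counts.columns:
        raise KeyError(f"method {method_label!r} not present in composition")
    if comp.n_clusters == 0:
        raise ValueError("no clusters: participation undefined")
    present = int((comp.counts[method_label] > 0).sum())
    return present / comp.n_clusters


def cluster_catalyst(
    registry: StudyRegistry,
    catalyst_id: str,
    constrained: bool = False,
    embedding: EmbeddingParams | None = None,
    clustering: ClusterParams | None = None,
    metric: str = "blended",
    blend_weight: float = 0.5,
) -> tuple[ClusterComposition, ClusterLabels, np.ndarray, list[str]]:
    """Full per-catalyst pipeline: pool, distance matrix, embed, cluster, count.

    Returns the composition table, the labels, the 2-D coordinates, and the
    per-conformer method provenance.
    """
    conformers, provenance = pool(registry, catalyst_id, constrained)
    sel = registry.selection_for(catalyst_id)
    dist = pairwise_distance_matrix(conformers, sel, metric=metric, blend_weight=blend_weight)
    coords = embed_2d(dist, embedding)
    labels = density_cluster(coords, clustering)
    comp = composition(labels, provenance)
    return comp, labels, coords, provenance
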