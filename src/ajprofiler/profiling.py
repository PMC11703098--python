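"""Embedding-space profiling: UMAP reduction, HDBSCAN clustering, frozen-model
assignment of new data, and per-sample cluster-occupancy profiles.

A ``ReducerBundle`` is fitted once on a reference embedding set (target fit
size 10,000 patches) and then frozen: new embeddings are mapped through the
fitted UMAP transform and given approximate cluster membership from the
fitted clusterer without ever refitting.  A sample's morphological profile is
the frequency vector of its patches over the clusters, with unassigned
(noise) patches kept as an explicit final bin so that profiles remain
comparable across samples with different noise rates.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import HDBSCAN

DEFAULT_FIT_SIZE = 10_000
#: HDBSCAN min_cluster_size at the reference fit scale; scaled proportionally
#: (floor 5) for smaller fits
MIN_CLUSTER_SIZE_AT_REF = 100


@dataclass
class ReducerParams:
    n_neighbors: int = 30
    #: 0.0 packs embedded points tightly, preserving the density gaps the
    #: clusterer needs; larger values are for visual spacing only
    min_dist: float = 0.0
    metric: str = "euclidean"
    min_cluster_size: int | None = None  # None -> scaled from fit size
    #: core-distance neighbor count for the density estimate; None follows the
    #: clustering library (ties it to min_cluster_size); smaller values give a
    #: finer estimate that can split bridged density peaks into more clusters
    min_samples: int | None = None
    #: new points farther than this factor times the fit set's own 99th-pct
    #: nearest-neighbor distance (in embedding space) are assigned to noise
    outlier_factor: float = 3.0


@dataclass
class ReducerBundle:
    """Frozen 2D reducer + density clusterer fitted on one embedding set."""

    umap_model: object
    clusterer: object
    fit_embeddings: np.ndarray
    fit_coords: np.ndarray
    fit_labels: np.ndarray
    n_fit: int
    seed: int
    params: ReducerParams
    emb_nn_cutoff: float
    coord_nn_cutoff: float
    cluster_sizes: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(len([c for c in self.cluster_sizes if c >= 0]))

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "bundle": self}, fh)

    @classmethod
    def load(cls, path: str) -> "ReducerBundle":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return payload["bundle"]


@dataclass
class MorphProfile:
    """Per-sample frequency vector over cluster indices plus a noise bin."""

    sample_id: str
    frequencies: np.ndarray  # length n_clusters + 1, noise bin last
    n_rois: int
    condition: str = ""

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=np.float64)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("profile frequencies must be nonnegative and sum to 1")
        self.frequencies = f


def _nn_cutoff(points: np.ndarray, factor: float) -> float:
    """factor x the 99th percentile of nearest-neighbor distances."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2, workers=1)
    q = float(np.quantile(d[:, 1], 0.99))
    return factor * max(q, 1e-12)


def fit_reducer(
    embeddings: np.ndarray,
    params: ReducerParams | None = None,
    seed: int = 0,
) -> ReducerBundle:
    """Fit UMAP (2 components, fixed seed) then HDBSCAN on the 2D coordinates.

    Cluster indices are the clusterer's native enumeration (0..k-1, noise -1).
    Requires at least 100 embeddings; the reference protocol fits on 10,000.
    """
    import umap

    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or len(X) < 100:
        raise ValueError("need at least 100 embeddings to fit the reducer")
    params = params or ReducerParams()
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(X)
    mcs = params.min_cluster_size
    if mcs is None:
        mcs = max(int(round(MIN_CLUSTER_SIZE_AT_REF * len(X) / DEFAULT_FIT_SIZE)), 5)
    clusterer = HDBSCAN(min_cluster_size=mcs, min_samples=params.min_samples)
    labels = clusterer.fit_predict(coords)
    uniq, counts = np.unique(labels, return_counts=True)
    return ReducerBundle(
        umap_model=reducer,
        clusterer=clusterer,
        fit_embeddings=X,
        fit_coords=np.asarray(coords, dtype=np.float64),
        fit_labels=labels.astype(np.int64),
        n_fit=len(X),
        seed=seed,
        params=params,
        emb_nn_cutoff=_nn_cutoff(X, params.outlier_factor),
        coord_nn_cutoff=_nn_cutoff(np.asarray(coords, dtype=np.float64), params.outlier_factor),
        cluster_sizes={int(u): int(c) for u, c in zip(uniq, counts)},
    )


def assign_clusters(bundle: ReducerBundle, embeddings: np.ndarray) -> np.ndarray:
    """Cluster label per embedding (-1 = noise) from the frozen bundle.

    New points are mapped by the frozen UMAP transform, then inherit the
    cluster label of the nearest fit point in the 2D plane.  Two density
    gates send points to noise instead: embeddings farther from the fit set
    (in the original space) than the bundle's embedding-space cutoff, and 2D
    coordinates farther from the fit coordinates than the 2D cutoff.  The
    bundle is never refitted or mutated.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != bundle.fit_embeddings.shape[1]:
        raise ValueError(
            f"embeddings must be 2D with dimension {bundle.fit_embeddings.shape[1]}"
        )
    if len(X) == 0:
        return np.zeros(0, dtype=np.int64)
    emb_tree = cKDTree(bundle.fit_embeddings)
    d_emb, _ = emb_tree.query(X, k=1, workers=1)
    coords = np.asarray(bundle.umap_model.transform(X), dtype=np.float64)
    coord_tree = cKDTree(bundle.fit_coords)
    d_2d, idx = coord_tree.query(coords, k=1, workers=1)
    labels = bundle.fit_labels[idx].copy()
    labels[d_emb > bundle.emb_nn_cutoff] = -1
    labels[d_2d > bundle.coord_nn_cutoff] = -1
    return labels


def occupancy_profile(
    labels: np.ndarray, n_clusters: int, sample_id: str = "", condition: str = ""
) -> MorphProfile:
    """Frequency vector over clusters 0..n_clusters-1 with a final noise bin."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("cannot profile an empty label list")
    if labels.min() < -1 or labels.max() >= n_clusters:
        raise ValueError("labels must lie in {-1, 0..n_clusters-1}")
    counts = np.zeros(n_clusters + 1, dtype=np.float64)
    for lab in labels:
        counts[lab if lab >= 0 else n_clusters] += 1
    return MorphProfile(
        sample_id=sample_id,
        frequencies=counts / counts.sum(),
        n_rois=int(labels.size),
        condition=condition,
    )


def sample_cluster_exemplars(
    bundle: ReducerBundle, rois, labels: np.ndarray, k: int = 5, seed: int = 0
) -> dict[int, np.ndarray]:
    """Up to ``k`` ROI indices per cluster, uniform without replacement.

    Clusters smaller than ``k`` return all members.  Returns a mapping
    cluster label -> array of indices into ``rois``/``labels``.
    """
    labels = np.asarray(labels)
    if rois is not None and len(labels) != len(rois):
        raise ValueError("labels must align with rois")
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for lab in sorted(set(labels.tolist())):
        if lab < 0:
            continue
        members = np.flatnonzero(labels == lab)
        take = min(k, len(members))
        out[int(lab)] = np.sort(rng.choice(members, size=take, replace=False))
    return out
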