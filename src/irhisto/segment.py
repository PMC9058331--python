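"""Per-image K-means segmentation of corrected spectra.

Each IR image is clustered independently (Lloyd's algorithm, k-means++
seeding, best of several restarts), clusters are labelled with histology
classes — for real data by a pathologist-validated mapping, for synthetic
data by majority vote against the ground-truth map — and class-restricted
spectra are extracted for classification.  Digital staining and a Ward
dendrogram over the centroids reproduce the usual visual outputs.

Distances are Euclidean on EMSC-corrected spectra: the correction already
normalizes, so no further per-spectrum scaling is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster import hierarchy
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_score

from .core import InvariantError, SpectraTable, TissueClass

UNASSIGNED = -1


@dataclass
class ClusterMap:
    """Per-pixel cluster assignment for one sample's image."""

    sample_id: str
    assignments: np.ndarray          # 2-D int image; -1 for masked pixels
    k: int
    centroids: np.ndarray            # (k, n_channels)
    label_map: dict[int, TissueClass] = field(default_factory=dict)
    inertia: float = np.nan          # within-cluster sum of squares
    restart_inertias: tuple[float, ...] = ()

    def __post_init__(self):
        a = np.asarray(self.assignments)
        if a.ndim != 2:
            raise InvariantError("assignments must be a 2-D image")
        vals = np.unique(a)
        if not np.all((vals >= -1) & (vals < self.k)):
            raise InvariantError("assignments must lie in {-1, 0..k-1}")
        if self.centroids.shape[0] != self.k:
            raise InvariantError("one centroid per cluster required")

    @property
    def occurring_clusters(self) -> list[int]:
        vals = np.unique(self.assignments)
        return [int(v) for v in vals if v >= 0]

    @property
    def labeled(self) -> bool:
        return all(c in self.label_map for c in self.occurring_clusters)


def _lloyd(
    X: np.ndarray, k: int, seed: int, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means run; asserts the WCSS never increases across iterations."""
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    x_sq = (X**2).sum(axis=1)
    prev = np.inf
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = x_sq[:, None] - 2.0 * X @ centers.T + (centers**2).sum(axis=1)
        np.maximum(d2, 0.0, out=d2)
        labels = np.argmin(d2, axis=1)
        wcss = float(d2[np.arange(X.shape[0]), labels].sum())
        assert wcss <= prev * (1 + 1e-9) + 1e-12, "k-means objective increased"
        for j in range(k):
            members = labels == j
            if members.any():
                centers[j] = X[members].mean(axis=0)
            else:  # re-seed an empty cluster from the farthest point
                far = int(np.argmax(d2[np.arange(X.shape[0]), labels]))
                centers[j] = X[far]
        if prev - wcss <= tol * max(prev, 1e-12):
            prev = wcss
            break
        prev = wcss
    # final assignment, then one mean update so every centroid is exactly
    # the mean of its members (WCSS can only decrease)
    d2 = x_sq[:, None] - 2.0 * X @ centers.T + (centers**2).sum(axis=1)
    np.maximum(d2, 0.0, out=d2)
    labels = np.argmin(d2, axis=1)
    for j in range(k):
        members = labels == j
        if members.any():
            centers[j] = X[members].mean(axis=0)
    wcss = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, wcss


def kmeans_segment(
    table: SpectraTable,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterMap:
    """K-means over one sample's spectra; best of ``restarts`` runs by WCSS."""
    ids = table.sample_ids
    if len(ids) != 1:
        raise InvariantError(f"expected one sample, found {ids}")
    n = len(table)
    if k < 1:
        raise InvariantError("k must be >= 1")
    if k > n:
        raise InvariantError(f"k ({k}) exceeds record count ({n})")
    X = np.ascontiguousarray(table.spectra)
    rng = np.random.default_rng(seed)
    best = None
    inertias = []
    for _ in range(max(1, restarts)):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        labels, centers, wcss = _lloyd(X, k, sub_seed, max_iter, tol)
        inertias.append(wcss)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    labels, centers, wcss = best
    rows = table.meta["row"].to_numpy(int)
    cols = table.meta["column"].to_numpy(int)
    shape = (rows.max() + 1, cols.max() + 1)
    assignments = np.full(shape, UNASSIGNED, dtype=int)
    assignments[rows, cols] = labels
    return ClusterMap(
        sample_id=ids[0],
        assignments=assignments,
        k=k,
        centroids=centers,
        inertia=wcss,
        restart_inertias=tuple(inertias),
    )


@dataclass
class ScanKResult:
    maps: dict[int, ClusterMap]
    silhouettes: dict[int, float]
    recommended_k: int


def scan_k(
    table: SpectraTable,
    k_range=range(2, 9),
    seed: int = 0,
    restarts: int = 5,
    max_silhouette_n: int = 2000,
) -> ScanKResult:
    """Cluster at each candidate k; recommend the k with the best mean
    silhouette on a fixed-seed subsample.  The human can always override —
    the emulated workflow validated cluster counts by eye."""
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise InvariantError("k_range must be non-empty")
    if max(k_range) > len(table):
        raise InvariantError("max(k_range) exceeds record count")
    X = table.spectra
    if np.allclose(X, X[0], rtol=0, atol=1e-12):
        warnings.warn(
            "all spectra identical; silhouette undefined, recommending k=1",
            RuntimeWarning,
        )
        cmap = kmeans_segment(table, 1, seed=seed, restarts=1)
        return ScanKResult({1: cmap}, {}, 1)
    rng = np.random.default_rng(seed)
    if len(table) > max_silhouette_n:
        sub = rng.choice(len(table), size=max_silhouette_n, replace=False)
    else:
        sub = np.arange(len(table))
    maps: dict[int, ClusterMap] = {}
    sils: dict[int, float] = {}
    for k in k_range:
        cmap = kmeans_segment(table, k, seed=seed, restarts=restarts)
        maps[k] = cmap
        rows = table.meta["row"].to_numpy(int)
        cols = table.meta["column"].to_numpy(int)
        labels = cmap.assignments[rows, cols]
        sub_labels = labels[sub]
        if np.unique(sub_labels).size < 2:
            sils[k] = -1.0
        else:
            sils[k] = float(silhouette_score(X[sub], sub_labels))
    recommended = max(sils, key=lambda k: (sils[k], -k))
    return ScanKResult(maps, sils, recommended)


def label_clusters(
    cmap: ClusterMap, labels: dict[int, TissueClass | str]
) -> ClusterMap:
    """Attach a cluster -> tissue-class mapping (many-to-one allowed)."""
    mapping = {int(i): TissueClass(str(v)) if not isinstance(v, TissueClass) else v
               for i, v in labels.items()}
    missing = [c for c in cmap.occurring_clusters if c not in mapping]
    if missing:
        raise InvariantError(f"labels missing for clusters {missing}")
    return replace(cmap, label_map=mapping)


def auto_label_by_ground_truth(
    cmap: ClusterMap, truth_map: np.ndarray
) -> ClusterMap:
    """Label each cluster with its majority ground-truth tissue class.

    Test-harness convenience for synthetic data, standing in for the
    pathologist-validated labelling used on real images.
    """
    if truth_map.shape != cmap.assignments.shape:
        raise InvariantError("ground-truth map shape mismatch")
    labels = {}
    for c in cmap.occurring_clusters:
        members = truth_map[cmap.assignments == c]
        values, counts = np.unique(members, return_counts=True)
        labels[c] = TissueClass(str(values[np.argmax(counts)]))
    return label_clusters(cmap, labels)


def extract_class_spectra(
    table: SpectraTable,
    cmap: ClusterMap,
    classes: set[TissueClass] | frozenset[TissueClass],
) -> SpectraTable:
    """Records whose pixel's cluster label is in ``classes``; the
    tissue_class column is set from the cluster label."""
    if not classes:
        raise InvariantError("classes must be non-empty")
    if not cmap.labeled:
        raise InvariantError("cluster map is not labeled")
    classes = {TissueClass(str(c)) if not isinstance(c, TissueClass) else c
               for c in classes}
    rows = table.meta["row"].to_numpy(int)
    cols = table.meta["column"].to_numpy(int)
    in_image = (rows < cmap.assignments.shape[0]) & (cols < cmap.assignments.shape[1])
    clusters = np.full(len(table), UNASSIGNED, dtype=int)
    clusters[in_image] = cmap.assignments[rows[in_image], cols[in_image]]
    pixel_class = np.array(
        [cmap.label_map[c].value if c >= 0 else "" for c in clusters]
    )
    keep = np.isin(pixel_class, [c.value for c in classes])
    out = table.select(keep)
    out.meta = out.meta.assign(tissue_class=pixel_class[keep])
    return out


# deterministic digital-stain palette (RGB in [0, 1]); cycles beyond 10
_PALETTE = np.array(
    [
        [0.122, 0.467, 0.706], [1.000, 0.498, 0.055], [0.173, 0.627, 0.173],
        [0.839, 0.153, 0.157], [0.580, 0.404, 0.741], [0.549, 0.337, 0.294],
        [0.890, 0.467, 0.761], [0.498, 0.498, 0.498], [0.737, 0.741, 0.133],
        [0.090, 0.745, 0.812],
    ]
)


def render_digital_stain(cmap: ClusterMap) -> np.ndarray:
    """RGB image with one fixed color per cluster index; masked pixels black."""
    img = np.zeros(cmap.assignments.shape + (3,))
    for c in range(cmap.k):
        img[cmap.assignments == c] = _PALETTE[c % len(_PALETTE)]
    return img


def centroid_dendrogram(cmap: ClusterMap) -> str:
    """Ward-linkage agglomerative tree over the k centroids, in Newick."""
    k = cmap.k
    if k < 1:
        raise InvariantError("need at least one cluster")
    if k == 1:
        return "(c0);"
    link = hierarchy.linkage(cmap.centroids, method="ward")
    tree = hierarchy.to_tree(link)

    def newick(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"c{node.id}:{length:.6g}"
        left = newick(node.get_left(), node.dist)
        right = newick(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    left = newick(tree.get_left(), tree.dist)
    right = newick(tree.get_right(), tree.dist)
    return f"({left},{right});"
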