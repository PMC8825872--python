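"""Density-based clustering of the latent space and evaluation metrics.

HDBSCAN labels the latent embedding; cells the density clusterer declines
to assign are noise (label −1) and are reported separately. A conservative
rescue pass can re-cluster only the noise points at a smaller minimum
cluster size, so very small populations (the motivating case is a
14-cell platelet cluster) are not silently discarded; existing clusters
are never modified. Partition agreement uses the adjusted Rand index and
cluster compactness the silhouette coefficient, with noise either dropped
(default, matching how noise is reported separately from ARI) or treated
as per-point singleton clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm
from sklearn.cluster import HDBSCAN

__all__ = ["ClusterAssignment", "cluster_latent", "rescue_small_clusters",
           "adjusted_rand_index", "silhouette_coefficient",
           "cluster_overlap_percent", "match_clusters_to_reference",
           "default_min_cluster_size"]


@dataclass
class ClusterAssignment:
    """Integer label per cell; −1 marks noise (unassigned) cells."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        found = np.unique(self.labels[self.labels >= 0])
        if found.size and not np.array_equal(found, np.arange(found.size)):
            # re-number to contiguous 0..C-1, preserving order
            remap = {old: new for new, old in enumerate(found)}
            self.labels = np.array(
                [remap[l] if l >= 0 else -1 for l in self.labels], dtype=int)

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == -1))

    @property
    def n_clusters(self) -> int:
        return int(np.sum(np.unique(self.labels) >= 0))


def default_min_cluster_size(n_cells: int) -> int:
    """max(5, 0.5% of cells) — scales with the dataset but never below 5."""
    return max(5, int(round(0.005 * n_cells)))


def cluster_latent(Z: np.ndarray, min_cluster_size: int | None = None,
                   **hdbscan_kwargs) -> ClusterAssignment:
    """HDBSCAN on the latent embedding rows."""
    Z = np.asarray(Z, dtype=np.float64)
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(len(Z))
    if len(Z) < min_cluster_size:
        raise ValueError(
            f"{len(Z)} cells is fewer than min_cluster_size={min_cluster_size}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("latent embedding contains NaN or Inf")
    # identical points break HDBSCAN's density estimate; trivially one cluster
    if np.allclose(Z, Z[0]):
        return ClusterAssignment(labels=np.zeros(len(Z), dtype=int))
    hdbscan_kwargs.setdefault("copy", True)
    labels = HDBSCAN(min_cluster_size=min_cluster_size,
                     **hdbscan_kwargs).fit_predict(Z)
    return ClusterAssignment(labels=labels)


def rescue_small_clusters(assignment: ClusterAssignment, Z: np.ndarray,
                          rescue_min_size: int = 3) -> ClusterAssignment:
    """Re-cluster only the noise points at a reduced minimum size.

    Newly found groups get fresh labels; unassignable points stay noise.
    Existing clusters are untouched, so the cluster count never decreases.
    """
    noise_idx = np.flatnonzero(assignment.labels == -1)
    if noise_idx.size < rescue_min_size:
        return ClusterAssignment(labels=assignment.labels.copy())
    sub = np.asarray(Z)[noise_idx]
    if np.allclose(sub, sub[0]):
        sub_labels = np.zeros(len(sub), dtype=int)
    else:
        # allow_single_cluster: the noise subset typically hides at most one
        # tiny group, which default HDBSCAN (root excluded) would never report
        sub_labels = HDBSCAN(min_cluster_size=rescue_min_size,
                             allow_single_cluster=True, copy=True).fit_predict(sub)
    labels = assignment.labels.copy()
    offset = assignment.n_clusters
    for new_label in np.unique(sub_labels[sub_labels >= 0]):
        labels[noise_idx[sub_labels == new_label]] = offset
        offset += 1
    return ClusterAssignment(labels=labels)


def _as_labels(x) -> np.ndarray:
    if isinstance(x, ClusterAssignment):
        return x.labels
    return np.asarray(x, dtype=int)


def adjusted_rand_index(labels_a, labels_b, drop_noise: bool = False) -> float:
    """Chance-corrected Rand index in [−1, 1].

    With ``drop_noise`` cells labelled −1 in either partition are excluded
    (noise is then reported separately); otherwise each −1 cell counts as
    its own singleton cluster.
    """
    a, b = _as_labels(labels_a), _as_labels(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    if drop_noise:
        keep = (a >= 0) & (b >= 0)
        a, b = a[keep], b[keep]
    else:
        a, b = a.copy(), b.copy()
        for lab in (a, b):
            noise = lab == -1
            if noise.any():
                lab[noise] = lab.max() + 1 + np.arange(noise.sum())
    if len(a) == 0:
        raise ValueError("no cells left after dropping noise")
    return float(_skm.adjusted_rand_score(a, b))


def silhouette_coefficient(Z: np.ndarray, labels, drop_noise: bool = True,
                           per_cell: bool = False):
    """Silhouette (Euclidean) over non-noise cells; needs ≥ 2 clusters.

    Returns the mean coefficient, or the per-cell values (in the order of
    the kept cells) when ``per_cell`` is set.
    """
    lab = _as_labels(labels)
    Z = np.asarray(Z, dtype=np.float64)
    if drop_noise:
        keep = lab >= 0
        Z, lab = Z[keep], lab[keep]
    if np.unique(lab).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if per_cell:
        return _skm.silhouette_samples(Z, lab, metric="euclidean")
    return float(_skm.silhouette_score(Z, lab, metric="euclidean"))


def cluster_overlap_percent(found_cluster, reference_cluster) -> float:
    """100 · |found ∩ reference| / |reference|."""
    ref = set(reference_cluster)
    if not ref:
        raise ValueError("reference cluster is empty")
    return 100.0 * len(set(found_cluster) & ref) / len(ref)


def match_clusters_to_reference(assignment, reference_labels) -> dict:
    """Map each found cluster to the reference label it overlaps most.

    Ties go to the smaller reference label. Noise (−1) is never mapped.
    """
    found = _as_labels(assignment)
    ref = _as_labels(reference_labels)
    if len(found) != len(ref):
        raise ValueError("label vectors differ in length")
    mapping = {}
    for c in np.unique(found[found >= 0]):
        members = ref[found == c]
        members = members[members >= 0]
        if members.size == 0:
            continue
        labels, counts = np.unique(members, return_counts=True)
        mapping[int(c)] = int(labels[np.argmax(counts)])  # first max = smallest label
    return mapping
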