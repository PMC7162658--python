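"""Connectivity-based parcellation.

Voxels of a structure are clustered by the similarity of their connectivity
fingerprints: the injection x voxel strength matrix is z-scored per
injection, voxel columns are correlated, and agglomerative clustering on
the distance ``1 - r`` produces labellings for a range of cluster counts.
The count with the highest mean silhouette (same distance) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "TracerConnectome",
    "Parcellation",
    "zscore_connectome",
    "fingerprint_similarity_matrix",
    "hierarchical_parcellation",
    "dice_overlap",
    "erode_mask",
]


@dataclass
class TracerConnectome:
    """Injection x voxel strengths, z-scored across voxels per injection."""

    strengths: np.ndarray
    injection_labels: list[str] = field(default_factory=list)
    voxel_coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.strengths.ndim != 2:
            raise ValueError("strengths must be a 2D injection x voxel matrix")
        if not self.injection_labels:
            self.injection_labels = [f"inj{i}" for i in range(self.strengths.shape[0])]


@dataclass
class Parcellation:
    """Cluster labels per voxel plus the model-selection record."""

    labels: np.ndarray
    k: int | None
    labels_by_k: dict[int, np.ndarray]
    silhouette_by_k: dict[int, float]
    linkage_record: np.ndarray | None = None
    degenerate: bool = False


def zscore_connectome(
    raw: np.ndarray,
    injection_labels: Sequence[str] | None = None,
    voxel_coordinates: np.ndarray | None = None,
) -> TracerConnectome:
    """Standardise each injection row across voxels (population sd)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw matrix must be 2D (injection x voxel)")
    labels = list(injection_labels) if injection_labels else [f"inj{i}" for i in range(raw.shape[0])]
    sd = raw.std(axis=1, ddof=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"injection row {labels[bad[0]]!r} is constant and cannot be z-scored")
    z = (raw - raw.mean(axis=1, keepdims=True)) / sd[:, None]
    return TracerConnectome(z, labels, voxel_coordinates)


def fingerprint_similarity_matrix(conn: TracerConnectome) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between voxel columns.

    Constant voxel columns cannot be correlated; they are excluded with a
    warning.  Returns ``(matrix, kept_voxel_indices)``.
    """
    x = conn.strengths
    if x.shape[0] < 2:
        raise ValueError("need at least 2 injections to correlate voxel columns")
    sd = x.std(axis=0, ddof=0)
    kept = np.nonzero(sd > 0)[0]
    if kept.size < x.shape[1]:
        warnings.warn(
            f"excluding {x.shape[1] - kept.size} constant voxel column(s) from the similarity matrix",
            stacklevel=2,
        )
    xc = x[:, kept] - x[:, kept].mean(axis=0, keepdims=True)
    xn = xc / np.linalg.norm(xc, axis=0, keepdims=True)
    r = np.clip(xn.T @ xn, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r, kept


def hierarchical_parcellation(
    sim: np.ndarray,
    k_range: Iterable[int] = range(2, 11),
    linkage_method: str = "average",
) -> Parcellation:
    """Agglomerative clustering on ``d = 1 - r`` with silhouette selection.

    Labels are produced for every ``k`` in ``k_range`` by cutting the
    dendrogram; the selected ``k`` maximises the mean silhouette on the same
    distance, ties broken toward smaller ``k``.  If all pairwise distances
    are (numerically) zero the input is degenerate and no ``k`` is selected.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if ks[0] < 2 or ks[-1] > n:
        raise ValueError(f"k_range must lie within [2, {n}]")
    d = 1.0 - sim
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.all(condensed < 1e-12):
        return Parcellation(
            labels=np.ones(n, dtype=int),
            k=None,
            labels_by_k={},
            silhouette_by_k={},
            degenerate=True,
        )
    z = hierarchy.linkage(condensed, method=linkage_method)
    labels_by_k: dict[int, np.ndarray] = {}
    sil_by_k: dict[int, float] = {}
    for k in ks:
        lab = hierarchy.fcluster(z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        n_found = np.unique(lab).size
        if 2 <= n_found <= n - 1:
            sil_by_k[k] = float(silhouette_score(d, lab, metric="precomputed"))
        else:
            sil_by_k[k] = float("nan")
    finite = [k for k in ks if np.isfinite(sil_by_k[k])]
    if finite:
        best = max(sil_by_k[k] for k in finite)
        k_sel = min(k for k in finite if sil_by_k[k] == best)
    elif len(ks) == 1:
        k_sel = ks[0]
    else:
        k_sel = None
    labels = labels_by_k[k_sel] if k_sel is not None else np.ones(n, dtype=int)
    return Parcellation(
        labels=labels,
        k=k_sel,
        labels_by_k=labels_by_k,
        silhouette_by_k=sil_by_k,
        linkage_record=z,
    )


def dice_overlap(
    labels_a: np.ndarray | Parcellation,
    labels_b: np.ndarray | Parcellation,
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Cluster-pair Dice matrix plus a greedy best matching.

    ``Dice(a, b) = 2 |a & b| / (|a| + |b|)``.  The matching pairs clusters
    by descending Dice without reusing a cluster on either side.
    """
    la = labels_a.labels if isinstance(labels_a, Parcellation) else np.asarray(labels_a)
    lb = labels_b.labels if isinstance(labels_b, Parcellation) else np.asarray(labels_b)
    if la.shape != lb.shape:
        raise ValueError("parcellations must cover the same voxel set")
    ids_a = np.unique(la)
    ids_b = np.unique(lb)
    dice = np.zeros((ids_a.size, ids_b.size))
    for i, a in enumerate(ids_a):
        ma = la == a
        for j, b in enumerate(ids_b):
            mb = lb == b
            denom = ma.sum() + mb.sum()
            dice[i, j] = 2.0 * np.sum(ma & mb) / denom if denom else 0.0
    order = np.argsort(dice, axis=None)[::-1]
    used_a: set[int] = set()
    used_b: set[int] = set()
    matching: list[tuple[int, int, float]] = []
    for flat in order:
        i, j = np.unravel_index(flat, dice.shape)
        if i in used_a or j in used_b:
            continue
        matching.append((int(ids_a[i]), int(ids_b[j]), float(dice[i, j])))
        used_a.add(i)
        used_b.add(j)
        if len(matching) == min(ids_a.size, ids_b.size):
            break
    return dice, matching


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """1-voxel (per iteration) erosion of a boolean mask, 6-connectivity.

    Used to drop voxels bordering adjacent structures before parcellation.
    """
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    return ndimage.binary_erosion(mask.astype(bool), structure=structure, iterations=iterations)
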