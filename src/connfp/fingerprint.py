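"""Seed->target connectivity fingerprints and their comparison.

A fingerprint is the ordered vector of Pearson correlations between one
seed summary timeseries and a fixed set of target timeseries, optionally
Fisher r-to-z transformed.  Subject fingerprints are averaged by a trimmed
("robust") mean into templates; fingerprint uniqueness is tested by a
within-subject label-exchange permutation test on the Manhattan distance
between group robust means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import Eigenvariate, RegionTimeseries

__all__ = [
    "Fingerprint",
    "TemplateFingerprint",
    "DistanceTestResult",
    "compute_fingerprint",
    "fisher_z",
    "robust_mean_template",
    "manhattan_distance",
    "fingerprint_distance_test",
]

_CLIP = 1.0 - 1e-7


@dataclass
class Fingerprint:
    values: np.ndarray
    target_labels: tuple[str, ...]
    scale: str = "r"  # "r" or "fisher_z"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.target_labels):
            raise ValueError("one value per target label is required")
        if self.scale not in ("r", "fisher_z"):
            raise ValueError("scale must be 'r' or 'fisher_z'")
        if self.scale == "r" and np.any(np.abs(self.values) > 1):
            raise ValueError("r-scale fingerprint values must lie in [-1, 1]")


@dataclass
class TemplateFingerprint:
    values: np.ndarray
    dispersion: np.ndarray
    target_labels: tuple[str, ...]
    n_subjects: int
    scale: str = "r"


@dataclass
class DistanceTestResult:
    observed_distance: float
    p_value: float
    n_permutations: int


def _pearson_columns(seed: np.ndarray, targets: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    sc = seed - seed.mean()
    sn = np.linalg.norm(sc)
    if sn == 0:
        raise ValueError("seed series is constant")
    tc = targets - targets.mean(axis=0, keepdims=True)
    tn = np.linalg.norm(tc, axis=0)
    bad = np.nonzero(tn == 0)[0]
    if bad.size:
        raise ValueError(f"target series {labels[bad[0]]!r} is constant")
    return np.clip((tc.T @ sc) / (tn * sn), -1.0, 1.0)


def compute_fingerprint(
    seed_series: Eigenvariate | RegionTimeseries | np.ndarray,
    target_series: RegionTimeseries | np.ndarray,
    target_labels: Sequence[str] | None = None,
    scale: str = "r",
    subject_id: str | None = None,
) -> Fingerprint:
    """Pearson correlation of one seed series with each target series."""
    if isinstance(seed_series, Eigenvariate):
        seed = np.asarray(seed_series.series, dtype=float)
    elif isinstance(seed_series, RegionTimeseries):
        if seed_series.n_units != 1:
            raise ValueError("seed RegionTimeseries must have a single unit")
        seed = seed_series.values[:, 0]
    else:
        seed = np.asarray(seed_series, dtype=float).ravel()
    if isinstance(target_series, RegionTimeseries):
        targets = target_series.values
        labels = tuple(target_series.unit_labels)
    else:
        targets = np.asarray(target_series, dtype=float)
        labels = tuple(target_labels) if target_labels else tuple(f"t{i}" for i in range(targets.shape[1]))
    if targets.ndim != 2 or targets.shape[0] != seed.size:
        raise ValueError("seed and target series must share the time axis")
    if seed.size < 3:
        raise ValueError("need at least 3 timepoints")
    r = _pearson_columns(seed, targets, labels)
    if scale == "fisher_z":
        return Fingerprint(fisher_z(r), labels, "fisher_z", subject_id)
    return Fingerprint(r, labels, "r", subject_id)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """arctanh with clipping of |r| >= 1 to +/-(1 - 1e-7) (warned)."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        warnings.warn("clipping correlation(s) with |r| >= 1 before r-to-z", stacklevel=2)
    z = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def _stack(fps: Sequence[Fingerprint]) -> tuple[np.ndarray, tuple[str, ...], str]:
    if not fps:
        raise ValueError("need at least one fingerprint")
    labels = fps[0].target_labels
    scale = fps[0].scale
    for fp in fps[1:]:
        if fp.target_labels != labels:
            raise ValueError("fingerprints have mismatching target order")
        if fp.scale != scale:
            raise ValueError("fingerprints have mismatching scales")
    return np.vstack([fp.values for fp in fps]), labels, scale


def trimmed_mean(x: np.ndarray, trim: float = 0.2, axis: int = 0) -> np.ndarray:
    """Mean after dropping ``floor(trim * n)`` values from each tail."""
    x = np.sort(np.asarray(x, dtype=float), axis=axis)
    n = x.shape[axis]
    cut = int(np.floor(trim * n))
    if cut:
        sl = [slice(None)] * x.ndim
        sl[axis] = slice(cut, n - cut)
        x = x[tuple(sl)]
    return x.mean(axis=axis)


def robust_mean_template(
    fps: Sequence[Fingerprint],
    trim: float = 0.2,
    method: str = "trimmed",
) -> TemplateFingerprint:
    """Per-target robust mean of subject fingerprints.

    ``method`` is ``"trimmed"`` (default, 20% per tail), ``"mean"`` or
    ``"median"``; dispersion is the standard error of the retained values.
    """
    x, labels, scale = _stack(fps)
    n = x.shape[0]
    if method == "trimmed":
        cut = int(np.floor(trim * n))
        xs = np.sort(x, axis=0)
        kept = xs[cut : n - cut] if cut else xs
        values = kept.mean(axis=0)
    elif method == "mean":
        kept = x
        values = x.mean(axis=0)
    elif method == "median":
        kept = x
        values = np.median(x, axis=0)
    else:
        raise ValueError("method must be 'trimmed', 'mean' or 'median'")
    m = kept.shape[0]
    dispersion = kept.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros(x.shape[1])
    return TemplateFingerprint(values, dispersion, labels, n, scale)


def manhattan_distance(fp_a: Fingerprint | TemplateFingerprint, fp_b: Fingerprint | TemplateFingerprint) -> float:
    """L1 distance between two fingerprints on matching targets/scale."""
    if tuple(fp_a.target_labels) != tuple(fp_b.target_labels):
        raise ValueError("fingerprints have mismatching target order")
    if fp_a.scale != fp_b.scale:
        raise ValueError("fingerprints have mismatching scales")
    return float(np.sum(np.abs(np.asarray(fp_a.values) - np.asarray(fp_b.values))))


def fingerprint_distance_test(
    fps_a: Sequence[Fingerprint] | np.ndarray,
    fps_b: Sequence[Fingerprint] | np.ndarray,
    n_perm: int = 10_000,
    rng_seed: int = 0,
    trim: float = 0.2,
) -> DistanceTestResult:
    """Permutation test of the Manhattan distance between group robust means.

    The two groups are the per-subject fingerprints of two seeds, paired by
    subject.  The null is built by exchanging each subject's pair of
    fingerprints between the groups at random; the p-value uses the add-one
    estimator ``(1 + #{null >= observed}) / (n_perm + 1)`` so it is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray([fp.values for fp in fps_a]) if not isinstance(fps_a, np.ndarray) else np.asarray(fps_a, float)
    b = np.asarray([fp.values for fp in fps_b]) if not isinstance(fps_b, np.ndarray) else np.asarray(fps_b, float)
    if a.shape != b.shape:
        raise ValueError("groups must be paired: same subjects and targets")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if not isinstance(fps_a, np.ndarray) and not isinstance(fps_b, np.ndarray):
        la = tuple(fps_a[0].target_labels)
        lb = tuple(fps_b[0].target_labels)
        if la != lb:
            raise ValueError("fingerprints have mismatching target order")
    observed = float(np.sum(np.abs(trimmed_mean(a, trim) - trimmed_mean(b, trim))))
    rng = np.random.default_rng(rng_seed)
    swap = rng.random((n_perm, a.shape[0])) < 0.5
    a3 = np.where(swap[:, :, None], b[None], a[None])
    b3 = np.where(swap[:, :, None], a[None], b[None])
    null = np.abs(trimmed_mean(a3, trim, axis=1) - trimmed_mean(b3, trim, axis=1)).sum(axis=-1)
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return DistanceTestResult(observed_distance=observed, p_value=p, n_permutations=n_perm)
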