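"""Synthetic data generators with planted ground truth.

Three generators cover the inputs of the pipeline:

* a tracer connectome (injection x voxel strengths) with ``k`` planted
  voxel clusters whose mean injection profiles differ by a controlled
  separation;
* multi-subject "species" datasets in which every seed / voxel signal is a
  weighted mixture of independent unit-variance target signals plus
  Gaussian noise, so the expected seed->target correlation is the closed
  form ``w_t / sqrt(sum(w^2) + noise_sd^2)``;
* probabilistic atlases built from smooth unimodal bumps.

All generators are deterministic given their ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import RegionTimeseries

__all__ = [
    "TracerSimSpec",
    "SpeciesSimSpec",
    "GroundTruth",
    "SubjectData",
    "SpeciesDataset",
    "generate_tracer_matrix",
    "generate_species_dataset",
    "generate_prob_atlas",
    "block_voxel_labels",
    "species_spec_from_dict",
]


@dataclass(frozen=True)
class TracerSimSpec:
    """Parameters of a planted-cluster tracer connectome simulation.

    ``separation`` is the root-mean-square per-injection difference between
    cluster mean profiles, in the same units as ``noise_sd``.
    """

    n_injections: int
    n_voxels: int
    k_clusters: int
    separation: float = 5.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_injections < 2:
            raise ValueError("n_injections must be >= 2")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.n_voxels < self.k_clusters:
            raise ValueError("n_voxels must be >= k_clusters")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SpeciesSimSpec:
    """Parameters of a synthetic multi-subject species dataset.

    ``seed_defs`` maps each seed name to its loading vector over targets
    (the planted fingerprint); ``voxel_labels`` assigns each voxel either a
    seed name (its circuit) or the string ``"unique"`` for a circuit whose
    loading vector is orthogonal to every seed vector.
    """

    n_subjects: int
    n_timepoints: int
    tr_seconds: float
    target_labels: tuple[str, ...]
    seed_defs: Mapping[str, Sequence[float]]
    voxel_labels: tuple[str, ...]
    noise_sd: float = 1.0
    rng_seed: int = 0
    grid_shape: tuple[int, int, int] | None = None
    brain_labels: tuple[str, ...] | None = None
    ar_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_timepoints <= 10:
            raise ValueError("n_timepoints must be > 10")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        nt = len(self.target_labels)
        for name, w in self.seed_defs.items():
            if len(w) != nt:
                raise ValueError(
                    f"seed {name!r} loading vector has length {len(w)}, expected {nt}"
                )
        valid = set(self.seed_defs) | {"unique"}
        for lab in self.voxel_labels:
            if lab not in valid:
                raise ValueError(f"voxel label {lab!r} is not a seed label or 'unique'")
        if self.brain_labels is not None:
            for lab in self.brain_labels:
                if lab not in valid:
                    raise ValueError(f"brain voxel label {lab!r} is not a seed label or 'unique'")
        if self.grid_shape is not None and int(np.prod(self.grid_shape)) != len(self.voxel_labels):
            raise ValueError("grid_shape does not match the number of voxel labels")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a simulation run."""

    cluster_labels: np.ndarray | None = None
    seed_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    expected_fingerprints: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_labels: np.ndarray | None = None
    shared_map: np.ndarray | None = None
    unique_loading: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x

        payload = {
            "cluster_labels": conv(self.cluster_labels),
            "seed_loadings": conv(self.seed_loadings),
            "expected_fingerprints": conv(self.expected_fingerprints),
            "voxel_labels": conv(self.voxel_labels),
            "shared_map": conv(self.shared_map),
            "unique_loading": conv(self.unique_loading),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SubjectData:
    targets: RegionTimeseries
    seeds: RegionTimeseries
    voxels: RegionTimeseries
    brain: RegionTimeseries | None = None


@dataclass
class SpeciesDataset:
    subjects: list[SubjectData]
    truth: GroundTruth
    grid_shape: tuple[int, int, int] | None = None
    spec: SpeciesSimSpec | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def generate_tracer_matrix(spec: TracerSimSpec) -> tuple[np.ndarray, GroundTruth]:
    """Injection x voxel strength matrix with ``k`` planted voxel clusters.

    Each cluster's mean injection profile is drawn i.i.d. N(0, separation^2/2)
    per injection so the expected per-injection rms difference between two
    cluster profiles equals ``separation``; i.i.d. N(0, noise_sd^2) noise is
    added per voxel.
    """
    rng = np.random.default_rng(spec.rng_seed)
    profiles = rng.normal(0.0, spec.separation / np.sqrt(2.0), size=(spec.n_injections, spec.k_clusters))
    # contiguous blocks of as-equal-as-possible size
    sizes = np.full(spec.k_clusters, spec.n_voxels // spec.k_clusters)
    sizes[: spec.n_voxels % spec.k_clusters] += 1
    labels = np.repeat(np.arange(spec.k_clusters), sizes)
    matrix = profiles[:, labels] + rng.normal(0.0, spec.noise_sd, size=(spec.n_injections, spec.n_voxels))
    truth = GroundTruth(cluster_labels=labels)
    return matrix, truth


def block_voxel_labels(grid_shape: tuple[int, int, int], blocks: Mapping[str, tuple[int, int]]) -> tuple[str, ...]:
    """Label a 3D grid by axis-0 slabs: ``blocks[name] = (x_start, x_stop)``.

    Slabs must cover every x index exactly once.
    """
    nx = grid_shape[0]
    per_x: list[str | None] = [None] * nx
    for name, (x0, x1) in blocks.items():
        for x in range(x0, x1):
            if per_x[x] is not None:
                raise ValueError(f"x index {x} covered by more than one block")
            per_x[x] = name
    if any(v is None for v in per_x):
        raise ValueError("blocks do not cover the full x extent")
    vol = np.empty(grid_shape, dtype=object)
    for x in range(nx):
        vol[x, :, :] = per_x[x]
    return tuple(vol.ravel())


def _orthogonal_loading(seed_vectors: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A loading vector orthogonal to all seed vectors and the constant vector.

    Orthogonality to the constant vector keeps the Pearson correlation of
    the resulting fingerprint with every seed fingerprint near zero, not
    just the raw dot product.  Scaled to the mean seed-vector norm.
    """
    n_targets = seed_vectors.shape[1]
    basis = np.vstack([seed_vectors, np.ones((1, n_targets))])
    q, _ = np.linalg.qr(basis.T)  # columns span the seed + constant space
    for _ in range(50):
        v = rng.standard_normal(n_targets)
        v = v - q @ (q.T @ v)
        nrm = np.linalg.norm(v)
        if nrm > 1e-8:
            scale = float(np.mean(np.linalg.norm(seed_vectors, axis=1)))
            return v / nrm * (scale if scale > 0 else 1.0)
    raise ValueError("could not construct a loading vector orthogonal to the seeds")


def _target_signals(rng: np.random.Generator, n_time: int, n_targets: int, ar: float) -> np.ndarray:
    x = rng.standard_normal((n_time, n_targets))
    if ar > 0:
        for t in range(1, n_time):
            x[t] = ar * x[t - 1] + np.sqrt(1 - ar**2) * x[t]
    return x


def generate_species_dataset(spec: SpeciesSimSpec) -> SpeciesDataset:
    """Per-subject target / seed / voxel (and optional whole-brain) series.

    Targets are independent unit-variance Gaussian series.  Every seed or
    voxel series is ``sum_t w_t * target_t + eps`` with
    ``eps ~ N(0, noise_sd^2)`` and ``w`` taken from the seed definitions (or
    the orthogonal "unique" loading).
    """
    rng = np.random.default_rng(spec.rng_seed)
    seed_names = list(spec.seed_defs)
    W = np.array([np.asarray(spec.seed_defs[s], dtype=float) for s in seed_names])
    if not np.all(np.isfinite(W)):
        raise ValueError("seed loading vectors must be finite")
    unique_w = None
    if "unique" in spec.voxel_labels or (spec.brain_labels and "unique" in spec.brain_labels):
        unique_w = _orthogonal_loading(W, rng)

    def loading_for(label: str) -> np.ndarray:
        return unique_w if label == "unique" else np.asarray(spec.seed_defs[label], dtype=float)

    voxel_W = np.array([loading_for(lab) for lab in spec.voxel_labels])  # n_vox x n_targets
    brain_W = None
    if spec.brain_labels is not None:
        brain_W = np.array([loading_for(lab) for lab in spec.brain_labels])

    subjects = []
    for _ in range(spec.n_subjects):
        tgt = _target_signals(rng, spec.n_timepoints, len(spec.target_labels), spec.ar_coef)
        seeds = tgt @ W.T + rng.normal(0.0, spec.noise_sd, size=(spec.n_timepoints, len(seed_names)))
        voxels = tgt @ voxel_W.T + rng.normal(0.0, spec.noise_sd, size=(spec.n_timepoints, voxel_W.shape[0]))
        brain = None
        if brain_W is not None:
            bvox = tgt @ brain_W.T + rng.normal(0.0, spec.noise_sd, size=(spec.n_timepoints, brain_W.shape[0]))
            brain = RegionTimeseries(bvox, spec.tr_seconds, [f"bv{i}" for i in range(brain_W.shape[0])])
        subjects.append(
            SubjectData(
                targets=RegionTimeseries(tgt, spec.tr_seconds, list(spec.target_labels)),
                seeds=RegionTimeseries(seeds, spec.tr_seconds, seed_names),
                voxels=RegionTimeseries(voxels, spec.tr_seconds, [f"v{i}" for i in range(voxel_W.shape[0])]),
                brain=brain,
            )
        )

    expected = {
        name: W[i] / np.sqrt(np.sum(W[i] ** 2) + spec.noise_sd**2)
        for i, name in enumerate(seed_names)
    }
    truth = GroundTruth(
        seed_loadings={name: W[i].copy() for i, name in enumerate(seed_names)},
        expected_fingerprints=expected,
        voxel_labels=np.array(spec.voxel_labels, dtype=object),
        shared_map=np.array([lab != "unique" for lab in spec.voxel_labels]),
        unique_loading=unique_w,
    )
    return SpeciesDataset(subjects=subjects, truth=truth, grid_shape=spec.grid_shape, spec=spec)


def species_spec_from_dict(d: Mapping) -> SpeciesSimSpec:
    """Build a :class:`SpeciesSimSpec` from a plain (YAML-friendly) mapping.

    ``voxel_blocks`` (label -> [x_start, x_stop] slabs on ``grid_shape``)
    may be given instead of an explicit ``voxel_labels`` list.
    """
    d = dict(d)
    if "voxel_blocks" in d:
        if d.get("grid_shape") is None:
            raise ValueError("voxel_blocks requires grid_shape")
        grid = tuple(int(v) for v in d["grid_shape"])
        blocks = {k: (int(v[0]), int(v[1])) for k, v in d.pop("voxel_blocks").items()}
        d["voxel_labels"] = block_voxel_labels(grid, blocks)
    d["target_labels"] = tuple(d["target_labels"])
    d["voxel_labels"] = tuple(d["voxel_labels"])
    if d.get("grid_shape") is not None:
        d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
    if d.get("brain_labels") is not None:
        d["brain_labels"] = tuple(d["brain_labels"])
    d["seed_defs"] = {k: [float(x) for x in v] for k, v in d["seed_defs"].items()}
    return SpeciesSimSpec(**d)


def generate_prob_atlas(
    n_areas: int,
    grid_shape: tuple[int, int, int],
    peak_locations: Sequence[Sequence[float]] | None = None,
    spread: float = 2.0,
    rng_seed: int = 0,
    uniform: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Per-area probability volumes: smooth Gaussian bumps in [0, 1].

    Returns an ``(n_areas,) + grid_shape`` array and area labels.  With
    ``uniform=True`` every voxel of every area has the same probability.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    if spread <= 0:
        raise ValueError("spread must be positive")
    labels = [f"area{i + 1}" for i in range(n_areas)]
    if uniform:
        return np.full((n_areas,) + tuple(grid_shape), 0.5), labels
    rng = np.random.default_rng(rng_seed)
    if peak_locations is None:
        peak_locations = [
            [rng.uniform(0, s - 1) for s in grid_shape] for _ in range(n_areas)
        ]
    peaks = np.asarray(peak_locations, dtype=float)
    if peaks.shape != (n_areas, 3):
        raise ValueError("peak_locations must be n_areas x 3")
    for p in peaks:
        if np.any(p < 0) or np.any(p > np.asarray(grid_shape) - 1):
            raise ValueError("peak locations must lie inside the grid")
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij"), axis=-1)
    vols = np.empty((n_areas,) + tuple(grid_shape))
    for i, p in enumerate(peaks):
        d2 = np.sum((coords - p) ** 2, axis=-1)
        vols[i] = np.exp(-d2 / (2.0 * spread**2))
    return vols, labels
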