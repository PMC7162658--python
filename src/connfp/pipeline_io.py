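"""Formats, configuration and orchestration of a full A->B comparison run.

``run_comparison`` wires the stages together: conditioning, source seed
fingerprints and robust-mean templates, target voxelwise similarity maps,
group sign-flip TFCE inference, voxel classification, the unassigned-vs-
template conjunction and localisation summaries, recording every seed in a
run manifest so the run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import fingerprint as fp
from . import localise as loc
from . import match
from .preprocess import BandpassSpec, RegionTimeseries, condition_timeseries
from .synthdata import SpeciesDataset

__all__ = [
    "PipelineConfig",
    "ComparisonResult",
    "TARGET_MODELS",
    "read_volume",
    "write_volume",
    "check_same_grid",
    "run_comparison",
]

# Reduced (12-target) and extended (17-target) homolog models.
TARGET_MODELS: dict[str, tuple[str, ...]] = {
    "reduced": (
        "IL", "PL", "Cg", "RSP", "OFC", "BLA",
        "HPCd", "HPCv", "M1", "S1", "S2", "TeA",
    ),
    "extended": (
        "IL", "PL", "Cg", "RSP", "OFC", "BLA",
        "HPCd", "HPCv", "M1", "S1", "S2", "TeA",
        "9-46d", "9-46v", "44", "FPm", "SMA",
    ),
}


@dataclass
class PipelineConfig:
    """Settings of a comparison run; defaults follow standard practice
    (10,000 permutations, alpha 0.05, TFCE E=0.5 / H=2, voxel p 0.001 with
    cluster-extent FDR 0.05)."""

    n_perm: int = 10_000
    alpha: float = 0.05
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_dh: float | None = None
    connectivity: int = 6
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    rng_seed: int = 0
    target_model: str = "reduced"
    trim: float = 0.2
    condition: bool = False
    source_band: tuple[float, float] | None = None
    target_band: tuple[float, float] | None = None
    despike_threshold: float = 5.0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tfce_E <= 0 or self.tfce_H <= 0:
            raise ValueError("TFCE exponents must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must lie in (0, 1)")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must lie in (0, 1)")
        if self.target_model not in TARGET_MODELS and self.target_model != "custom":
            raise ValueError(f"unknown target model {self.target_model!r}")
        if not 0 <= self.trim < 0.5:
            raise ValueError("trim must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("source_band", "target_band"):
            if raw.get(key) is not None:
                raw[key] = tuple(float(v) for v in raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("source_band", "target_band"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class ComparisonResult:
    templates: dict[str, fp.TemplateFingerprint]
    distance_tests: pd.DataFrame
    similarity_stacks: dict[str, np.ndarray]
    stat_maps: dict[str, match.StatMap]
    assignment: match.AssignmentMap
    conjunction: np.ndarray
    volume_fractions: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI-1 volume; returns (data, affine). Gzip accepted."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def write_volume(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write data as NIfTI-1, preserving dtype and affine."""
    if affine is None:
        affine = np.eye(4)
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def check_same_grid(affine_a: np.ndarray, affine_b: np.ndarray, atol: float = 1e-6) -> None:
    if not np.allclose(affine_a, affine_b, atol=atol):
        raise ValueError("volumes are on different grids (affines differ)")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _hash_dataset(ds: SpeciesDataset) -> str:
    h = hashlib.sha256()
    for subj in ds.subjects:
        for ts in (subj.targets, subj.seeds, subj.voxels, subj.brain):
            if ts is not None:
                h.update(np.ascontiguousarray(ts.values).tobytes())
    return h.hexdigest()


def _conditioned(ts: RegionTimeseries, band: tuple[float, float] | None, cfg: PipelineConfig) -> RegionTimeseries:
    if not cfg.condition:
        return ts
    bp = BandpassSpec(*band) if band is not None else None
    return condition_timeseries(ts, band=bp, z_mad_threshold=cfg.despike_threshold)


def run_comparison(
    source: SpeciesDataset,
    target: SpeciesDataset,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> ComparisonResult:
    """Match every target-species voxel against source-species templates.

    Both datasets must use the same ordered target-region labels.  The
    target dataset needs a ``grid_shape`` so that its voxels map onto a 3D
    volume for TFCE.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    src_labels = tuple(source.subjects[0].targets.unit_labels)
    tgt_labels = tuple(target.subjects[0].targets.unit_labels)
    if src_labels != tgt_labels:
        missing = sorted(set(src_labels) ^ set(tgt_labels))
        raise ValueError(f"target-model mismatch between species; differing targets: {missing}")
    if target.grid_shape is None:
        raise ValueError("target dataset needs a grid_shape for voxelwise inference")
    grid = tuple(target.grid_shape)

    ss = np.random.SeedSequence(cfg.rng_seed)
    seeds = iter(ss.generate_state(64))

    # --- source: per-subject seed fingerprints -> templates -------------
    seed_names = list(source.subjects[0].seeds.unit_labels)
    per_seed_fps: dict[str, list[fp.Fingerprint]] = {s: [] for s in seed_names}
    for i, subj in enumerate(source.subjects):
        tgt_ts = _conditioned(subj.targets, cfg.source_band, cfg)
        seed_ts = _conditioned(subj.seeds, cfg.source_band, cfg)
        for j, sname in enumerate(seed_names):
            per_seed_fps[sname].append(
                fp.compute_fingerprint(seed_ts.values[:, j], tgt_ts, src_labels, subject_id=f"s{i}")
            )
    templates = {s: fp.robust_mean_template(per_seed_fps[s], trim=cfg.trim) for s in seed_names}

    # --- within-source fingerprint uniqueness ---------------------------
    rows = []
    for a_i in range(len(seed_names)):
        for b_i in range(a_i + 1, len(seed_names)):
            a, b = seed_names[a_i], seed_names[b_i]
            res = fp.fingerprint_distance_test(
                per_seed_fps[a], per_seed_fps[b],
                n_perm=cfg.n_perm, rng_seed=int(next(seeds)), trim=cfg.trim,
            )
            rows.append({"seed_a": a, "seed_b": b,
                         "distance": res.observed_distance, "p_value": res.p_value,
                         "n_permutations": res.n_permutations})
    distance_df = pd.DataFrame(rows)

    # --- target: voxel fingerprints -> similarity stacks ----------------
    n_vox = target.subjects[0].voxels.n_units
    stacks = {s: np.empty((target.n_subjects, n_vox)) for s in seed_names}
    for i, subj in enumerate(target.subjects):
        tgt_ts = _conditioned(subj.targets, cfg.target_band, cfg)
        vox_ts = _conditioned(subj.voxels, cfg.target_band, cfg)
        t = tgt_ts.values - tgt_ts.values.mean(axis=0, keepdims=True)
        v = vox_ts.values - vox_ts.values.mean(axis=0, keepdims=True)
        tn = np.linalg.norm(t, axis=0)
        vn = np.linalg.norm(v, axis=0)
        tn[tn == 0] = np.inf
        vn[vn == 0] = np.inf
        voxel_fps = np.clip((v.T @ t) / np.outer(vn, tn), -1.0, 1.0)
        for s in seed_names:
            stacks[s][i] = match.voxelwise_similarity_map(voxel_fps, templates[s].values)

    # --- group inference per template -----------------------------------
    stat_maps: dict[str, match.StatMap] = {}
    for s in seed_names:
        stat_maps[s] = match.group_onesample_tfce(
            stacks[s].reshape((target.n_subjects,) + grid),
            n_perm=cfg.n_perm, alpha=cfg.alpha, rng_seed=int(next(seeds)),
            E=cfg.tfce_E, H=cfg.tfce_H, dh=cfg.tfce_dh, connectivity=cfg.connectivity,
        )
    assignment = match.classify_voxels(stat_maps, alpha=cfg.alpha)

    # --- conjunction: unassigned evidence vs each template --------------
    evidence = match.unassigned_evidence(stacks)
    conj, _ = match.conjunction_difference(
        evidence.reshape((target.n_subjects,) + grid),
        {s: stacks[s].reshape((target.n_subjects,) + grid) for s in seed_names},
        n_perm=cfg.n_perm, alpha=cfg.alpha, rng_seed=int(next(seeds)),
        E=cfg.tfce_E, H=cfg.tfce_H, dh=cfg.tfce_dh, connectivity=cfg.connectivity,
    )
    assignment.sig_different = conj

    # --- localisation against planted circuits --------------------------
    fractions = None
    if target.truth.voxel_labels is not None:
        vl = np.asarray(target.truth.voxel_labels, dtype=object).reshape(grid)
        structures = {str(lab): vl == lab for lab in sorted(set(vl.ravel()))}
        label_masks = {f"assigned_{s}": assignment.matched[s] for s in seed_names}
        label_masks["unassigned"] = assignment.unassigned
        label_masks["sig_different"] = conj
        fractions = loc.volume_fractions(label_masks, structures)

    manifest = {
        "package": "connfp",
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "rng_seed": cfg.rng_seed,
        "source_hash": _hash_dataset(source),
        "target_hash": _hash_dataset(target),
        "templates": seed_names,
        "grid_shape": list(grid),
    }

    result = ComparisonResult(
        templates=templates,
        distance_tests=distance_df,
        similarity_stacks=stacks,
        stat_maps=stat_maps,
        assignment=assignment,
        conjunction=conj,
        volume_fractions=fractions,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, grid, Path(out_dir))
    return result


def _write_outputs(result: ComparisonResult, grid: tuple[int, ...], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tmpl_rows = []
    for s, t in result.templates.items():
        for lab, v, d in zip(t.target_labels, t.values, t.dispersion):
            tmpl_rows.append({"seed": s, "target": lab, "value": v, "dispersion": d})
    pd.DataFrame(tmpl_rows).to_csv(out_dir / "templates.csv", index=False)
    result.distance_tests.to_csv(out_dir / "distance_tests.csv", index=False)
    if result.volume_fractions is not None:
        result.volume_fractions.to_csv(out_dir / "volume_fractions.csv")
    for s, sm in result.stat_maps.items():
        write_volume(sm.t.reshape(grid), out_dir / f"tmap_{s}.nii.gz")
        write_volume(sm.p_corrected.reshape(grid), out_dir / f"pcorr_{s}.nii.gz")
    write_volume(result.assignment.unassigned, out_dir / "unassigned.nii.gz")
    write_volume(result.conjunction, out_dir / "sig_different.nii.gz")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
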