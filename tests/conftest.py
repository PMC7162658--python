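import numpy as np
import pytest

from connfp.synthdata import SpeciesSimSpec, block_voxel_labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def hadamard12_loadings():
    """Four mutually orthogonal, zero-mean unit loading vectors over 12 targets."""
    h = np.array([
        [1, 1, 1, 1, 1, 1, -1, -1, -1, -1, -1, -1],
        [1, 1, 1, -1, -1, -1, 1, 1, 1, -1, -1, -1],
        [1, 1, -1, 1, -1, -1, -1, -1, 1, 1, 1, -1],
        [1, -1, 1, -1, 1, -1, 1, -1, 1, -1, 1, -1],
    ], dtype=float)
    h /= np.linalg.norm(h, axis=1, keepdims=True)
    return h


def two_species_specs(
    n_subjects=20,
    n_timepoints=500,
    seed_a=1,
    seed_b=2,
    grid_shape=(6, 6, 6),
    noise_sd=1.0,
):
    """Two species sharing circuits c1/c2; species B has a third, unique circuit."""
    h = hadamard12_loadings()
    targets = tuple(f"T{i}" for i in range(12))
    seed_defs = {"c1": h[0], "c2": h[1], "c3": h[2]}
    spec_a = SpeciesSimSpec(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        tr_seconds=1.0,
        target_labels=targets,
        seed_defs=seed_defs,
        voxel_labels=("c1", "c2", "c3"),
        noise_sd=noise_sd,
        rng_seed=seed_a,
    )
    nx = grid_shape[0]
    blocks = {"c1": (0, nx // 3), "c2": (nx // 3, 2 * nx // 3), "unique": (2 * nx // 3, nx)}
    spec_b = SpeciesSimSpec(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        tr_seconds=1.0,
        target_labels=targets,
        seed_defs=seed_defs,
        voxel_labels=block_voxel_labels(grid_shape, blocks),
        noise_sd=noise_sd,
        rng_seed=seed_b,
        grid_shape=grid_shape,
    )
    return spec_a, spec_b
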