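"""Cross-species voxelwise fingerprint matching and group inference.

Per-subject similarity maps (Fisher-z of the correlation between a voxel's
fingerprint and a template fingerprint) are fed into a one-sample sign-flip
permutation test with threshold-free cluster enhancement (TFCE) and
max-statistic family-wise correction.  Voxels significantly similar to a
template are assigned to it (multi-membership allowed); voxels similar to
no template are "unassigned".  A minimum-statistic conjunction of paired
sign-flip contrasts flags voxels whose unassigned evidence significantly
exceeds the similarity to every template.  Whole-brain connectivity maps
use a weighted seed timeseries with cluster-extent FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from numba import njit
from scipy import ndimage, stats

from .fingerprint import _CLIP

__all__ = [
    "StatMap",
    "AssignmentMap",
    "voxelwise_similarity_map",
    "tfce_enhance",
    "group_onesample_tfce",
    "classify_voxels",
    "unassigned_evidence",
    "conjunction_difference",
    "weighted_timeseries",
    "wholebrain_connectivity_map",
]

T_CAP = 100.0  # cap for t-statistics with degenerate (zero) variance


@dataclass
class StatMap:
    t: np.ndarray
    p_corrected: np.ndarray
    n_subjects: int
    n_permutations: int
    tfce_params: dict = field(default_factory=dict)


@dataclass
class AssignmentMap:
    matched: dict[str, np.ndarray]
    unassigned: np.ndarray
    sig_different: np.ndarray | None = None

    def label_sets(self) -> np.ndarray:
        """Per-voxel frozenset of matched template ids (object array)."""
        shape = self.unassigned.shape
        out = np.empty(shape, dtype=object)
        for idx in np.ndindex(shape):
            out[idx] = frozenset(k for k, m in self.matched.items() if m[idx])
        return out


# ---------------------------------------------------------------------------
# similarity maps
# ---------------------------------------------------------------------------

def voxelwise_similarity_map(voxel_fps: np.ndarray, template_values: np.ndarray) -> np.ndarray:
    """Fisher-z of the Pearson r between each voxel fingerprint and a template.

    ``voxel_fps`` is an (n_voxels, n_targets) array for one subject.
    Constant voxel fingerprints get similarity 0 (with a warning).
    """
    x = np.asarray(voxel_fps, dtype=float)
    t = np.asarray(template_values, dtype=float)
    if x.ndim != 2 or x.shape[1] != t.size:
        raise ValueError("voxel fingerprints and template must share the target axis")
    if t.size < 3:
        raise ValueError("need at least 3 targets to correlate fingerprints")
    tc = t - t.mean()
    tn = np.linalg.norm(tc)
    if tn == 0:
        raise ValueError("template fingerprint is constant")
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    const = xn == 0
    if np.any(const):
        warnings.warn(f"{int(const.sum())} constant voxel fingerprint(s) set to similarity 0", stacklevel=2)
    xn[const] = 1.0
    r = np.clip((xc @ tc) / (xn * tn), -_CLIP, _CLIP)
    z = np.arctanh(r)
    z[const] = 0.0
    return z


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _neighbor_table(shape: tuple[int, int, int], connectivity: int) -> np.ndarray:
    """Flat-index neighbour list, padded with -1, for a 3D grid."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    offsets = []
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        order = sum(o != 0 for o in off)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append(off)
    nx, ny, nz = shape
    idx = np.arange(nx * ny * nz).reshape(shape)
    nbr = np.full((nx * ny * nz, len(offsets)), -1, dtype=np.int64)
    for j, (dx, dy, dz) in enumerate(offsets):
        src = idx[
            max(0, -dx) : nx - max(0, dx),
            max(0, -dy) : ny - max(0, dy),
            max(0, -dz) : nz - max(0, dz),
        ]
        dst = idx[
            max(0, dx) : nx - max(0, -dx),
            max(0, dy) : ny - max(0, -dy),
            max(0, dz) : nz - max(0, -dz),
        ]
        nbr[src.ravel(), j] = dst.ravel()
    # compact: move valid entries to the front so kernels can early-break
    out = np.full_like(nbr, -1)
    for i in range(nbr.shape[0]):
        vals = nbr[i][nbr[i] >= 0]
        out[i, : vals.size] = vals
    return out


@njit(cache=False)
def _uf_find(parent, v):  # pragma: no cover - numba
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=False)
def _tfce_kernel(vals, nbr, E, H, dh):  # pragma: no cover - numba
    n = vals.shape[0]
    out = np.zeros(n)
    vmax = 0.0
    for i in range(n):
        if vals[i] > vmax:
            vmax = vals[i]
    if vmax <= 0.0 or dh <= 0.0:
        return out
    order = np.argsort(vals)[::-1]
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    active = np.zeros(n, dtype=np.uint8)
    nsteps = int(np.floor(vmax / dh + 1e-12))
    ptr = 0
    for s in range(nsteps, 0, -1):
        h = s * dh
        while ptr < n and vals[order[ptr]] >= h:
            v = order[ptr]
            active[v] = 1
            for j in range(nbr.shape[1]):
                u = nbr[v, j]
                if u < 0:
                    break
                if active[u]:
                    ra = _uf_find(parent, v)
                    rb = _uf_find(parent, u)
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            ptr += 1
        inc = (h**H) * dh
        for i in range(ptr):
            v = order[i]
            r = _uf_find(parent, v)
            out[v] += (size[r] ** E) * inc
    return out


def tfce_enhance(
    stat_volume: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 6,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed 3D statistic map.

    For each voxel ``v``, sums ``extent(v, h)^E * h^H * dh`` over thresholds
    ``h = dh, 2 dh, ... <= height(v)``, where ``extent`` is the size of the
    connected suprathreshold component containing ``v`` at threshold ``h``.
    Negative values are enhanced on the negated map and returned with their
    sign.  ``dh`` defaults to ``max(|stat|) / 100``.
    """
    vol = np.asarray(stat_volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("stat volume must be 3D")
    if E <= 0 or H <= 0:
        raise ValueError("E and H must be positive")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    vmax = float(np.max(np.abs(vol))) if vol.size else 0.0
    if vmax == 0.0:
        return np.zeros_like(vol)
    if dh is None:
        dh = vmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    nbr = _neighbor_table(vol.shape, connectivity)
    flat = vol.ravel()
    pos = _tfce_kernel(np.maximum(flat, 0.0), nbr, E, H, dh)
    out = pos
    if np.any(flat < 0):
        neg = _tfce_kernel(np.maximum(-flat, 0.0), nbr, E, H, dh)
        out = pos - neg
    return out.reshape(vol.shape)


# ---------------------------------------------------------------------------
# group inference
# ---------------------------------------------------------------------------

def _onesample_t(signs: np.ndarray, x: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t for every sign pattern (rows of ``signs``)."""
    n = x.shape[0]
    mean = signs @ x / n
    var = (sumsq[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.where(var == 0, np.sign(mean) * T_CAP, t)
    return np.clip(np.nan_to_num(t, nan=0.0), -T_CAP, T_CAP)


def _sign_patterns(n_subjects: int, n_perm: int, rng: np.random.Generator, max_exact: int) -> tuple[np.ndarray, bool]:
    if n_subjects <= max_exact and 2**n_subjects <= max(n_perm, 2**n_subjects):
        bits = np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects)[None, :]
        return np.where(bits & 1, -1.0, 1.0), True
    return rng.choice([-1.0, 1.0], size=(n_perm, n_subjects)), False


def group_onesample_tfce(
    maps: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 6,
    max_exact: int = 12,
) -> StatMap:
    """One-sample sign-flip permutation test with TFCE FWE correction.

    ``maps`` is (n_subjects, nx, ny, nz).  The positive direction is tested:
    corrected p per voxel is the add-one proportion of permutation
    max-TFCE statistics at or above the voxel's observed TFCE value.  When
    ``n_subjects <= max_exact`` all ``2^n`` sign patterns are enumerated
    (exact test, identity pattern included in the null).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (n_subjects, nx, ny, nz)")
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    shape = maps.shape[1:]
    x = maps.reshape(n, -1)
    sumsq = np.sum(x**2, axis=0)
    t_obs = _onesample_t(np.ones((1, n)), x, sumsq)[0]
    if dh is None:
        vmax = float(np.max(np.abs(t_obs)))
        dh = vmax / 100.0 if vmax > 0 else 1.0
    tfce_obs = tfce_enhance(t_obs.reshape(shape), E, H, dh, connectivity)
    rng = np.random.default_rng(rng_seed)
    signs, exact = _sign_patterns(n, n_perm, rng, max_exact)
    t_null = _onesample_t(signs, x, sumsq)
    n_null = signs.shape[0]
    max_null = np.empty(n_null)
    for i in range(n_null):
        enh = tfce_enhance(t_null[i].reshape(shape), E, H, dh, connectivity)
        max_null[i] = enh.max() if enh.size else 0.0
    sorted_null = np.sort(max_null)
    counts = n_null - np.searchsorted(sorted_null, tfce_obs.ravel(), side="left")
    if exact:
        p = counts / n_null
    else:
        p = (1.0 + counts) / (n_null + 1.0)
    p = np.clip(p, 1.0 / (n_null + (0 if exact else 1)), 1.0).reshape(shape)
    return StatMap(
        t=t_obs.reshape(shape),
        p_corrected=p,
        n_subjects=n,
        n_permutations=n_null,
        tfce_params={"E": E, "H": H, "dh": dh, "connectivity": connectivity},
    )


def classify_voxels(stat_maps: dict[str, StatMap], alpha: float = 0.05) -> AssignmentMap:
    """Assign each voxel to every template with corrected p < alpha.

    Voxels significant for no template are unassigned; multi-membership is
    preserved (no forced winner).
    """
    if not stat_maps:
        raise ValueError("need at least one statistic map")
    shapes = {sm.p_corrected.shape for sm in stat_maps.values()}
    if len(shapes) != 1:
        raise ValueError("statistic maps are on different grids")
    matched = {k: sm.p_corrected < alpha for k, sm in stat_maps.items()}
    any_match = np.zeros(next(iter(shapes)), dtype=bool)
    for m in matched.values():
        any_match |= m
    return AssignmentMap(matched=matched, unassigned=~any_match)


def unassigned_evidence(similarity_stacks: dict[str, np.ndarray]) -> np.ndarray:
    """Per-subject unassigned-evidence maps: ``1 - max_k z_k``.

    ``similarity_stacks[k]`` is the (n_subjects, ...) z-map stack for
    template ``k``.
    """
    stacks = np.stack(list(similarity_stacks.values()))
    return 1.0 - stacks.max(axis=0)


def conjunction_difference(
    unassigned_maps: np.ndarray,
    assigned_maps: dict[str, np.ndarray],
    n_perm: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    **tfce_params,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Minimum-statistic conjunction of paired sign-flip contrasts.

    For each template ``k`` the paired difference (unassigned evidence minus
    similarity to ``k``) is tested with a one-sample sign-flip TFCE test;
    the conjunction mask is the intersection of all per-template corrected
    significance masks.  Returns ``(conjunction_mask, per_template_masks)``.
    """
    u = np.asarray(unassigned_maps, dtype=float)
    masks: dict[str, np.ndarray] = {}
    conj: np.ndarray | None = None
    seeds = np.random.SeedSequence(rng_seed).spawn(len(assigned_maps))
    for ss, (k, a) in zip(seeds, sorted(assigned_maps.items())):
        a = np.asarray(a, dtype=float)
        if a.shape != u.shape:
            raise ValueError(f"template {k!r} maps are not paired with the unassigned maps")
        sm = group_onesample_tfce(
            u - a, n_perm=n_perm, alpha=alpha, rng_seed=int(ss.generate_state(1)[0]), **tfce_params
        )
        masks[k] = sm.p_corrected < alpha
        conj = masks[k].copy() if conj is None else (conj & masks[k])
    assert conj is not None
    return conj, masks


# ---------------------------------------------------------------------------
# whole-brain connectivity from a weighted seed
# ---------------------------------------------------------------------------

def weighted_timeseries(t_map: np.ndarray | StatMap, voxel_ts: np.ndarray) -> np.ndarray:
    """Weighted sum of voxel series, weights = positive part of the t-map."""
    t = t_map.t if isinstance(t_map, StatMap) else np.asarray(t_map, dtype=float)
    t = t.ravel()
    x = np.asarray(voxel_ts, dtype=float)
    if x.ndim != 2 or x.shape[1] != t.size:
        raise ValueError("voxel timeseries must be time x voxel matching the t-map")
    w = np.maximum(t, 0.0)
    total = w.sum()
    if total == 0:
        raise ValueError("no voxel with positive t-statistic")
    return x @ (w / total)


def wholebrain_connectivity_map(
    weighted_series: list[np.ndarray],
    brain_voxel_ts: list[np.ndarray],
    grid_shape: tuple[int, int, int],
    n_perm: int = 10_000,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    rng_seed: int = 0,
    connectivity: int = 6,
) -> dict:
    """Cluster-extent corrected group map of seed-to-brain connectivity.

    Per subject, the weighted seed series is correlated with every brain
    voxel (Fisher-z); a one-sample t-map is thresholded at the uncorrected
    ``voxel_p`` (one-sided), clusters are formed, and cluster sizes are
    compared against a sign-flip null of maximum cluster sizes, with
    Benjamini-Hochberg correction across observed clusters.
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must lie in (0, 1)")
    n = len(weighted_series)
    if n < 2 or len(brain_voxel_ts) != n:
        raise ValueError("need >= 2 paired subjects")
    zmaps = []
    for s, b in zip(weighted_series, brain_voxel_ts):
        s = np.asarray(s, float).ravel()
        b = np.asarray(b, float)
        sc = s - s.mean()
        bc = b - b.mean(axis=0, keepdims=True)
        denom = np.linalg.norm(bc, axis=0) * np.linalg.norm(sc)
        denom[denom == 0] = np.inf
        r = np.clip((bc.T @ sc) / denom, -_CLIP, _CLIP)
        zmaps.append(np.arctanh(r))
    x = np.vstack(zmaps)
    sumsq = np.sum(x**2, axis=0)
    t_obs = _onesample_t(np.ones((1, n)), x, sumsq)[0]
    t_crit = float(stats.t.ppf(1.0 - voxel_p, df=n - 1))
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])

    def max_cluster_size(tflat: np.ndarray) -> int:
        lab, nlab = ndimage.label((tflat > t_crit).reshape(grid_shape), structure=structure)
        if nlab == 0:
            return 0
        return int(np.max(ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))))

    rng = np.random.default_rng(rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _onesample_t(signs, x, sumsq)
    null_sizes = np.array([max_cluster_size(t_null[i]) for i in range(n_perm)])
    labels, n_clusters = ndimage.label((t_obs > t_crit).reshape(grid_shape), structure=structure)
    cluster_ids = np.arange(1, n_clusters + 1)
    sizes = ndimage.sum_labels(np.ones(grid_shape), labels, index=cluster_ids).astype(int) if n_clusters else np.array([], int)
    p_raw = np.array([(1.0 + np.sum(null_sizes >= s)) / (n_perm + 1.0) for s in sizes])
    if p_raw.size:
        p_fdr = stats.false_discovery_control(p_raw, method="bh")
    else:
        p_fdr = p_raw
    sig_mask = np.zeros(grid_shape, dtype=bool)
    for cid, p in zip(cluster_ids, p_fdr):
        if p < cluster_alpha:
            sig_mask |= labels == cid
    return {
        "t": t_obs.reshape(grid_shape),
        "clusters": labels,
        "cluster_sizes": sizes,
        "cluster_p_raw": p_raw,
        "cluster_p_fdr": p_fdr,
        "significant_mask": sig_mask,
        "t_critical": t_crit,
    }
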