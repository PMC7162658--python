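"""Timeseries conditioning and seed summary extraction.

Conditioning comprises linear detrending, despiking (running-median / MAD
clipping) and zero-phase Butterworth bandpass filtering.  Multi-voxel seed
regions are summarised by their principal eigenvariate (first left singular
vector of the centred time x voxel matrix) together with the fraction of
variance it explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "RegionTimeseries",
    "BandpassSpec",
    "Eigenvariate",
    "bandpass_filter",
    "detrend_linear",
    "despike",
    "principal_eigenvariate",
    "condition_timeseries",
]


@dataclass
class RegionTimeseries:
    """A time x unit matrix of signals sampled at a fixed interval.

    Units may be voxels or regions; ``unit_labels`` names them in column
    order.
    """

    values: np.ndarray
    tr_seconds: float
    unit_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a time x unit matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.unit_labels:
            self.unit_labels = [f"u{i}" for i in range(self.values.shape[1])]
        if len(self.unit_labels) != self.values.shape[1]:
            raise ValueError("unit_labels length must match number of units")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "RegionTimeseries":
        return RegionTimeseries(values, self.tr_seconds, list(self.unit_labels))


@dataclass(frozen=True)
class BandpassSpec:
    """Passband edges in Hz; must satisfy 0 < low < high."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.low_hz <= 0:
            raise ValueError("low_hz must be positive")
        if self.high_hz <= self.low_hz:
            raise ValueError("high_hz must exceed low_hz")

    def validate_for_tr(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.high_hz >= nyquist:
            raise ValueError(
                f"high_hz={self.high_hz} is at or above the Nyquist frequency "
                f"{nyquist:.4g} Hz for tr={tr_seconds}s; the low-pass edge must "
                "sit safely below the sampling limit (a span of several volumes "
                "per cycle) to be realisable"
            )


@dataclass
class Eigenvariate:
    """Summary series of a multi-voxel seed plus its explained variance."""

    series: np.ndarray
    variance_explained: float


def bandpass_filter(ts: RegionTimeseries, band: BandpassSpec, order: int = 4) -> RegionTimeseries:
    """Zero-phase Butterworth bandpass; removes the mean as a side effect.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    effective attenuation is twice the one-pass roll-off and the phase
    response is identically zero.  The default order gives > 90%
    amplitude rejection one third of an octave beyond the passband edge.
    """
    band.validate_for_tr(ts.tr_seconds)
    fs = 1.0 / ts.tr_seconds
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, ts.values, axis=0)
    out = out - out.mean(axis=0, keepdims=True)
    return ts.copy_with(out)


def detrend_linear(ts: RegionTimeseries) -> RegionTimeseries:
    """Remove the per-unit ordinary-least-squares line (and mean)."""
    if ts.n_time < 3:
        raise ValueError("linear detrending requires at least 3 timepoints")
    out = signal.detrend(ts.values, axis=0, type="linear")
    return ts.copy_with(out)


def despike(ts: RegionTimeseries, z_mad_threshold: float = 5.0, window: int = 11) -> RegionTimeseries:
    """Replace samples deviating > threshold x MAD from a running median.

    The running median uses an odd ``window`` with edge replication; the MAD
    is a single per-unit scalar (median absolute deviation from the running
    median).  Units with MAD == 0 (e.g. constant series) are returned
    unchanged.
    """
    if z_mad_threshold <= 0:
        raise ValueError("z_mad_threshold must be positive")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    x = ts.values
    run_med = ndimage.median_filter(x, size=(window, 1), mode="nearest")
    dev = np.abs(x - run_med)
    mad = np.median(dev, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        bad = (dev > z_mad_threshold * mad) & (mad > 0)
    out = np.where(bad, run_med, x)
    return ts.copy_with(out)


def principal_eigenvariate(seed: RegionTimeseries | np.ndarray, normalise_voxels: bool = False) -> Eigenvariate:
    """First singular-vector summary of a time x voxel seed matrix.

    Columns are mean-centred (and optionally variance-normalised); the
    returned series is the first left singular vector scaled to unit
    variance, with its sign fixed so that it correlates non-negatively with
    the seed-mean timeseries.
    """
    x = seed.values if isinstance(seed, RegionTimeseries) else np.asarray(seed, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(xc):
        raise ValueError("seed matrix is constant (all-zero after centring)")
    if normalise_voxels:
        sd = xc.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    series = u[:, 0].copy()
    mean_ts = xc.mean(axis=1)
    proj = float(series @ mean_ts)
    if proj < 0:
        series = -series
    elif proj == 0:
        # deterministic tie-break: first nonzero element positive
        nz = np.nonzero(series)[0]
        if nz.size and series[nz[0]] < 0:
            series = -series
    sd = series.std(ddof=1)
    if sd > 0:
        series = series / sd
    total = float(np.sum(s**2))
    ve = float(s[0] ** 2 / total)
    return Eigenvariate(series=series, variance_explained=ve)


def condition_timeseries(
    ts: RegionTimeseries,
    band: BandpassSpec | None = None,
    z_mad_threshold: float = 5.0,
    order: tuple[str, ...] = ("detrend", "despike", "bandpass"),
) -> RegionTimeseries:
    """Apply the standard conditioning chain in the given order."""
    steps = {
        "detrend": detrend_linear,
        "despike": lambda t: despike(t, z_mad_threshold),
        "bandpass": (lambda t: bandpass_filter(t, band)) if band is not None else None,
    }
    out = ts
    for name in order:
        fn = steps.get(name)
        if fn is None:
            if name == "bandpass":
                continue
            raise ValueError(f"unknown conditioning step {name!r}")
        out = fn(out)
    return out
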