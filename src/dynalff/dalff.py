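"""Static and sliding-window dynamic ALFF.

ALFF (amplitude of low-frequency fluctuations) is defined here as the mean
single-sided DFT amplitude (2/N)|X(f)| across the frequency bins inside the
pass-band (conventionally 0.01-0.08 Hz).  Dynamic ALFF recomputes this inside
sliding windows; the dispersion of windowed ALFF across windows (SD, or the
coefficient of variation CV = SD/mean) quantifies temporal variability of
local spontaneous activity.

The windowed amplitudes are computed by complex correlation of each voxel
series with per-bin Fourier kernels (one FFT-based convolution per in-band
bin), which is algebraically identical to a per-window demeaned DFT: the mean
only affects bin 0, which is never in-band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .cohort import BoldRun, band_bins

__all__ = [
    "WindowSpec",
    "AlffMap",
    "DalffMaps",
    "window_indices",
    "compute_alff",
    "compute_static_alff",
    "compute_dynamic_alff",
    "standardize_map",
]

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.01, 0.08)
_MEAN_EPS = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in volumes: length w, step s."""

    length_tr: int = 50
    step_tr: int = 1

    def __post_init__(self) -> None:
        if self.length_tr < 1:
            raise ValueError("window length must be >= 1")
        if self.step_tr < 1:
            raise ValueError("window step must be >= 1")

    def n_windows(self, T: int) -> int:
        if self.length_tr > T:
            raise ValueError(f"window length {self.length_tr} exceeds T={T}")
        return (T - self.length_tr) // self.step_tr + 1


@dataclass
class AlffMap:
    """Per-voxel ALFF (non-negative amplitude units inside the mask)."""

    values: np.ndarray
    band: tuple[float, float]
    mask: np.ndarray


@dataclass
class DalffMaps:
    """Windowed-ALFF stack and its per-voxel summary maps.

    window_stack: (x, y, z, n_windows); mean/sd/cv: 3D.  ``cv_flagged`` marks
    voxels whose mean windowed ALFF fell below a small epsilon, where CV was
    set to 0 instead of dividing by ~0.
    """

    window_stack: np.ndarray
    mean_map: np.ndarray
    sd_map: np.ndarray
    cv_map: np.ndarray
    cv_flagged: np.ndarray
    n_windows: int
    band: tuple[float, float]
    spec: WindowSpec
    mask: np.ndarray


def window_indices(T: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Ordered half-open (start, end) volume ranges; count floor((T-w)/s)+1."""
    n = spec.n_windows(T)
    return [(k * spec.step_tr, k * spec.step_tr + spec.length_tr)
            for k in range(n)]


def compute_alff(series: np.ndarray, tr_s: float,
                 band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Mean single-sided DFT amplitude (2/N)|X(f)| over in-band bins.

    The series is demeaned before the DFT; a constant (or all-zero) series has
    no in-band energy and returns 0.  Positively homogeneous: scaling the
    series by c > 0 scales ALFF by c.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("series must be 1D with length >= 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.size
    idx = band_bins(n, tr_s, band)
    coeff = np.fft.rfft(x - x.mean())
    return float(np.mean(2.0 / n * np.abs(coeff[idx])))


def compute_static_alff(run: BoldRun,
                        band: tuple[float, float] = DEFAULT_BAND) -> AlffMap:
    """ALFF of the full-length series of every in-mask voxel."""
    if not run.mask.any():
        raise ValueError("mask is empty")
    T = run.n_volumes
    idx = band_bins(T, run.tr_s, band)
    Y = run.data[run.mask]  # (V, T)
    coeff = np.fft.rfft(Y - Y.mean(axis=1, keepdims=True), axis=1)
    vals = (2.0 / T * np.abs(coeff[:, idx])).mean(axis=1)
    out = np.zeros(run.mask.shape)
    out[run.mask] = vals
    return AlffMap(out, band, run.mask)


def _windowed_amplitudes(Y: np.ndarray, tr_s: float, spec: WindowSpec,
                         band: tuple[float, float]) -> np.ndarray:
    """Windowed ALFF for row-wise series Y (V, T) -> (V, n_windows).

    For each in-band bin j of the length-w window DFT, the windowed coefficient
    X_k(j) = sum_t y[k+t] exp(-2 pi i j t / w) is a correlation of y with a
    fixed complex kernel, evaluated at every window start by FFT convolution.
    """
    V, T = Y.shape
    w, s = spec.length_tr, spec.step_tr
    idx = band_bins(w, tr_s, band)
    t = np.arange(w)
    amp_sum = np.zeros((V, T - w + 1))
    for j in idx:
        kern = np.exp(-2j * np.pi * j * t / w)
        X = fftconvolve(Y, kern[::-1][None, :], mode="valid", axes=1)
        amp_sum += np.abs(X)
    stack = (2.0 / w) * amp_sum / idx.size
    return stack[:, ::s]


def compute_dynamic_alff(run: BoldRun, spec: WindowSpec = WindowSpec(),
                         band: tuple[float, float] = DEFAULT_BAND) -> DalffMaps:
    """Sliding-window ALFF per voxel with mean/SD/CV summaries.

    SD uses denominator n_windows - 1.  With a single window the SD is
    undefined; zeros are returned with a logged warning.
    """
    if not run.mask.any():
        raise ValueError("mask is empty")
    T = run.n_volumes
    n_win = spec.n_windows(T)
    Y = run.data[run.mask]
    stack_flat = _windowed_amplitudes(Y, run.tr_s, spec, band)
    assert stack_flat.shape[1] == n_win

    shape = run.mask.shape
    stack = np.zeros((*shape, n_win))
    stack[run.mask] = stack_flat
    mean_map = np.zeros(shape)
    sd_map = np.zeros(shape)
    mean_map[run.mask] = stack_flat.mean(axis=1)
    if n_win > 1:
        sd_map[run.mask] = stack_flat.std(axis=1, ddof=1)
    else:
        logger.warning("single window: SD across windows undefined, "
                       "returning zeros")
    cv_map = np.zeros(shape)
    flagged = np.zeros(shape, dtype=bool)
    ok = run.mask & (mean_map > _MEAN_EPS)
    cv_map[ok] = sd_map[ok] / mean_map[ok]
    flagged[run.mask & ~ok] = True
    return DalffMaps(stack, mean_map, sd_map, cv_map, flagged, n_win, band,
                     spec, run.mask)


def standardize_map(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score a 3D map within the mask (mean 0, SD 1); zeros outside.

    Removes inter-subject scanner scaling before group statistics.  Affine
    transforms of the input yield the identical z-map.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    v = np.asarray(values, dtype=float)[mask]
    sd = v.std()
    if sd == 0:
        raise ValueError("zero variance inside mask")
    out = np.zeros(values.shape)
    out[mask] = (v - v.mean()) / sd
    return out
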