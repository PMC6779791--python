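"""Temporal preprocessing applied before (dynamic) ALFF computation.

Stages, in pipeline order: initial-volume discard, motion QC (framewise
displacement and exclusion rule), nuisance regression (with linear detrend as
intercept+slope columns), ideal Fourier band-pass filtering, and optional
spatial Gaussian smoothing.  Spatial registration steps (slice timing,
realignment, normalization) are out of scope: input is assumed voxel-aligned,
and motion QC products are accepted as inputs so the exclusion rule remains
testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .cohort import BoldRun, band_bins, FWHM_TO_SIGMA

__all__ = [
    "MotionTrace",
    "NuisanceSet",
    "discard_initial_volumes",
    "framewise_displacement",
    "motion_exclusion_check",
    "friston24",
    "regress_nuisance",
    "bandpass_filter",
    "spatial_smooth",
]

logger = logging.getLogger(__name__)


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion estimates.

    translations: (T, 3) in mm; rotations: (T, 3) in radians.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.translations.shape != self.rotations.shape or \
                self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")

    def __len__(self) -> int:
        return self.translations.shape[0]

    @classmethod
    def from_file(cls, path: str | Path) -> "MotionTrace":
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] != 6:
            raise ValueError("motion file must have 6 columns "
                             "(3 translations mm, 3 rotations rad)")
        return cls(arr[:, :3], arr[:, 3:])


@dataclass
class NuisanceSet:
    """Per-volume nuisance regressors (motion expansion, WM/CSF signals)."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if self.matrix.size and self.matrix.shape[1] != len(self.labels):
            raise ValueError("labels must match regressor columns")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def empty(cls, n_volumes: int) -> "NuisanceSet":
        return cls(np.empty((n_volumes, 0)), [])


def discard_initial_volumes(run: BoldRun, k: int) -> BoldRun:
    """Drop the first ``k`` volumes (scanner equilibration)."""
    if not 0 <= k < run.n_volumes:
        raise ValueError(f"k={k} must satisfy 0 <= k < T={run.n_volumes}")
    return BoldRun(run.data[..., k:], run.tr_s, run.affine, run.mask)


def framewise_displacement(trace: MotionTrace, radius_mm: float = 50.0
                           ) -> tuple[np.ndarray, float]:
    """Power-style framewise displacement.

    FD(t) = sum |delta translation| + radius * sum |delta rotation|, FD(0)=0;
    rotations are converted to arc length on a ``radius_mm`` sphere.  The mean
    is taken over the T-1 frame-to-frame displacements.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    dt = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1) * radius_mm
    fd = np.concatenate([[0.0], dt + dr])
    return fd, float(fd[1:].mean())


@dataclass
class QcDecision:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


def motion_exclusion_check(trace: MotionTrace,
                           fd_mean: float | None = None,
                           max_translation_mm: float = 2.0,
                           max_rotation_deg: float = 2.0,
                           max_mean_fd: float = 0.3) -> QcDecision:
    """Subject-level motion exclusion rule.

    Fails when any per-axis |translation| exceeds 2 mm, any |rotation| exceeds
    2.0 degrees, or mean FD exceeds 0.3 mm.
    """
    if fd_mean is None:
        _, fd_mean = framewise_displacement(trace)
    t_max = float(np.abs(trace.translations).max())
    r_max_deg = float(np.degrees(np.abs(trace.rotations)).max())
    if t_max > max_translation_mm:
        return QcDecision(False, f"translation {t_max:.2f} mm > "
                                 f"{max_translation_mm} mm")
    if r_max_deg > max_rotation_deg:
        return QcDecision(False, f"rotation {r_max_deg:.2f} deg > "
                                 f"{max_rotation_deg} deg")
    if fd_mean > max_mean_fd:
        return QcDecision(False, f"mean FD {fd_mean:.3f} > {max_mean_fd}")
    return QcDecision(True)


def friston24(trace: MotionTrace) -> NuisanceSet:
    """Friston 24-parameter motion expansion: [p, p^2, p(t-1), p(t-1)^2]."""
    p = np.hstack([trace.translations, trace.rotations])
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    mat = np.hstack([p, p ** 2, lag, lag ** 2])
    labels = ([f"mot{i}" for i in range(6)] + [f"mot{i}_sq" for i in range(6)]
              + [f"mot{i}_lag" for i in range(6)]
              + [f"mot{i}_lag_sq" for i in range(6)])
    return NuisanceSet(mat, labels)


def _prune_collinear(X: np.ndarray, labels: list[str]
                     ) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that add no rank; warn about each drop."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping collinear nuisance column %r", labels[j])
    return X[:, keep], [labels[j] for j in keep]


def regress_nuisance(run: BoldRun, nuisance: NuisanceSet,
                     detrend: bool = False) -> BoldRun:
    """Replace every in-mask voxel series by its OLS residual against
    ``[intercept | (trend) | nuisance]``.

    Residuals are orthogonal to every retained regressor.  Rank-deficient
    designs are repaired by dropping collinear columns with a logged warning.
    """
    T = run.n_volumes
    if nuisance.matrix.size and nuisance.n_volumes != T:
        raise ValueError("nuisance rows must equal run length")
    cols = [np.ones(T)]
    labels = ["intercept"]
    if detrend:
        cols.append(np.linspace(-1.0, 1.0, T))
        labels.append("trend")
    if nuisance.matrix.size:
        cols.append(nuisance.matrix)
        labels.extend(nuisance.labels)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X, labels = _prune_collinear(X, labels)
    vox = run.mask
    Y = run.data[vox].T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = run.data.copy()
    out[vox] = resid.T
    return BoldRun(out, run.tr_s, run.affine, run.mask)


def bandpass_filter(run: BoldRun, lo_hz: float, hi_hz: float) -> BoldRun:
    """Ideal Fourier band-pass: zero every rfft bin outside [lo, hi] Hz.

    The mean (bin 0) is always removed.  Exactly idempotent; matches the
    spectral definition of ALFF bin-by-bin.
    """
    T = run.n_volumes
    idx = band_bins(T, run.tr_s, (lo_hz, hi_hz))
    flat = run.data.reshape(-1, T)
    coeff = np.fft.rfft(flat, axis=1)
    keep = np.zeros(coeff.shape[1], dtype=bool)
    keep[idx] = True
    coeff[:, ~keep] = 0.0
    out = np.fft.irfft(coeff, n=T, axis=1).reshape(run.data.shape)
    return BoldRun(out, run.tr_s, run.affine, run.mask)


def spatial_smooth(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Per-volume Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2))."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return run
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / run.voxel_size_mm
    out = gaussian_filter(run.data, sigma=(*sigma_vox, 0.0))
    return BoldRun(out, run.tr_s, run.affine, run.mask)
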