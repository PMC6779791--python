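"""Synthetic two-group BOLD cohort with a planted dynamic-ALFF effect.

The generator emulates a case/control resting-state fMRI study in which the
patient group carries a focal region of elevated *temporal variability* of the
low-frequency amplitude, without a matching difference in mean amplitude.  The
mechanism is a slow sinusoidal amplitude modulation of a band-limited carrier:
modulation redistributes amplitude across sliding windows (raising the SD/CV of
windowed ALFF) while leaving the full-run spectral amplitude nearly unchanged.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; per-subject substreams are indexed by subject
order, so cohorts are bit-for-bit reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy.ndimage import gaussian_filter

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "BoldRun",
    "band_limited_noise",
    "amplitude_modulated_series",
    "build_effect_mask",
    "make_brain_mask",
    "simulate_cohort",
    "write_cohort",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class SubjectRecord:
    """Group label plus clinical/demographic covariates for one subject.

    ``duration_years``, ``updrs_iii`` and ``hy_stage`` are disease attributes
    and are ``None`` for controls.
    """

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    duration_years: float | None
    updrs_iii: float | None
    hy_stage: float | None
    moca: float
    mmse: float
    mean_fd: float

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if (self.duration_years is not None) != (self.group == "patient"):
            raise ValueError("duration_years must be present iff group == 'patient'")
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be >= 0")


@dataclass
class BoldRun:
    """One subject's 4D BOLD-like time series.

    data: 4D array (x, y, z, t), arbitrary signal units.
    tr_s: repetition time in seconds.
    affine: 4x4 voxel-to-world transform.
    mask: 3D boolean array aligned with data.
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial shape of data")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside mask")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        return img

    @classmethod
    def from_nifti(cls, path: str | Path, mask: np.ndarray | str | Path,
                   tr_s: float | None = None) -> "BoldRun":
        img = nib.load(str(path))
        if isinstance(mask, (str, Path)):
            mask = np.asarray(nib.load(str(mask)).dataobj) > 0
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(np.asarray(img.dataobj, dtype=float), tr_s,
                   np.asarray(img.affine), mask)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated acquisition protocol: TR 2 s, 185 volumes,
    0.01-0.08 Hz pass-band, 3 mm voxels, 6 mm smoothing, 28 subjects per group.
    The effect is a sphere of radius 2.5 voxels (81 voxels) of amplitude
    modulation at depth 0.6 in patients, with per-subject depth coupled to
    simulated disease duration.
    """

    n_per_group: int = 28
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 185
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.08
    effect_center_vox: tuple[int, int, int] = (8, 8, 8)
    effect_radius_vox: float = 2.5
    modulation_depth: float = 0.6
    duration_coupling: float = 0.05   # depth units per year of disease
    mod_freq_hz: float = 0.005        # slow envelope, below the pass-band
    noise_sd: float = 0.5             # white-noise SD relative to unit-SD carrier
    smooth_fwhm_mm: float = 6.0
    brain_radius_vox: float | None = None  # None -> inscribed sphere
    duration_mean_years: float = 8.46
    duration_sd_years: float = 2.92
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = 1.0 / (2.0 * self.tr_s)
        if not (0.0 < self.band_lo_hz < self.band_hi_hz < nyq):
            raise ValueError(
                f"band ({self.band_lo_hz}, {self.band_hi_hz}) Hz must satisfy "
                f"0 < lo < hi < Nyquist ({nyq} Hz)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.modulation_depth < 0:
            raise ValueError("modulation_depth must be >= 0")
        if self.effect_radius_vox < 0:
            raise ValueError("effect_radius_vox must be >= 0")
        if not (0 < self.mod_freq_hz < self.band_lo_hz):
            raise ValueError("mod_freq_hz must lie in (0, band_lo_hz)")
        center = np.asarray(self.effect_center_vox, dtype=float)
        shape = np.asarray(self.grid_shape, dtype=float)
        if np.any(center - self.effect_radius_vox < 0) or \
                np.any(center + self.effect_radius_vox > shape - 1):
            raise ValueError("effect region must lie fully inside the grid")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff


# --------------------------------------------------------------------------- #
# signal primitives
# --------------------------------------------------------------------------- #

def band_bins(n: int, tr_s: float, band: tuple[float, float]) -> np.ndarray:
    """Indices of rfft bins whose frequency lies in [lo, hi] (inclusive).

    Bin 0 (the mean) is never in-band because lo > 0 is required.
    """
    lo, hi = band
    nyq = 1.0 / (2.0 * tr_s)
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, Nyquist={nyq}) Hz")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if idx.size == 0:
        raise ValueError(f"no DFT bins inside band ({lo}, {hi}) Hz for n={n}")
    return idx


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def band_limited_noise(n: int, tr_s: float, band: tuple[float, float],
                       seed) -> np.ndarray:
    """Zero-mean unit-SD noise with spectral energy confined to ``band``.

    Fourier-domain construction: unit-magnitude coefficients with uniform
    random phases at the in-band rfft bins, zeros elsewhere.  All power is
    in-band by construction and the series mean is exactly zero.
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    idx = band_bins(n, tr_s, band)
    rng = _as_rng(seed)
    coeff = np.zeros(n // 2 + 1, dtype=complex)
    coeff[idx] = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=idx.size))
    x = np.fft.irfft(coeff, n=n)
    # each unit-coefficient bin contributes variance 2/n^2; normalise to SD 1
    return x * (n / np.sqrt(2.0 * idx.size))


def amplitude_modulated_series(n: int, tr_s: float, band: tuple[float, float],
                               depth: float, mod_freq_hz: float,
                               seed: int) -> np.ndarray:
    """Band-limited carrier times a slow sinusoidal envelope ``1 + d sin``.

    ``depth=0`` reduces exactly to ``band_limited_noise`` with the same seed.
    The envelope phase is drawn from a seed-derived substream so the carrier
    stream is untouched.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    lo = band[0]
    if not (0 < mod_freq_hz < lo):
        raise ValueError("mod_freq_hz must lie below the pass-band")
    carrier = band_limited_noise(n, tr_s, band, seed)
    phase = np.random.default_rng([int(seed), 0x5EED]).uniform(0, 2 * np.pi)
    t = np.arange(n) * tr_s
    return carrier * (1.0 + depth * np.sin(2.0 * np.pi * mod_freq_hz * t + phase))


def build_effect_mask(grid_shape: tuple[int, int, int],
                      center_vox: tuple[int, int, int] | tuple[float, ...],
                      radius_vox: float) -> np.ndarray:
    """Boolean sphere: voxel included iff Euclidean distance to center <= radius."""
    if radius_vox < 0:
        raise ValueError("radius_vox must be >= 0")
    center = np.asarray(center_vox, dtype=float)
    shape = np.asarray(grid_shape, dtype=float)
    if np.any(center - radius_vox < 0) or np.any(center + radius_vox > shape - 1):
        raise ValueError("sphere must lie inside the grid")
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius_vox ** 2


def make_brain_mask(grid_shape: tuple[int, int, int],
                    radius_vox: float | None = None) -> np.ndarray:
    """Spherical brain-like analysis mask inscribed in the grid."""
    if radius_vox is None:
        radius_vox = min(grid_shape) / 2.0 - 1.0
    center = (np.asarray(grid_shape, dtype=float) - 1) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius_vox ** 2


# --------------------------------------------------------------------------- #
# cohort synthesis
# --------------------------------------------------------------------------- #

def _draw_covariates(cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[SubjectRecord]:
    """Demographics matched in expectation between groups; clinical scales for
    patients only.  Distribution scales follow the emulated cohort (duration
    mean 8.46 SD 2.92 y, UPDRS-III 29.1 +/- 8.7, H-Y 2.02 +/- 0.71, group-wise
    MoCA/MMSE means)."""
    records: list[SubjectRecord] = []
    n = cfg.n_per_group
    for group in ("patient", "control"):
        sexes = np.array(["M"] * ((n + 1) // 2) + ["F"] * (n // 2))
        rng.shuffle(sexes)
        ages = rng.normal(59.0, 8.0, size=n).clip(35.0, 85.0)
        mean_fd = np.abs(rng.normal(0.12, 0.05, size=n)).clip(0.005, 0.29)
        if group == "patient":
            durations = rng.normal(cfg.duration_mean_years,
                                   cfg.duration_sd_years, size=n).clip(0.5, None)
            updrs = rng.normal(29.1, 8.7, size=n).clip(5.0, None)
            hy = rng.normal(2.02, 0.71, size=n).clip(1.0, 5.0)
            moca = rng.normal(24.39, 2.52, size=n).clip(0.0, 30.0)
            mmse = rng.normal(27.64, 1.25, size=n).clip(0.0, 30.0)
        else:
            moca = rng.normal(25.86, 1.73, size=n).clip(0.0, 30.0)
            mmse = rng.normal(27.71, 1.24, size=n).clip(0.0, 30.0)
        for i in range(n):
            sid = f"sub-{len(records) + 1:03d}"
            records.append(SubjectRecord(
                subject_id=sid, group=group, age=float(ages[i]),
                sex=str(sexes[i]),
                duration_years=float(durations[i]) if group == "patient" else None,
                updrs_iii=float(updrs[i]) if group == "patient" else None,
                hy_stage=float(hy[i]) if group == "patient" else None,
                moca=float(moca[i]), mmse=float(mmse[i]),
                mean_fd=float(mean_fd[i])))
    return records


def _simulate_run(cfg: SimulationConfig, rng: np.random.Generator,
                  brain_mask: np.ndarray, effect_mask: np.ndarray,
                  depth: float) -> np.ndarray:
    """One subject's 4D array: per-voxel band-limited carriers, a shared slow
    envelope over the effect voxels (depth > 0), white noise, spatial smoothing."""
    n = cfg.n_volumes
    idx = band_bins(n, cfg.tr_s, (cfg.band_lo_hz, cfg.band_hi_hz))
    vox = np.flatnonzero(brain_mask.ravel())
    nv = vox.size
    coeff = np.zeros((nv, n // 2 + 1), dtype=complex)
    coeff[:, idx] = np.exp(
        1j * rng.uniform(0.0, 2.0 * np.pi, size=(nv, idx.size)))
    series = np.fft.irfft(coeff, n=n, axis=1) * (n / np.sqrt(2.0 * idx.size))

    if depth > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) * cfg.tr_s
        env = 1.0 + depth * np.sin(2.0 * np.pi * cfg.mod_freq_hz * t + phase)
        # unit-RMS envelope: modulation redistributes amplitude over time
        # without raising total in-band energy, so mean ALFF stays matched
        # between groups while its windowed variability rises
        env /= np.sqrt(1.0 + depth ** 2 / 2.0)
        in_effect = effect_mask.ravel()[vox]
        series[in_effect] *= env
    else:
        rng.uniform()  # keep substream alignment across depths

    data = np.zeros((*cfg.grid_shape, n))
    data.reshape(-1, n)[vox] = series
    data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    if cfg.smooth_fwhm_mm > 0:
        sigma_vox = cfg.smooth_fwhm_mm * FWHM_TO_SIGMA / cfg.voxel_size_mm
        data = gaussian_filter(data, sigma=(sigma_vox,) * 3 + (0.0,))
    return data


def simulate_cohort(config: SimulationConfig
                    ) -> list[tuple[BoldRun, SubjectRecord]]:
    """Generate ``2 * n_per_group`` runs (patients first, then controls).

    Inside the effect sphere, patient voxels are amplitude-modulated with a
    per-subject depth ``d_i = modulation_depth +
    duration_coupling * (duration_i - duration_mean_years)`` floored at 0;
    controls and out-of-sphere voxels carry unmodulated signal.
    """
    ss = np.random.SeedSequence(config.seed)
    cov_seed, *subj_seeds = ss.spawn(2 * config.n_per_group + 1)
    records = _draw_covariates(config, np.random.default_rng(cov_seed))
    brain_mask = make_brain_mask(config.grid_shape, config.brain_radius_vox)
    effect_mask = build_effect_mask(config.grid_shape, config.effect_center_vox,
                                    config.effect_radius_vox) & brain_mask
    affine = config.affine
    cohort = []
    for rec, sseed in zip(records, subj_seeds):
        if rec.group == "patient":
            depth = max(0.0, config.modulation_depth + config.duration_coupling
                        * (rec.duration_years - config.duration_mean_years))
        else:
            depth = 0.0
        data = _simulate_run(config, np.random.default_rng(sseed),
                             brain_mask, effect_mask, depth)
        cohort.append((BoldRun(data, config.tr_s, affine, brain_mask), rec))
    return cohort


COVARIATE_COLUMNS = ["subject_id", "group", "age", "sex", "duration_years",
                     "updrs_iii", "hy_stage", "moca", "mmse", "mean_fd"]


def write_cohort(cohort: list[tuple[BoldRun, SubjectRecord]],
                 out_dir: str | Path) -> dict[str, Path]:
    """Write per-subject 4D NIfTI files, the shared mask, and a covariates CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for run, rec in cohort:
        p = out / f"{rec.subject_id}_bold.nii.gz"
        nib.save(run.to_nifti(), str(p))
        paths[rec.subject_id] = p
    run0 = cohort[0][0]
    mask_path = out / "mask.nii.gz"
    nib.save(nib.Nifti1Image(run0.mask.astype(np.uint8), run0.affine),
             str(mask_path))
    paths["mask"] = mask_path
    cov_path = out / "participants.csv"
    with open(cov_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=COVARIATE_COLUMNS)
        w.writeheader()
        for _, rec in cohort:
            row = {k: v for k, v in asdict(rec).items() if k in COVARIATE_COLUMNS}
            w.writerow({k: ("" if v is None else v) for k, v in row.items()})
    paths["covariates"] = cov_path
    return paths
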