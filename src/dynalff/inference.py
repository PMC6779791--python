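"""Voxelwise covariate-adjusted group inference with cluster-level correction.

The group comparison is an ordinary-least-squares GLM fit independently at
every in-mask voxel, with a t statistic for the group contrast.  Familywise
control follows random field theory (RFT/"GRF"): residual smoothness is
estimated from the spatial derivatives of normalized residuals, converted to
resolution elements (resels), and each suprathreshold cluster receives a
corrected p from the expected Euler characteristic of a t field combined with
the classic exp(-beta k^(2/3)) extent tail.  A label-permutation max-extent
corrector is provided as a nonparametric validation alternative.

Scalar helpers cover the demographic-table statistics: Pearson chi-square on a
2x2 table, a covariate-adjusted group test on scalars, and partial correlation
of a regional measure with a clinical score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import label as cc_label

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "Cluster",
    "ClusterTable",
    "build_design",
    "fit_voxelwise_glm",
    "estimate_fwhm",
    "grf_cluster_correction",
    "permutation_cluster_correction",
    "partial_correlation",
    "chi_square_2x2",
    "group_scalar_test",
]

_LN4 = 4.0 * np.log(2.0)


# --------------------------------------------------------------------------- #
# design
# --------------------------------------------------------------------------- #

@dataclass
class DesignMatrix:
    """Subjects-by-regressors design with labelled columns.

    The group column is a 0/1 indicator; covariates are mean-centered so the
    intercept stays interpretable (centering does not affect the group t).
    """

    X: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.labels):
            raise ValueError("labels must match design columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(f"design matrix is rank deficient "
                             f"(columns: {self.labels})")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def contrast(self, label: str) -> np.ndarray:
        c = np.zeros(self.X.shape[1])
        c[self.labels.index(label)] = 1.0
        return c


def build_design(covariates: pd.DataFrame,
                 covariate_names: tuple[str, ...] = ("age", "sex", "mean_fd"),
                 group_col: str = "group",
                 patient_label: str = "patient") -> DesignMatrix:
    """Intercept + group indicator + mean-centered covariates.

    Sex is encoded 0/1 (M=0, F=1) before centering.
    """
    n = len(covariates)
    cols = [np.ones(n)]
    labels = ["intercept"]
    group = (covariates[group_col] == patient_label).to_numpy(dtype=float)
    cols.append(group)
    labels.append("group")
    for name in covariate_names:
        v = covariates[name]
        if v.dtype == object:
            v = v.map({"M": 0.0, "F": 1.0})
            if v.isna().any():
                raise ValueError(f"column {name!r} has unmappable entries")
        v = v.to_numpy(dtype=float)
        cols.append(v - v.mean())
        labels.append(name)
    return DesignMatrix(np.column_stack(cols), labels)


# --------------------------------------------------------------------------- #
# voxelwise GLM
# --------------------------------------------------------------------------- #

@dataclass
class GlmResult:
    beta: np.ndarray            # (p, x, y, z)
    t_map: np.ndarray           # 3D group-contrast t
    df: int
    residual_maps: np.ndarray   # (n_subjects, x, y, z)
    mask: np.ndarray
    fwhm_mm: np.ndarray | None = None  # per-axis, set by estimate_fwhm


def fit_voxelwise_glm(maps: np.ndarray, design: DesignMatrix,
                      contrast: np.ndarray | str = "group",
                      mask: np.ndarray | None = None) -> GlmResult:
    """OLS at every in-mask voxel; t = c'b / sqrt(s^2 c'(X'X)^-1 c).

    ``maps`` is (n_subjects, x, y, z).  Residual maps are retained for the
    smoothness estimate that RFT correction needs.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (n_subjects, x, y, z)")
    if maps.shape[0] != design.n:
        raise ValueError("subject count must equal design rows")
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    if isinstance(contrast, str):
        contrast = design.contrast(contrast)
    c = np.asarray(contrast, dtype=float)
    X = design.X
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    Y = maps[:, mask]  # (n, V)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    denom = np.sqrt(np.maximum(sigma2 * (c @ XtX_inv @ c), 1e-300))
    t_flat = (c @ beta) / denom

    shape = mask.shape
    t_map = np.zeros(shape)
    t_map[mask] = t_flat
    beta_maps = np.zeros((p, *shape))
    beta_maps[:, mask] = beta
    resid_maps = np.zeros((n, *shape))
    resid_maps[:, mask] = resid
    return GlmResult(beta_maps, t_map, df, resid_maps, mask)


def estimate_fwhm(residual_maps: np.ndarray, voxel_size_mm,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Per-axis smoothness (FWHM, mm) from normalized residual derivatives.

    Standard RFT estimator: residuals are normalized voxelwise to unit sum of
    squares across subjects; the variance of their spatial forward differences
    along each axis estimates Lambda_dd, and FWHM_d = sqrt(4 ln 2 / Lambda_dd)
    voxels.  A floor of one voxel is applied.
    """
    R = np.asarray(residual_maps, dtype=float)
    if R.ndim != 4 or R.shape[0] < 3:
        raise ValueError("need >= 3 residual maps of shape (n, x, y, z)")
    if mask is None:
        mask = np.ones(R.shape[1:], dtype=bool)
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    ss = np.sqrt((R ** 2).sum(axis=0))
    ss[ss == 0] = 1.0
    U = R / ss
    fwhm_vox = np.empty(3)
    for d in range(3):
        ax = d + 1
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        m_lo = [slice(None)] * 3
        m_hi = [slice(None)] * 3
        m_lo[d] = slice(0, -1)
        m_hi[d] = slice(1, None)
        pair = mask[tuple(m_lo)] & mask[tuple(m_hi)]
        if not pair.any():
            fwhm_vox[d] = 1.0
            continue
        diff = U[tuple(sl_hi)] - U[tuple(sl_lo)]  # (n, ...)
        lam = float((diff[:, pair] ** 2).sum(axis=0).mean())
        fwhm_vox[d] = np.sqrt(_LN4 / lam) if lam > 0 else np.inf
    fwhm_vox = np.maximum(fwhm_vox, 1.0)
    return fwhm_vox * voxel_size_mm


# --------------------------------------------------------------------------- #
# GRF cluster correction
# --------------------------------------------------------------------------- #

@dataclass
class Cluster:
    size: int
    peak_t: float
    peak_index: tuple[int, int, int]
    peak_coord_mm: tuple[float, float, float]
    p_cluster: float
    sign: int
    voxel_indices: np.ndarray = field(repr=False)


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    voxel_threshold: float
    df: int

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def label_map(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Integer map: cluster rank (1-based, largest first); 0 background."""
        out = np.zeros(shape, dtype=int)
        for i, cl in enumerate(self.clusters, start=1):
            out[tuple(cl.voxel_indices.T)] = i
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cluster": i + 1, "size_voxels": c.size,
                 "peak_x_mm": c.peak_coord_mm[0], "peak_y_mm": c.peak_coord_mm[1],
                 "peak_z_mm": c.peak_coord_mm[2], "peak_t": c.peak_t,
                 "sign": c.sign, "p_cluster": c.p_cluster}
                for i, c in enumerate(self.clusters)]
        return pd.DataFrame(rows, columns=["cluster", "size_voxels", "peak_x_mm",
                                           "peak_y_mm", "peak_z_mm", "peak_t",
                                           "sign", "p_cluster"])


def _t_ec_densities(u: float, df: int) -> np.ndarray:
    """Euler characteristic densities rho_0..rho_3 of a unit t field.

    Worsley-style expressions; resel counts absorb the (4 ln 2 / FWHM^2)
    roughness factors.
    """
    from math import lgamma, exp

    v = float(df)
    base = (1.0 + u * u / v) ** (-(v - 1.0) / 2.0)
    gam = exp(lgamma((v + 1.0) / 2.0) - lgamma(v / 2.0))
    rho0 = stats.t.sf(u, v)
    rho1 = _LN4 ** 0.5 / (2.0 * np.pi) * base
    rho2 = _LN4 / (2.0 * np.pi) ** 1.5 * gam / np.sqrt(v / 2.0) * u * base
    rho3 = _LN4 ** 1.5 / (2.0 * np.pi) ** 2 * base * ((v - 1.0) / v * u * u - 1.0)
    return np.array([rho0, rho1, max(rho2, 0.0), max(rho3, 0.0)])


def _resel_counts(mask: np.ndarray, fwhm_vox: np.ndarray) -> np.ndarray:
    """Resel counts R_0..R_3, approximating the mask by its bounding box.

    R_3 uses the exact in-mask volume; lower orders use bounding-box edge
    lengths in FWHM units.
    """
    idx = np.argwhere(mask)
    extent = idx.max(axis=0) - idx.min(axis=0) + 1
    a = extent / fwhm_vox
    r3 = mask.sum() / np.prod(fwhm_vox)
    r2 = a[0] * a[1] + a[0] * a[2] + a[1] * a[2]
    r1 = a.sum()
    return np.array([1.0, r1, r2, r3])


def _extract_clusters(t_map: np.ndarray, mask: np.ndarray, u: float,
                      connectivity: int = 26) -> list[dict]:
    structure = {6: np.array([[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
                              [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
                              [[0, 0, 0], [0, 1, 0], [0, 0, 0]]]),
                 18: None, 26: np.ones((3, 3, 3), dtype=int)}
    if connectivity == 18:
        s = np.ones((3, 3, 3), dtype=int)
        for c in ((0, 0, 0), (0, 0, 2), (0, 2, 0), (0, 2, 2),
                  (2, 0, 0), (2, 0, 2), (2, 2, 0), (2, 2, 2)):
            s[c] = 0
        struct = s
    else:
        struct = structure[connectivity]
    out = []
    for sign in (1, -1):
        supra = mask & (sign * t_map > u)
        if not supra.any():
            continue
        lab, n_lab = cc_label(supra, structure=struct)
        for i in range(1, n_lab + 1):
            vox = np.argwhere(lab == i)
            tvals = t_map[tuple(vox.T)]
            peak_pos = int(np.argmax(sign * tvals))
            out.append({"size": len(vox), "sign": sign,
                        "peak_t": float(tvals[peak_pos]),
                        "peak_index": tuple(int(x) for x in vox[peak_pos]),
                        "voxel_indices": vox})
    return out


def grf_cluster_correction(t_map: np.ndarray, df: int, mask: np.ndarray,
                           fwhm_mm, voxel_size_mm,
                           voxel_p: float = 0.001, cluster_p: float = 0.05,
                           affine: np.ndarray | None = None,
                           two_sided: bool = True,
                           connectivity: int = 26) -> ClusterTable:
    """RFT cluster-level correction of a voxelwise-thresholded t map.

    The voxel threshold u is the (two-sided by default) t quantile at
    ``voxel_p``.  The expected cluster count E[m] comes from the t-field EC
    densities and resel counts; the extent tail is the Friston approximation
    P(n >= k) = exp(-beta k^(2/3)) with beta matched to the expected cluster
    size.  Corrected p = 1 - exp(-E[m_total] P(n >= k)); clusters with
    p < ``cluster_p`` are retained, largest first.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
    fwhm_mm = np.broadcast_to(np.asarray(fwhm_mm, float), (3,))
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    fwhm_vox = np.maximum(fwhm_mm / voxel_size_mm, 1.0)
    u = float(stats.t.ppf(1.0 - (voxel_p / 2.0 if two_sided else voxel_p), df))

    resels = _resel_counts(mask, fwhm_vox)
    rho = _t_ec_densities(u, df)
    e_m = float(np.maximum(resels @ rho, 1e-300))       # clusters per sign
    e_m_total = 2.0 * e_m if two_sided else e_m
    e_voxels = mask.sum() * stats.t.sf(u, df)           # suprathreshold voxels
    e_n = max(e_voxels / e_m, 1e-300)                   # expected cluster size
    from math import gamma
    beta = (gamma(2.5) / e_n) ** (2.0 / 3.0)

    raw = _extract_clusters(t_map, mask, u, connectivity)
    clusters = []
    for cl in raw:
        p_ext = float(np.exp(-beta * cl["size"] ** (2.0 / 3.0)))
        p_fwe = float(1.0 - np.exp(-e_m_total * p_ext))
        if p_fwe < cluster_p:
            coord = _world_coord(cl["peak_index"], affine, voxel_size_mm, mask)
            clusters.append(Cluster(cl["size"], cl["peak_t"], cl["peak_index"],
                                    coord, p_fwe, cl["sign"],
                                    cl["voxel_indices"]))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return ClusterTable(clusters, u, df)


def _world_coord(index, affine, voxel_size_mm, mask):
    if affine is None:
        affine = np.diag([*voxel_size_mm, 1.0])
        affine[:3, 3] = -voxel_size_mm * (np.asarray(mask.shape) - 1) / 2.0
    xyz = affine @ np.array([*index, 1.0])
    return tuple(float(v) for v in xyz[:3])


def permutation_cluster_correction(maps: np.ndarray, design: DesignMatrix,
                                   mask: np.ndarray,
                                   voxel_p: float = 0.001,
                                   cluster_p: float = 0.05,
                                   n_perm: int = 500, seed: int = 0,
                                   affine: np.ndarray | None = None,
                                   two_sided: bool = True,
                                   connectivity: int = 26) -> ClusterTable:
    """Nonparametric alternative: max-cluster-extent null from group-label
    permutations of the design's group column; p = (1 + #{max_ext >= k}) /
    (1 + n_perm)."""
    res = fit_voxelwise_glm(maps, design, "group", mask)
    u = float(stats.t.ppf(1.0 - (voxel_p / 2.0 if two_sided else voxel_p),
                          res.df))
    raw = _extract_clusters(res.t_map, mask, u, connectivity)
    rng = np.random.default_rng(seed)
    gcol = design.labels.index("group")
    null_max = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        Xp = design.X.copy()
        Xp[:, gcol] = rng.permutation(Xp[:, gcol])
        dp = DesignMatrix(Xp, design.labels)
        rp = fit_voxelwise_glm(maps, dp, "group", mask)
        cls = _extract_clusters(rp.t_map, mask, u, connectivity)
        null_max[b] = max((c["size"] for c in cls), default=0)
    voxel_size_mm = (np.ones(3) if affine is None
                     else np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(0)))
    clusters = []
    for cl in raw:
        p = float((1 + (null_max >= cl["size"]).sum()) / (1 + n_perm))
        if p < cluster_p:
            coord = _world_coord(cl["peak_index"], affine, voxel_size_mm, mask)
            clusters.append(Cluster(cl["size"], cl["peak_t"], cl["peak_index"],
                                    coord, p, cl["sign"], cl["voxel_indices"]))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return ClusterTable(clusters, u, res.df)


# --------------------------------------------------------------------------- #
# scalar statistics
# --------------------------------------------------------------------------- #

def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    r is the correlation of the two residual vectors against
    [intercept | covariates]; the two-sided p comes from
    t = r sqrt((n - 2 - k) / (1 - r^2)) with k covariates.  With no
    covariates this is exactly the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (np.size(covariates) == 0):
        Z = np.ones((x.size, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.size:
            cov = cov.T
        Z = np.column_stack([np.ones(x.size), cov])
        k = cov.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx <= 1e-10 * max(np.linalg.norm(x - x.mean()), 1e-30) or \
            sy <= 1e-10 * max(np.linalg.norm(y - y.mean()), 1e-30):
        raise ValueError("zero residual variance: correlation undefined")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction), df = 1, two-sided p."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if tab.sum() == 0 or (tab.sum(axis=0) == 0).any() or \
            (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def group_scalar_test(values, groups, covariates=None) -> tuple[float, float]:
    """Covariate-adjusted group-effect t on a per-subject scalar.

    Same GLM machinery as the voxelwise fit applied to a single outcome; with
    no covariates this is the pooled-variance two-sample t (patient - control).
    """
    values = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if g.dtype.kind in "US O":
        g = (g == "patient").astype(float)
    g = g.astype(float)
    if g.sum() == 0 or g.sum() == g.size:
        raise ValueError("both groups must be nonempty")
    cols = [np.ones(values.size), g]
    labels = ["intercept", "group"]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != values.size:
            cov = cov.T
        cov = cov - cov.mean(axis=0)
        cols.append(cov)
        labels.extend(f"cov{i}" for i in range(cov.shape[1]))
    design = DesignMatrix(np.column_stack(cols), labels)
    res = fit_voxelwise_glm(values.reshape(-1, 1, 1, 1), design, "group")
    t = float(res.t_map[0, 0, 0])
    p = float(2.0 * stats.t.sf(abs(t), res.df))
    return t, p
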