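"""End-to-end orchestration: simulate/load -> preprocess -> dALFF -> group GLM
with cluster correction -> clinical correlations -> SVM classification.

Every stage writes its artifacts under the output directory and a manifest
records the configuration, the seed, and SHA-256 checksums of the outputs, so
a run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

from .cohort import (SimulationConfig, SubjectRecord, BoldRun, simulate_cohort,
                     build_effect_mask, COVARIATE_COLUMNS)
from .preprocess import (discard_initial_volumes, regress_nuisance,
                         bandpass_filter, NuisanceSet)
from .dalff import (WindowSpec, compute_static_alff, compute_dynamic_alff,
                    standardize_map)
from .inference import (build_design, fit_voxelwise_glm, estimate_fwhm,
                        grf_cluster_correction, permutation_cluster_correction,
                        partial_correlation, chi_square_2x2, group_scalar_test,
                        ClusterTable, DesignMatrix)
from .classify import (extract_cluster_feature, loocv_classify, kfold_classify,
                       label_permutation_test, CvResult, PermutationResult,
                       _fit_fold)

__all__ = ["PipelineConfig", "PipelineResult", "read_covariates",
           "run_pipeline", "nested_cv_classify"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the emulated study protocol:
    10 volumes discarded, 0.01-0.08 Hz band, window 50 TR step 1, voxel
    p<0.001 with cluster p<0.05 (GRF), LOOCV, 5,000 permutations."""

    discard_volumes: int = 10
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.08
    window_length_tr: int = 50
    window_step_tr: int = 1
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    correction: str = "grf"          # "grf" | "perm"
    n_perm_cluster: int = 500
    variability_map: str = "cv"      # "cv" | "sd"
    standardize: bool = True
    cv_scheme: str = "loocv"         # "loocv" | "kfold"
    kfold_k: int = 10
    n_perm: int = 5000
    svm_c: float = 1.0
    classifier_mode: str = "faithful"  # "faithful" | "nested"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.correction not in ("grf", "perm"):
            raise ValueError("correction must be 'grf' or 'perm'")
        if self.variability_map not in ("cv", "sd"):
            raise ValueError("variability_map must be 'cv' or 'sd'")
        if self.cv_scheme not in ("loocv", "kfold"):
            raise ValueError("cv_scheme must be 'loocv' or 'kfold'")
        if self.classifier_mode not in ("faithful", "nested"):
            raise ValueError("classifier_mode must be 'faithful' or 'nested'")
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError("band must satisfy 0 < lo < hi")
        T = self.simulation.n_volumes - self.discard_volumes
        if self.window_length_tr > T:
            raise ValueError(
                f"window length {self.window_length_tr} exceeds the "
                f"{T} analyzed volumes (window rule: w <= T)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat TOML config; keys mirror the dataclass fields, with simulation
        parameters under a [simulation] table."""
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_raw = raw.pop("simulation", {})
        if "grid_shape" in sim_raw:
            sim_raw["grid_shape"] = tuple(sim_raw["grid_shape"])
        if "effect_center_vox" in sim_raw:
            sim_raw["effect_center_vox"] = tuple(sim_raw["effect_center_vox"])
        sim = SimulationConfig(**sim_raw)
        return cls(simulation=sim, **raw)


@dataclass
class PipelineResult:
    demographics: pd.DataFrame
    cluster_table: ClusterTable
    cluster_table_static: ClusterTable
    correlations: pd.DataFrame
    cv_result: CvResult | None
    kfold_result: CvResult | None
    permutation: PermutationResult | None
    dice_vs_planted: float | None
    group_maps: np.ndarray
    raw_cv_maps: np.ndarray
    cluster_mask: np.ndarray | None
    labels: np.ndarray
    t_map: np.ndarray
    fwhm_mm: np.ndarray
    mask: np.ndarray
    manifest: dict


def read_covariates(path: str | Path) -> list[SubjectRecord]:
    """Parse and validate the covariates table into typed records."""
    df = pd.read_csv(path)
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject id {dup!r}")
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        group = str(row["group"])
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValueError(f"row {rownum}: non-numeric age {row['age']!r}")
        dur = row["duration_years"]
        dur = None if pd.isna(dur) else float(dur)
        if group == "control" and dur is not None:
            logger.warning("row %d: control %s has a disease duration; "
                           "ignoring it", rownum, row["subject_id"])
            dur = None
        if group == "patient" and dur is None:
            raise ValueError(f"row {rownum}: patient {row['subject_id']} "
                             f"lacks duration_years")
        def opt(col):
            v = row[col]
            return None if pd.isna(v) else float(v)
        try:
            records.append(SubjectRecord(
                subject_id=str(row["subject_id"]), group=group, age=age,
                sex=str(row["sex"]), duration_years=dur,
                updrs_iii=opt("updrs_iii"), hy_stage=opt("hy_stage"),
                moca=float(row["moca"]), mmse=float(row["mmse"]),
                mean_fd=float(row["mean_fd"])))
        except ValueError as e:
            raise ValueError(f"row {rownum}: {e}") from e
    return records


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])[COVARIATE_COLUMNS]


def _load_cohort(input_dir: Path) -> list[tuple[BoldRun, SubjectRecord]]:
    records = read_covariates(input_dir / "participants.csv")
    mask = np.asarray(nib.load(str(input_dir / "mask.nii.gz")).dataobj) > 0
    cohort = []
    for rec in records:
        p = input_dir / f"{rec.subject_id}_bold.nii.gz"
        if not p.exists():
            p = input_dir / f"{rec.subject_id}_bold.nii"
        cohort.append((BoldRun.from_nifti(p, mask), rec))
    return cohort


def demographics_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Group summary table with the chi-square (sex) and covariate-adjusted
    group tests mirroring a clinical demographics table."""
    df = records_to_frame(records)
    pat = df[df.group == "patient"]
    con = df[df.group == "control"]
    rows = []
    tab = [[int((pat.sex == "M").sum()), int((pat.sex == "F").sum())],
           [int((con.sex == "M").sum()), int((con.sex == "F").sum())]]
    _, p_sex = chi_square_2x2(tab)
    rows.append({"variable": "sex (M/F)",
                 "patients": f"{tab[0][0]}/{tab[0][1]}",
                 "controls": f"{tab[1][0]}/{tab[1][1]}", "p": p_sex})
    for col in ("age", "moca", "mmse", "mean_fd"):
        _, p = group_scalar_test(df[col].to_numpy(),
                                 (df.group == "patient").to_numpy())
        rows.append({"variable": col,
                     "patients": f"{pat[col].mean():.2f} ± {pat[col].std():.2f}",
                     "controls": f"{con[col].mean():.2f} ± {con[col].std():.2f}",
                     "p": p})
    for col in ("duration_years", "updrs_iii", "hy_stage"):
        rows.append({"variable": col,
                     "patients": f"{pat[col].mean():.2f} ± {pat[col].std():.2f}",
                     "controls": "N/A", "p": np.nan})
    return pd.DataFrame(rows)


def _subject_variability_maps(cohort, config: PipelineConfig
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Temporal preprocessing and (d)ALFF per subject.

    Returns (variability maps, static ALFF maps, raw cluster-scale CV maps);
    the first two are optionally z-scored within the mask for the group GLM,
    the third keeps CV in native units for reporting and correlations.
    """
    band = (config.band_lo_hz, config.band_hi_hz)
    spec = WindowSpec(config.window_length_tr, config.window_step_tr)
    var_maps, static_maps, raw_cv = [], [], []
    for run, rec in cohort:
        run = discard_initial_volumes(run, config.discard_volumes)
        run = regress_nuisance(run, NuisanceSet.empty(run.n_volumes),
                               detrend=True)
        run = bandpass_filter(run, *band)
        dmaps = compute_dynamic_alff(run, spec, band)
        vmap = dmaps.cv_map if config.variability_map == "cv" else dmaps.sd_map
        raw_cv.append(dmaps.cv_map)
        smap = compute_static_alff(run, band).values
        if config.standardize:
            vmap = standardize_map(vmap, run.mask)
            smap = standardize_map(smap, run.mask)
        var_maps.append(vmap)
        static_maps.append(smap)
    return (np.stack(var_maps), np.stack(static_maps), np.stack(raw_cv))


def nested_cv_classify(var_maps: np.ndarray, design: DesignMatrix,
                       labels: np.ndarray, mask: np.ndarray,
                       fwhm_mm, voxel_size_mm, config: PipelineConfig
                       ) -> CvResult:
    """Leave-one-out CV with the feature cluster re-selected inside every
    training fold (no test subject contributes to feature selection).

    Folds whose training GLM yields no surviving cluster fall back to the
    uncorrected peak-t voxel neighbourhood so every subject gets a prediction.
    """
    n = labels.size
    scores = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        d_tr = DesignMatrix(design.X[tr], design.labels)
        res = fit_voxelwise_glm(var_maps[tr], d_tr, "group", mask)
        table = grf_cluster_correction(res.t_map, res.df, mask, fwhm_mm,
                                       voxel_size_mm, config.voxel_p,
                                       config.cluster_p)
        if len(table):
            cl_mask = table.label_map(mask.shape) == 1
        else:
            peak = np.unravel_index(np.argmax(np.abs(res.t_map)), mask.shape)
            cl_mask = np.zeros(mask.shape, dtype=bool)
            cl_mask[peak] = True
        X_tr = extract_cluster_feature(var_maps[tr], cl_mask)
        X_te = extract_cluster_feature(var_maps[[i]], cl_mask)
        scores[i] = _fit_fold(X_tr, labels[tr], X_te, config.svm_c)[0]
    preds = (scores > 0).astype(int)
    return CvResult.from_predictions(labels, preds, scores, "nested-loocv")


def run_pipeline(config: PipelineConfig | None = None,
                 input_dir: str | Path | None = None,
                 out_dir: str | Path | None = None,
                 write_subject_maps: bool = False) -> PipelineResult:
    """Execute the full analysis; simulate a cohort when no input is given."""
    config = config or PipelineConfig()
    t0 = time.time()
    if input_dir is None:
        logger.info("simulating cohort (seed=%d)", config.simulation.seed)
        cohort = simulate_cohort(config.simulation)
        planted = build_effect_mask(config.simulation.grid_shape,
                                    config.simulation.effect_center_vox,
                                    config.simulation.effect_radius_vox)
    else:
        cohort = _load_cohort(Path(input_dir))
        planted = None
    records = [rec for _, rec in cohort]
    run0 = cohort[0][0]
    mask = run0.mask
    voxel_size = run0.voxel_size_mm
    affine = run0.affine

    logger.info("computing per-subject dALFF maps (n=%d)", len(cohort))
    var_maps, static_maps, raw_cv = _subject_variability_maps(cohort, config)

    cov_df = records_to_frame(records)
    design = build_design(cov_df)
    labels = (cov_df.group == "patient").to_numpy(dtype=int)

    glm = fit_voxelwise_glm(var_maps, design, "group", mask)
    fwhm = estimate_fwhm(glm.residual_maps, voxel_size, mask)
    glm.fwhm_mm = fwhm
    logger.info("residual smoothness FWHM = %s mm", np.round(fwhm, 2))
    if config.correction == "grf":
        table = grf_cluster_correction(glm.t_map, glm.df, mask, fwhm,
                                       voxel_size, config.voxel_p,
                                       config.cluster_p, affine)
    else:
        table = permutation_cluster_correction(
            var_maps, design, mask, config.voxel_p, config.cluster_p,
            config.n_perm_cluster, config.seed, affine)

    glm_s = fit_voxelwise_glm(static_maps, design, "group", mask)
    fwhm_s = estimate_fwhm(glm_s.residual_maps, voxel_size, mask)
    table_s = grf_cluster_correction(glm_s.t_map, glm_s.df, mask, fwhm_s,
                                     voxel_size, config.voxel_p,
                                     config.cluster_p, affine)

    dice = None
    cl_mask = None
    if len(table):
        cl_mask = table.label_map(mask.shape) == 1
        if planted is not None:
            inter = (cl_mask & planted & mask).sum()
            dice = float(2 * inter / (cl_mask.sum() + (planted & mask).sum()))

    # partial correlations of regional variability with clinical scores
    corr_rows = []
    if cl_mask is not None:
        pat = cov_df.group == "patient"
        feat_pat = raw_cv[pat.to_numpy()][:, cl_mask].mean(axis=1)
        covs = np.column_stack([
            cov_df.loc[pat, "age"],
            (cov_df.loc[pat, "sex"] == "F").astype(float)])
        for col in ("duration_years", "updrs_iii", "hy_stage", "moca", "mmse"):
            vals = cov_df.loc[pat, col].to_numpy(dtype=float)
            r, p = partial_correlation(feat_pat, vals, covs)
            corr_rows.append({"score": col, "r": r, "p": p, "n": int(pat.sum())})
    correlations = pd.DataFrame(corr_rows, columns=["score", "r", "p", "n"])

    cv_res = kfold_res = perm_res = None
    if cl_mask is not None:
        if config.classifier_mode == "faithful":
            fm = extract_cluster_feature(var_maps, cl_mask, labels,
                                         [r.subject_id for r in records])
            cv_res = (loocv_classify(fm.X, fm.labels, config.svm_c)
                      if config.cv_scheme == "loocv"
                      else kfold_classify(fm.X, fm.labels, config.kfold_k,
                                          config.seed, config.svm_c))
            kfold_res = kfold_classify(fm.X, fm.labels, config.kfold_k,
                                       config.seed, config.svm_c)
            perm_res = label_permutation_test(
                fm.X, fm.labels, config.n_perm, config.seed,
                scheme=config.cv_scheme, k=config.kfold_k, C=config.svm_c)
        else:
            cv_res = nested_cv_classify(var_maps, design, labels, mask,
                                        fwhm, voxel_size, config)

    manifest = {
        "config": _jsonable(dataclasses.asdict(config)),
        "n_subjects": len(records),
        "elapsed_s": round(time.time() - t0, 2),
    }
    result = PipelineResult(
        demographics=demographics_table(records), cluster_table=table,
        cluster_table_static=table_s, correlations=correlations,
        cv_result=cv_res, kfold_result=kfold_res, permutation=perm_res,
        dice_vs_planted=dice, group_maps=var_maps, raw_cv_maps=raw_cv,
        cluster_mask=cl_mask, labels=labels, t_map=glm.t_map,
        fwhm_mm=fwhm, mask=mask, manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, cohort, affine, Path(out_dir),
                       write_subject_maps)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _write_outputs(result: PipelineResult, cohort, affine, out: Path,
                   write_subject_maps: bool) -> None:
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(result.t_map.astype(np.float32), affine),
             str(out / "group_t_map.nii.gz"))
    lab = result.cluster_table.label_map(result.mask.shape)
    nib.save(nib.Nifti1Image(lab.astype(np.int16), affine),
             str(out / "cluster_labels.nii.gz"))
    result.cluster_table.to_frame().to_csv(out / "cluster_table.csv",
                                           index=False)
    result.demographics.to_csv(out / "demographics.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    metrics = {}
    if result.cv_result is not None:
        c = result.cv_result
        pd.DataFrame({
            "subject_id": [rec.subject_id for _, rec in cohort],
            "true_label": c.y_true, "predicted_label": c.y_pred,
            "decision_score": c.scores,
        }).to_csv(out / "predictions.csv", index=False)
        np.savetxt(out / "roc_points.csv", c.roc_points(), delimiter=",",
                   header="score,fpr,tpr", comments="")
        metrics["cv"] = {"scheme": c.scheme, "accuracy": c.accuracy,
                         "sensitivity": c.sensitivity,
                         "specificity": c.specificity, "auc": c.auc}
    if result.kfold_result is not None:
        metrics["kfold"] = {"scheme": result.kfold_result.scheme,
                            "accuracy": result.kfold_result.accuracy}
    if result.permutation is not None:
        metrics["permutation"] = {"p": result.permutation.p_value,
                                  "n_perm": result.permutation.n_perm}
    if result.dice_vs_planted is not None:
        metrics["dice_vs_planted"] = result.dice_vs_planted
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    if write_subject_maps:
        maps_dir = out / "subject_maps"
        maps_dir.mkdir(exist_ok=True)
        for (run, rec), m in zip(cohort, result.group_maps):
            nib.save(nib.Nifti1Image(m.astype(np.float32), affine),
                     str(maps_dir / f"{rec.subject_id}_variability.nii.gz"))
    checks = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checks[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    manifest = dict(result.manifest, checksums=checks)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
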