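"""Voxelwise group comparison of dALFF variability with cluster correction.

Simulates a 12+12 cohort, fits the covariate-adjusted GLM (age, sex, mean FD)
at every voxel of the per-subject CV maps, estimates residual smoothness, and
applies random-field cluster correction (voxel p<0.001, cluster p<0.05).
Prints the cluster table and the overlap with the planted sphere, plus the
partial correlation of cluster CV with disease duration.
"""

import numpy as np

from dynalff import (SimulationConfig, simulate_cohort, build_effect_mask,
                     build_design, fit_voxelwise_glm, estimate_fwhm,
                     grf_cluster_correction, partial_correlation)
from dynalff.pipeline import (PipelineConfig, _subject_variability_maps,
                              records_to_frame)

sim = SimulationConfig(n_per_group=12, grid_shape=(14, 14, 14),
                       n_volumes=185, effect_center_vox=(7, 7, 7),
                       effect_radius_vox=2.5, modulation_depth=0.7, seed=5)
cohort = simulate_cohort(sim)
mask = cohort[0][0].mask

config = PipelineConfig(simulation=sim)
var_maps, _, raw_cv = _subject_variability_maps(cohort, config)

covars = records_to_frame([rec for _, rec in cohort])
design = build_design(covars)
glm = fit_voxelwise_glm(var_maps, design, "group", mask)
fwhm = estimate_fwhm(glm.residual_maps, sim.voxel_size_mm, mask)
table = grf_cluster_correction(glm.t_map, glm.df, mask, fwhm,
                               sim.voxel_size_mm, voxel_p=0.001,
                               cluster_p=0.05, affine=sim.affine)

print(f"residual smoothness FWHM: {np.round(fwhm, 1)} mm")
print(table.to_frame().round(3).to_string(index=False))

planted = build_effect_mask(sim.grid_shape, sim.effect_center_vox,
                            sim.effect_radius_vox) & mask
cl = table.label_map(mask.shape) == 1
dice = 2 * (cl & planted).sum() / (cl.sum() + planted.sum())
print(f"Dice overlap of top cluster with planted sphere: {dice:.2f}")

pat = covars.group == "patient"
feat = raw_cv[pat.to_numpy()][:, cl].mean(axis=1)
covs = np.column_stack([covars.loc[pat, "age"],
                        (covars.loc[pat, "sex"] == "F").astype(float)])
r, p = partial_correlation(feat, covars.loc[pat, "duration_years"], covs)
print(f"cluster CV vs disease duration (age/sex partialled): "
      f"r = {r:.3f}, p = {p:.2g}")
# The surviving cluster sits on the planted sphere, and its CV rises with
# simulated disease duration because per-subject modulation depth is
# duration-coupled.
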