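"""Compute static ALFF and sliding-window dynamic ALFF for one subject.

Simulates a single patient-like run, applies the temporal preprocessing
(discard, detrend, 0.01-0.08 Hz band-pass), then prints how the windowed-ALFF
variability (CV) differs between the modulated sphere and the rest of the
brain, while the *static* ALFF barely differs — the defining signature of a
dynamic-amplitude effect.
"""

import numpy as np

from dynalff import (SimulationConfig, simulate_cohort, build_effect_mask,
                     discard_initial_volumes, regress_nuisance,
                     bandpass_filter, NuisanceSet, WindowSpec,
                     compute_static_alff, compute_dynamic_alff)

config = SimulationConfig(n_per_group=1, grid_shape=(12, 12, 12),
                          n_volumes=185, effect_center_vox=(6, 6, 6),
                          effect_radius_vox=2.5, modulation_depth=0.8,
                          duration_coupling=0.0, noise_sd=0.3, seed=21)
run, record = simulate_cohort(config)[0]  # the patient

run = discard_initial_volumes(run, 10)
run = regress_nuisance(run, NuisanceSet.empty(run.n_volumes), detrend=True)
run = bandpass_filter(run, 0.01, 0.08)

maps = compute_dynamic_alff(run, WindowSpec(50, 1), (0.01, 0.08))
static = compute_static_alff(run, (0.01, 0.08))

effect = build_effect_mask(config.grid_shape, config.effect_center_vox,
                           config.effect_radius_vox) & run.mask
rest = run.mask & ~effect

print(f"{maps.n_windows} windows of 50 TR at step 1 from "
      f"{run.n_volumes} volumes")
print(f"CV of windowed ALFF   inside sphere: {maps.cv_map[effect].mean():.3f}"
      f"   elsewhere: {maps.cv_map[rest].mean():.3f}")
print(f"static ALFF           inside sphere: "
      f"{static.values[effect].mean():.3f}   elsewhere: "
      f"{static.values[rest].mean():.3f}")
# The modulated sphere roughly doubles the CV of windowed ALFF while leaving
# static ALFF nearly unchanged: temporal variability, not mean amplitude.
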