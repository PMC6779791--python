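# Methods

`dynalff` implements a sliding-window dynamic-ALFF analysis of resting-state
BOLD fMRI, together with a synthetic cohort generator that realises the data
conditions such an analysis assumes. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data do
and do not establish.

## ALFF and dynamic ALFF

For a voxel series x(t) sampled at repetition time TR, the amplitude of
low-frequency fluctuations is defined spectrally:

    ALFF = mean over band bins f of (2/N) |X(f)|,   f in [0.01, 0.08] Hz,

where X is the DFT of the demeaned series and (2/N)|X| the single-sided
amplitude. The *mean* (not the sum) over in-band bins is used so that values
are comparable across window lengths; ALFF is positively homogeneous (scaling
the series scales ALFF) and zero for constant series.

Dynamic ALFF recomputes this inside sliding windows of w volumes at step s
(defaults w=50, s=1, so 175 analyzed volumes yield 126 windows). Windows are
rectangular and demeaned; no taper. Per voxel the package emits the mean, SD
(denominator n−1), and coefficient of variation CV = SD/mean of windowed
ALFF. Group inference operates on the CV map by default, with the SD map
available; CV is invariant to global multiplicative rescaling of the run,
which removes scanner-gain differences by construction.

Implementation detail: the windowed coefficient X_k(f) at an in-band bin is a
complex correlation of the series with a fixed length-w kernel, evaluated at
every window start by FFT convolution. This is algebraically identical to a
demeaned per-window DFT — demeaning only alters bin 0, which is never in-band
— and makes the 126-window stack cheap. A direct per-window DFT oracle checks
this identity in the tests.

Voxels whose mean windowed ALFF falls below 1e−12 get CV set to 0 and a flag,
avoiding ratio blow-ups in background voxels.

## Temporal preprocessing

Pipeline order: discard the first k volumes (default 10; 185 acquired → 175
analyzed) → nuisance regression → band-pass → (optional smoothing). Nuisance
regression is voxelwise OLS against [intercept | linear trend | regressors];
the linear trend plays the role of detrending and residuals are exactly
orthogonal to every retained regressor. Collinear columns are dropped with a
warning rather than failing. A Friston-24 motion expansion helper
([p, p², p(t−1), p(t−1)²]) is provided for real motion traces.

The band-pass is an ideal Fourier mask: every rfft bin outside [lo, hi] is
zeroed, including bin 0. This matches the spectral definition of ALFF
bin-for-bin, is exactly idempotent, and is testable per bin, at the cost of
the usual implicit-periodicity edge effects (irrelevant at these series
lengths and band widths).

Motion QC implements the subject-level exclusion rule: any per-axis
|translation| > 2 mm, any |rotation| > 2.0°, or mean framewise displacement
> 0.3 mm excludes the subject. FD follows the Power convention — the sum of
absolute backward differences of the six parameters, rotations converted to
arc length on a 50 mm sphere — with the mean taken over the T−1 transitions.
Units for the 0.3 threshold are mm. Frame censoring is deliberately absent:
exclusion is whole-subject only. Slice timing, realignment and spatial
normalization are out of scope; input is assumed voxel-aligned, and the QC
rule accepts externally produced motion traces so it stays testable.

Smoothing is per-volume Gaussian convolution with σ = FWHM/(2√(2 ln 2)) per
axis converted by voxel size; FWHM 0 is the identity.

## Synthetic cohort

The generator emulates a two-group (default 28+28) resting-state study on a
desk-scale grid (16³ voxels of 3 mm; configurable up to realistic sizes).
Per subject, every in-mask voxel receives an independent band-limited
carrier: unit-magnitude Fourier coefficients with random phases at the
in-band bins of the 185-volume grid, zeros elsewhere, scaled to unit SD. The
analysis mask is an inscribed sphere (radius min(grid)/2 − 1), giving a
brain-like geometry.

The planted effect is a sphere (default center (8,8,8), radius 2.5 voxels =
81 voxels) in which *patient* carriers are multiplied by a slow sinusoidal
envelope 1 + d·sin(2π f_mod t + φ), f_mod = 0.005 Hz (below the pass-band so
the envelope is not itself an in-band signal), φ random per subject. The
envelope is normalised to unit RMS, so modulation redistributes amplitude
across time without raising total in-band energy: windowed-ALFF SD/CV rises
while mean ALFF stays matched between groups — a *dynamic-only* effect, which
is the study premise. Per-subject depth is coupled to simulated disease
duration, dᵢ = d₀ + γ(durationᵢ − 8.46 y) floored at 0, with defaults
d₀ = 0.6 and γ = 0.05/year; this makes regional CV rise with duration so the
clinical-correlation analysis has a recoverable signal.

White noise (SD 0.5 relative to the unit-SD carrier) is added everywhere and
each volume is Gaussian-smoothed at 6 mm FWHM, inducing the spatial
smoothness that random-field theory assumes.

Covariates are drawn to be matched in expectation: age ~ N(59, 8²) in both
groups, sexes balanced, mean FD ~ |N(0.12, 0.05)|; patients additionally get
duration ~ N(8.46, 2.92²) truncated positive, UPDRS-III ~ N(29.1, 8.7²), H-Y
~ N(2.02, 0.71²), and group-specific MoCA/MMSE distributions. All randomness
descends from one integer seed via `numpy.random.SeedSequence`, with
per-subject substreams indexed by subject order; cohorts are bit-identical
across runs.

What the generator does *not* emulate: hemodynamic response or neurovascular
coupling, 1/f noise spectra, physiological confounds, head-motion imagery
(mean FD is a scalar covariate only), anatomical structure, or registration
error. Passing tests therefore demonstrate the statistical machinery —
calibration under the null, recovery of a planted dynamic effect, valid
permutation inference — not robustness to the artefact structure of real
scanner data.

## Group inference

The group comparison is a voxelwise OLS GLM on per-subject variability maps
with intercept, 0/1 group indicator, and mean-centered age, sex (0/1) and
mean FD; t = c'β̂ / √(σ̂² c'(XᵀX)⁻¹c) with df = n − p. Maps are z-scored
within the mask per subject before the GLM (default; configurable), removing
inter-subject scale. Centering covariates does not change the group t.

Cluster-level correction follows random field theory. Residual smoothness is
estimated from the spatial derivatives of voxelwise-normalized residuals:
FWHM_d = √(4 ln 2 / λ_d) voxels with λ_d the mean squared forward difference
along axis d, floored at one voxel. The voxel threshold u is the two-sided
t quantile at p = 0.001 (both signs are clustered and reported; the
directional hypothesis is left to the reader, so familywise control covers
both signs by doubling the expected cluster count). Suprathreshold voxels are
grouped by 26-connectivity (configurable 6/18/26). The expected number of
clusters E[m] is the t-field expected Euler characteristic, Σ R_d ρ_d(u),
with resel counts R_d from the mask volume and its bounding box in FWHM
units, and ρ_d the standard t-field EC densities. The cluster-extent tail
uses the classical approximation P(n ≥ k) = exp(−β k^{2/3}) with β matched to
the expected cluster size E[n] = E[suprathreshold voxels]/E[m]; corrected
p = 1 − exp(−E[m_total]·P(n ≥ k)). Clusters with p below the cluster
threshold (default 0.05) are kept, largest first, with peak t and world-space
peak coordinates (so MNI-space inputs give MNI peaks).

A nonparametric validator is built in: group labels are permuted in the
design, the GLM re-fit, and the maximal cluster extent collected, giving
add-one permutation p-values per cluster. On simulated cohorts the two
routes select the same dominant cluster.

Measured calibration at the default conditions (50 null cohorts, 28+28, 16³):
the voxelwise two-sided p<0.001 exceedance rate is statistically compatible
with 0.001 (the CV map's mild skewness makes the t test slightly
conservative; the SD map and Gaussian controls sit at 0.001), and no null
cohort produced a surviving corrected cluster.

Scalar statistics mirror a clinical Table-1: Pearson chi-square without
continuity correction (df 1) for sex; the same GLM machinery for
covariate-adjusted group tests on scalars (equal to the pooled two-sample t
when no covariates are given); and partial correlation — Pearson correlation
of residuals after regressing both variables on [intercept | covariates],
with p from t = r√((n−2−k)/(1−r²)). Clinical correlations are computed in
patients only (controls have no disease duration), with age and sex
partialled out, on *raw* (un-z-scored) cluster-mean CV.

## Classification

The default feature is the cluster-mean CV within the group-difference
cluster — one scalar per subject. The classifier is a soft-margin linear SVM
(hinge loss, C = 1; C is a free parameter with no tuning performed), with
training-fold standardization applied before fitting and the held-out fold
transformed by the training parameters. Scores of exactly 0 predict control.

Cross-validation: LOOCV by default, stratified seeded k-fold (default k=10)
for comparison; k = n reduces exactly to LOOCV. Metrics come from held-out
predictions only: accuracy, sensitivity (patient = positive), specificity,
and AUC as the Mann-Whitney rank statistic on pooled held-out decision
scores. Significance uses a label-permutation test: each iteration shuffles
the label vector (group sizes preserved) and re-runs the *entire* CV;
p = (1 + #{null ≥ observed}) / (1 + n_perm), which can never be 0. Default
5,000 iterations.

Two feature-selection modes are exposed. The *faithful* mode selects the
cluster on the full sample and then cross-validates — the procedure clinical
studies typically report, which is optimistically biased because every test
subject contributed to feature selection. The *nested* mode re-selects the
cluster inside each training fold (falling back to the peak voxel when no
cluster survives in a fold), giving an unbiased estimate; comparing the two
quantifies the selection bias.

Because the permutation loops re-run the CV thousands of times on a single
feature, single-column problems use an exact 1-D soft-margin SVM solver
(enumeration of KKT-consistent support-vector configurations; any KKT point
of this convex QP is a global optimum) that is ~10× faster than the
general-purpose path. Multi-column feature matrices use scikit-learn's SVC,
and the tests verify the two agree decision-for-decision on random problems,
alongside a brute-force primal-minimization oracle.

A caution documented by the tests: under the null, LOOCV accuracy is not
centred on 0.5 — removing one subject tilts the balanced training set
against the held-out class, so uninformative features score *below* chance
on average. Permutation inference is unaffected (its null shares the bias),
but raw LOOCV accuracies should never be compared to 0.5 by eye. The
permutation p-value itself is slightly conservative (super-uniform) because
accuracy is discrete and ties count against the observed value; with the
add-one formula this is the standard, valid behaviour.

## Problem sizes and numerical choices

Defaults were chosen so a full cohort analysis (simulate → dALFF → GLM →
cluster correction → LOOCV) runs in seconds and the repeated-cohort
calibration suites in minutes on one core: 16³ grid, ~1,500 mask voxels,
56 subjects, 126 windows. Key tolerances: ALFF agrees with the direct-DFT
oracle to 1e−10 relative; the covariate-free GLM t agrees with the textbook
two-sample t to 1e−10; smoothness estimates are accepted within 20% (the
discrete-derivative estimator reads ~1.18 voxels on white noise, within that
band of the voxel-size floor). Ties in SVM decision scores break toward
control; cluster tables sort by extent, ties by discovery order; degenerate
inputs (empty masks, zero-variance maps, single windows, missing classes)
raise or warn as documented in each docstring.

## Known limitations

- RFT cluster p-values use the box-resel approximation for non-box masks and
  the k^{2/3} extent tail; both are standard but approximate at low
  smoothness (< ~2 voxels FWHM). The permutation corrector is the fallback
  when assumptions are in doubt.
- The synthetic effect is a single spherical region with a sinusoidal
  envelope; real dynamic-amplitude alterations are unlikely to be so
  regular. Recovery rates reported by the acceptance suite are specific to
  these conditions.
- The faithful classification mode inherits the circularity of
  select-then-validate designs; its accuracies describe the procedure, not
  generalization to new samples. Use the nested mode for the unbiased
  number.
- With ~1.3 envelope cycles per run, per-subject CV depends on the random
  envelope phase; this is realistic (scan windows sample arbitrary phases of
  slow fluctuations) but adds between-subject variance that caps power at
  small n.
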