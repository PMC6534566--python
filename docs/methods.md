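# Methods

This note documents the models, estimators, and design choices behind
`fct`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Preprocessing and connectivity estimation

**Motion censoring.** A frame is censored when FD strictly exceeds
0.2 mm or DVARS strictly exceeds 75 (boundary values are kept — the
thresholds are read as strict inequalities), together with 1 frame
before and 2 frames after, clipped at run boundaries. Surviving
segments shorter than 5 frames are removed, and runs with strictly more
than 50% of frames censored are discarded. DVARS is unitless on
synthetic data; the generator calibrates its scale to the standard
threshold rather than the other way around.

**Nuisance regression.** Per ROI, an intercept, a linear trend, and a
global regressor are fit by OLS on kept frames only; residuals are
formed at all frames. The global signal is approximated at ROI level by
the mean across ROIs, with one deliberate refinement: ROI *j* is
regressed on the mean of the *other* ROIs. Regressing every ROI on the
all-ROI mean forces the residual columns to sum exactly to zero on kept
frames, which makes the downstream AR least-squares design exactly
singular — an artifact of the ROI-level approximation that the
vertex-level operation on real data does not have. The leave-one-out
variant keeps the interpretation (shared-signal removal) while avoiding
the exact collapse. `regress_global=False` reproduces the
no-global-regression control.

**Static FC** is the per-run Pearson correlation over kept frames,
Fisher z-transformed off the diagonal, averaged over runs, transformed
back, diagonal reset to 1. Correlations are clipped at 1 − 1e−12 before
`atanh`.

**Dynamic FC** is the least-squares AR-1 coefficient matrix over all
frame pairs (t−1, t) that are consecutive, both kept, and inside one
censoring segment of one run; transitions across gaps and run
boundaries contribute no pairs. No intercept is included (the series
are detrended upstream; an explicit check in the tests compares the fit
to a brute-force regression over the enumerated pair list).
`R^2 = 1 − ||Cov(eps)||_F / ||Cov(x)||_F` uses unbiased covariances;
the ratio is essentially normalization-invariant.

A practical note on identifiability: a *noiseless* AR trajectory from a
single initial state is numerically rank-deficient (the Krylov sequence
collapses), so exact-identification checks use several noiseless
segments with fresh initial states. With noise, the accuracy of `A` at
a given length is governed by `tr(Σ_eps) tr(Σ_x^{-1})/T`; matrices whose
modes are all damped near the spectral radius are identified most
accurately, while realistic heterogeneous damping raises the error
floor — the identification tests therefore use near-uniformly damped
test matrices, while the cohort generator keeps heterogeneous, more
realistic dynamics.

## Behavioral preparation

Measures are residualized on an intercept plus covariates (age, gender,
race, education, mean FD; categorical covariates one-hot encoded with
the first level dropped), then quantile normalized by the rank-based
inverse-normal transform with average ranks for ties and offset
(r − 0.5)/n — a symmetric, simple variant among the common choices.
The order (residualize, then normalize) follows the standard pipeline
for variance-component analysis.

## Similarity kernels

Whole-brain kernels correlate subjects' vectorized FC: the strict upper
triangle for static FC (R(R−1)/2 entries) and all R² entries, diagonal
included, for dynamic FC (the AR matrix is non-symmetric and its
diagonal is informative). Block-restricted variants use the diagonal
block (upper triangle for static, all entries for dynamic) or the
off-diagonal block (both directed blocks concatenated for dynamic, to
preserve asymmetry). Static correlations are vectorized in r-space;
Fisher-z vectorization is available but off by default.

For the contribution analysis a second kernel family is used: each FC
entry is standardized across subjects and each unordered (sub)network
block pair *b* gets the Gram kernel `F_b = Z_b Z_b^T / P_b` with weight
`w_b = P_b / P`, so that `Σ_b w_b F_b` reconstructs the standardized
whole-matrix kernel exactly (tested to 1e−10). Per-subject Pearson
normalization would break this additivity, which is why the
entry-standardized family is used only here, clearly labeled.

## Variance-component estimation

The estimator is method-of-moments (Haseman–Elston / MINQUE style):
for measures p, q and kernel basis {F_1..F_K, noise}, solve
`G σ = b` with `G_kl = <F_k, F_l>_F` and `b_k = y_p^T F_k y_q`, then
symmetrize. The estimator is deterministic, unbiased, and fast at desk
scale; a restricted-maximum-likelihood implementation (eigendecomposition
plus 1-D profile search) serves as an independent oracle in the tests
for the single-kernel, single-measure case.

One correction to the textbook presentation matters in practice.
Behavioral columns are centered (the model has zero mean), and centering
removes the grand-mean component from `Y` but not from `F`. Since
FC-similarity kernels always carry a large shared component, the naive
basis {F, I} is severely biased — in our checks, an estimated M near 0
at a true M of 0.3. The implementation therefore uses the
projection-consistent basis {PFP, P} with `P = I − 11^T/n`, for which
`Cov(PY) = Sigma_c PFP + Sigma_e P` holds exactly and the estimator
agrees with the REML oracle.

Negative diagonal components are truncated at zero for *reporting*
(keeping M and M_i inside [0, 1]); raw estimates are retained. The
moment system is rejected when its condition number exceeds 1e10
(e.g. F = I, which is unidentifiable). Kernels are used as printed
(unit diagonal, no trace normalization); measures are variance-1 by
construction after quantile normalization.

## Jackknife inference

Delete-1 jackknife over subjects: sub-kernels by row/column deletion,
behavior by row deletion, aggregated by the standard estimates of the
mean difference and its variance, with a two-tailed standard-normal
p-value. Leave-one-out refits are computed by exact algebraic downdates
of the cached Gram entries and quadratic forms, verified in the tests
against direct refits; centering and projection are applied once at the
full-sample level (re-projecting per deletion would break the exact
caching and differs by O(1/N)).

Difference statistics (overall M, per-measure T, category means, the
task-minus-self interaction) are computed on the **raw** components:
truncation at zero inflates each model's M by an amount that grows with
its kernel count, so differences of truncated estimates carry a
spurious bias (clearly visible when comparing the two-kernel combined
model against the dynamic-only model) and their null distribution is
off-center. The per-measure T is the jackknife z of the M_i difference
(dynamic minus static; positive T = dynamics explain more), ranked in
descending order with name tie-breaks. Unclassified measures are
excluded from category contrasts. Jackknife SDs (`sqrt(V_jack)`) are
the error bars reported throughout.

**Known limitation.** Under an *exact-zero* association null (behavior
independent of both kernels) the M-difference is a degenerate quadratic
statistic — its linear influence function vanishes — and the delete-1
jackknife then overestimates its variance by roughly a factor of two, a
classical property of the jackknife for degenerate U-statistics. The
resulting z-test is conservative in that regime (empirically ~0–1
rejections per 200 replicates at α = 0.05 instead of ~10). Under
non-degenerate nulls and alternatives — the regime of real cohorts,
where M is far from zero — the jackknife variance is consistent and the
test is well behaved (the power checks in the suite reject essentially
always at a true single-model gap of 0.15, N = 200).

**Block contributions.** The multi-kernel model over the weighted block
kernels {w_b F_b} is fit on the task-performance measures; each block's
reported contribution is its truncated explained-trace share, scaled by
the mean diagonal of its kernel so contributions sum on the per-subject
variance scale. The significance test jackknifes the *raw* explained
trace of each block (scale-invariant z): with 36 kernels, the
total-variance denominator of a share is weakly identified in single
leave-one-out samples and a ratio statistic would be unstable. p-values
are BH-FDR corrected across blocks at q = 0.05. The exact reformulation
behind published per-block contribution figures is not public; this
additive-decomposition reading is one defensible implementation and is
labeled as such.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not the biophysics of BOLD (no hemodynamics, no spatial geometry, no
physiological noise spectra — conclusions about those features cannot
be drawn from these tests).

- **Parcellation**: contiguous assignment of ROIs to 8 labeled networks
  (7 cortical + subcortical), default 40 ROIs; each network optionally
  split into contiguous subnetworks.
- **Dynamics**: a shared base AR matrix (dominant positive diagonal ≈
  hemodynamic autocorrelation, stronger within- than between-network
  coupling) plus, per subject, a combination of 5 shared connectivity
  modes (standard-normal loadings, mode scale 1.25) and idiosyncratic
  noise (scale 0.05), rescaled to spectral radius 0.9. The shared modes
  are what make some subject pairs genuinely more similar than others;
  purely i.i.d. perturbations would give a constant off-diagonal
  (degenerate) similarity kernel. At the default calibration the fitted
  AR R² lands in the 0.55–0.85 band across subjects.
- **Runs**: 2 runs × 600 frames per subject (burn-in 200, discarded),
  innovation covariance the identity.
- **Motion**: baseline FD ≈ 0.04–0.12 mm and DVARS ≈ 40–55, with
  spikes exceeding both thresholds; the spike count is searched so the
  realized censored fraction lands within ±0.05 of the target (default
  0.10). Infeasible targets (short runs) raise.
- **Behavior** (two-stage): the static and dynamic kernels are computed
  from the simulated time series by the pipeline's own code, then `Y`
  is drawn exactly from the matrix-normal model given those kernels —
  `C = L_F U L_c^T` per kernel with symmetric PSD square roots
  (eigen-clipping at −1e−10) — so the recorded true M equals the trace
  formula exactly. Default loadings: task measures 0.5 on the dynamic
  kernel only; self-reported measures 0.25 on each kernel; unclassified
  measures 0; residual variance fills each measure to 1 (true overall
  M = 0.417). This is the design under which the qualitative
  task/self dichotomy is expected: it is a *direction* prediction, not
  a quantitative reproduction of any published value.
- **Covariates**: age, gender, race, education, and the realized mean
  FD, with small linear effects added to the raw measures so the
  behavioral preparation step performs real work. Quantile
  normalization is rank-based, so the true M survives preparation only
  approximately; estimator-level validation therefore bypasses
  preparation, while the end-to-end pipeline check is qualitative.
- **Determinism**: all randomness descends from one root seed through
  named substreams per stage; rebuilding a cohort from the same config
  reproduces the bundle byte-for-byte.

For estimator-level studies that need many cohorts, similarity kernels
are drawn directly from a factor model (`sample_similarity_kernel`):
a shared backbone raising the off-diagonal level plus low-dimensional
factors creating structured inter-subject variation. The REML-oracle
agreement study uses the backbone-only variant — the regime of
whole-brain FC-similarity matrices, which are dominated by a global
shared component; with strongly factor-structured kernels the moment
and likelihood estimators weight eigendirections differently and their
per-cohort scatter grows, though both remain unbiased.

## Problem sizes and numerical choices

Default study conditions: N = 120 subjects, 40 ROIs, 2 × 600 frames,
Q = 24 measures — the structure of a large resting-state study at
roughly one-tenth scale per axis, chosen so the full pipeline completes
in seconds and simulation studies in minutes. Tolerances: PSD
eigen-clipping at −1e−10; moment-system condition limit 1e10; atanh
clipping at 1 − 1e−12; jackknife z with p = 1 when both the estimate
and its variance vanish (identical models). Ties in ranking are broken
by measure name for determinism.
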