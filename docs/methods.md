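# Methods

This note documents the models, parameter choices, numerical decisions,
and known limitations of `epidyn`. Everything stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Macroscale: feature gradients

Each regional BOLD series (>= 64 frames) is summarized by a battery of
42 named statistics in four families:

- *distribution*: mean, sd, skewness, kurtosis, quantiles {5, 25, 50,
  75, 95}%, IQR, median absolute deviation, range, fraction of samples
  beyond 2 sd;
- *autocorrelation*: ACF at lags 1-10, first zero-crossing lag, 1/e
  decay lag, spectral power fractions in [0.01, 0.027], [0.027, 0.073]
  and [0.073, 0.1] Hz, spectral centroid, log-log spectral slope;
- *entropy-variability*: sample entropy (m = 2, r = 0.2 sd),
  permutation entropy (order 3, normalized), StatAv(5), sliding-window
  sd ratio, 10-bin histogram entropy, root-mean-square of successive
  differences;
- *nonlinear-model*: AR(1) coefficient, AR(2) coefficients and one-step
  prediction error variance, time-reversal asymmetry at lags 1 and 2.

The battery is deliberately compact; the gradient pipeline is agnostic
to battery size, and tests assert pipeline behavior, not equivalence to
any larger feature library. Features that are non-finite or constant
across regions for any subject are removed for all subjects (shared
filtering). Rows are normalized across regions by
`y = 1 / (1 + exp(-(x - median) / (1.35 IQR)))` — 1.35 IQR approximates
the sd for Gaussian data, making the transform robust to outliers —
followed by a linear rescale to [0, 1]. The pre-rescale transform is
invariant to positive affine transformations of the raw feature.

PCA treats regions as observations and features as variables
(feature-wise centering). Centering regions instead would remove each
region's mean feature level and change the first component; we chose the
standard observation/variable orientation and flag this as the one place
where a different convention could alter results. Component signs are
fixed by nonnegative correlation with the anterior-posterior centroid
coordinate (or the region index when no parcellation is supplied).

Individuals are aligned to a reference computed from the control group
only: orthogonal Procrustes (rotation/reflection, no scaling, columns
centered), top k = 10 components aligned, the first two analyzed.

Group inference per region uses the two-sided t statistic of the group
regressor with nuisance covariates (age, sex) partialled out, a
Freedman-Lane permutation null (reduced-model residuals permuted, fitted
part added back), and family-wise error control by the max-|t|
distribution computed separately within each hemisphere. The calibration
of this test under the null is the pipeline's core statistical guarantee
and is measured by the acceptance suite (rejection rate at alpha = 0.05
within [0.01, 0.10] over 200 repetitions). Network-wise comparisons use
subject-level means over the seven functional communities at Bonferroni
alpha/7.

The FC gradient (the spatial axis that parameterizes the mean-field
model) is a diffusion-map embedding of the FC matrix: rows sparsified to
their top decile, cosine affinity between sparsified profiles,
anisotropic normalization with alpha = 0.5, automatic diffusion time
(eigenvalue scaling lambda / (1 - lambda)), first nontrivial component,
z-scored. For small parcellations (< ~30 regions) the 90th-percentile
sparsification keeps very few entries per row; tests therefore use
either structured matrices or moderate sizes.

## Microscale: parametric mean-field model

Reduced Wong-Wang gating dynamics per region with the four standard
drive components (recurrent input, external input, connectome-weighted
inter-regional input, additive noise), Euler-Maruyama integration, and
the gating variable clamped to [0, 1] after each step (gating semantics;
prevents noise-driven escape). Fixed neural constants: a = 270 /nC,
b = 108 Hz, d = 0.154 s, gamma = 0.641, tau_s = 0.1 s, J = 0.2609 nA.
The transfer function's removable singularity at a x = b is evaluated by
a second-order series with limit 1/d. Initial gating 0.001; the first
2 minutes of every session are discarded, which also covers hemodynamic
burn-in.

Balloon-Windkessel hemodynamics (kappa = 0.65 /s, gamma_h = 0.41 /s,
tau_h = 0.98 s, alpha = 0.32, rho = 0.34, V0 = 0.02, k1 = 7 rho, k2 = 2,
k3 = 2 rho - 0.2) are integrated with the same Euler step; the resting
state (0, 1, 1, 1) is an exact fixed point, so zero neural drive yields
exactly zero BOLD. Sessions are 600 s, 120 s discarded, sampled every
2 s: 240 frames. Training simulations use dt = 50 ms, evaluation
dt = 10 ms.

Regional parameters are linear in a cortical gradient; with the global
coupling G that is 7 free coefficients. The estimation box is
RC in [0, 10], I in [0, 0.5] nA, sigma in (0, 0.01], G in [0.5, 10];
coefficient search ranges are chosen so these boxes are reachable
(slopes |a_w| <= 3, |a_I| <= 0.15, |a_sigma| <= 0.002). Candidates whose
implied regional parameters leave the box are penalized (cost 10 plus
overflow), never clipped.

## Fitting

Cost = (1 - r) + KS, with r the Pearson correlation between
upper-triangular entries of empirical and simulated static FC (group FC
averaged across subjects via Fisher z) and KS the exact two-sample
Kolmogorov-Smirnov statistic between upper-triangular FCD entries,
averaged over per-subject empirical FCD matrices. The FCD window is 30
frames (60 s) with step 1 — the unique window length for which a
240-frame session yields the canonical 211 x 211 FCD. The exact-ECDF KS
avoids a histogram bin-count free parameter and upper-bounds any binned
variant.

CMA-ES (in-package implementation of the standard (mu/mu_w, lambda)
strategy; population 4 + floor(3 ln 7) = 9, initial step 25% of each box
width, box-normalized coordinates) runs `n_iterations` generations from
each of `n_initializations` random starts; the best offspring of every
generation is recorded, so the candidate count is exactly their product
(500 x 10 = 5,000 at full settings). All candidates are re-evaluated at
dt = 10 ms on validation targets with a single fixed noise realization
(common random numbers, so candidate ranking reflects coefficients
rather than simulation noise); the top 10 by validation cost proceed.
The test stage averages each finalist's cost over 5 fixed noise
realizations shared by all candidates: with a single realization the
winner is partly decided by realization luck, and averaging makes the
final ranking stable (`n_test_repeats`, default 5).

Group differences in fitted parameters are tested by shuffling subjects
between cohorts within each of the train/validation/test subsets,
refitting both groups completely, and comparing the observed
patient-minus-control RC and I maps to the permutation null, with
Benjamini-Hochberg correction across regions.

## Spatial surrogates

The variogram gamma(d) is estimated in 25 equal-width bins up to the
75th percentile of pairwise centroid distances, with Gaussian
distance-weighting of pair contributions (bandwidth 3 bin spacings —
narrow bandwidths leave short-distance bins dominated by a handful of
pairs); bins containing no pairs are flagged and excluded from fitting
and fidelity metrics. Surrogates are built by permuting the map,
smoothing with k-nearest-neighbor exponential-decay kernels over a grid
of neighborhood fractions {0.03, 0.05, 0.075, 0.1, ..., 0.9} (the
sub-0.1 entries reproduce short-range autocorrelation), and rescaling
the smoothed field by sqrt(alpha) plus sqrt(beta) white noise, with
(alpha, beta >= 0) fit by least squares so the surrogate variogram
matches the target across bins; the kernel with minimal mismatch wins.
Surrogates preserve the variogram but neither the values nor the ranks
of the original map.

The corrected association test computes Spearman rho between two maps
and an add-one two-sided p against the null of correlations with
surrogates of the first map, generated per hemisphere (inter-hemispheric
centroid distances cross the medial wall and are not meaningful
smoothness distances). Which map is surrogated is the caller's choice;
the pipeline surrogates the gradient-difference map.

## Synthetic cohorts

Centroids are placed on two hemispheric spherical caps (radius 60 mm) so
hemisphere-wise statistics are exercisable; the seven functional
communities are assigned cyclically within each hemisphere. Connectomes
emulate log(1 + streamline count): counts decay exponentially with
distance (default decay 60 mm) times lognormal noise, the strongest
edges are kept to the requested density (relaxed if the graph
disconnects), and weights are rescaled to maximum 1.

Default ground-truth coefficients (G = 1.5, a_w = 0.5, b_w = 1.0,
a_I = 0.02, b_I = 0.235, a_sigma = 0.0003, b_sigma = 0.004) place the
network in the stable low-activity regime near the bifurcation edge,
where connectome-propagated noise produces structured FC (off-diagonal
mean ~0.1-0.2, FC-SC coupling ~0.5) — the regime in which this model
family reproduces resting-state data. The hierarchy slope a_w = 0.5
spans roughly a factor-ten range of recurrent strength across the
gradient, a strong but plausible sensory-to-association hierarchy.

Pseudo-subjects share their group's parameters up to Gaussian jitter on
the external input (sd = 5% of the group's I span) — a stand-in for
subject-level variability, which group-level fits do not characterize —
and receive additive Gaussian measurement noise at SNR 5 relative to the
temporal fluctuation sd. Near the bifurcation edge this jitter
occasionally produces a weakly-coupled subject; this is treated as
realistic within-group heterogeneity. No scanner artifacts, motion, or
physiological noise are simulated, so passing tests demonstrate
correctness of the pipeline's statistics and estimator on model data,
not robustness to real-world artifacts.

Recovery experiments condition on the generating gradient: the cohort is
simulated from parameters linear in a known gradient, and the same
gradient is supplied to the fit targets, so the experiment isolates
coefficient estimation from gradient re-estimation (the empirical-style
pipeline instead derives the gradient from the group FC; on small
synthetic cohorts the FC gradient correlates only moderately with the
generating axis). The recovery benchmark is one fixed problem instance —
parcellation, connectome, gradient, and cohort — exactly as an empirical
study fits one dataset; the experiment seed drives optimizer
initialization and evaluation noise.

The benchmark cohort is pure model output: no subject-level parameter
jitter and no measurement noise, so the only between-subject variability
is the neuronal noise realization. This matters, and the reason is an
identifiability result measured during development. First, at this scale
and gating level the first-order effect of the recurrent-connection
slope on regional excitability (a_w J S, roughly 0.007 nA per gradient
unit) can be compensated by the external-input slope within its bounds,
so the *sign* of the hierarchy slope is constrained only by second-order
dynamical signatures. Second, subject-level jitter on I makes the
per-subject FCD targets a heterogeneous mixture that no single parameter
set can match (the generating parameters themselves score a KS distance
near 0.4); that misspecification further biases the landscape. Even on
homogeneous model output, however, the degeneracy does not fully
disappear: while the naive sign-flip of the generating parameters is
decisively worse (averaged test cost 0.76 vs 0.29), a *re-optimized*
inverted-slope family (much larger G and recurrent intercept, slope
reversed, input slope adjusted) reproduces the FC/FCD statistics as well
as the truth — within about 0.01 cost on fresh noise realizations — and
both families operate at plausible low firing rates. Which family a fit
returns therefore depends on optimizer initialization. What is robust is
axis recovery: the external-input map is recovered outright, and the
recurrent-connection map is recovered up to an overall sign. The
practical reading for real data: group-level fits of this model family
report the excitability axis robustly, but hierarchy-slope orientation
should be corroborated independently when parcellations are small.

A caution discovered during development and visible in the candidate
records: coarse 50-ms training systematically mis-ranks candidates very
close to the bifurcation edge (stable at 50 ms, saturating at 10 ms);
the validation re-evaluation at 10 ms is what eliminates them, and it
needs a diverse candidate pool (many initializations) to retain
well-behaved candidates of the correct hierarchy sign. Reduced-budget
recovery therefore keeps the full 10 initializations and shrinks only
the generation count.

## Problem sizes

Default experiment sizes: 8-12 regions for estimation experiments,
28-68 regions for map statistics and surrogates, 200 repetitions for
calibration rates, 200-1000 surrogates for variogram checks. These sizes
give stable statistics at desk scale; all are parameters, and the
full-size protocol (68 regions, 5,000 candidates) runs unchanged —
only slower.

## Known limitations

- Subject-level variability is a modeling stand-in; the fits are
  group-level.
- The feature battery is compact by design; feature identity in any
  larger battery is not emulated.
- Euclidean centroid distances, not geodesic surface distances, underlie
  variograms and surrogates.
- No conduction delays; interactions are instantaneous.
- Sign identifiability of the hierarchy slopes through the
  (1 - r) + KS objective is weak at very small parcellations; see the
  caution above.
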