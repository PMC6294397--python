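# Methods

`classim` simulates and analyses a 2AFC visual psychophysics experiment —
detection/discrimination of a luminance offset on the central bar of a
13-bar array embedded in Gaussian luminance noise — entirely in silico.
Every quantity the package reports is produced by running model observers
on synthetic stimuli and feeding their responses through the same
estimation machinery one would apply to human data.

## Stimuli and protocol

A stimulus is a 13-vector of luminance deviations from a 30 cd/m²
background, in cd/m². Each trial presents a target and a non-target
stimulus, `s[q] = n[q] + t[q]`: the noise `n` is iid zero-mean Gaussian
per bar with SD σ_N = c × 0.3 cd/m², c ∈ {1, 2, 4, 8} (contrast levels
1–4), and the signal `t` is zero except at the central bar, where it
takes ρ[q]. The four tasks fix (ρ[0], ρ[1]): bright (0, +ρ), dark
(0, −ρ), polarity discrimination (−ρ, +ρ), and mixed polarity (0, ±ρ
with a fair coin per trial). |ρ[1]| = snr_level × σ_N, snr_level ∈ 1–4,
so the nominal SNR equals the level. Conditions are constant within
50-trial blocks; double-pass blocks repeat the stimuli of trials 1–25 in
trials 26–50 under a random permutation (drawn without fixed points, so
a repeat never sits at its original within-half position).

Units are physical (cd/m² deviations) rather than normalized. This is
load-bearing: the divisive gain-control constants below (10 and 0.4) sit
inside the operating range of pooled filter responses only on this
scale. On a scale where σ_N is numerically 1–8, both normalization
stages are saturated at every contrast and the two-branch model loses
its contrast-dependent behaviour.

Not modelled: display gamma, spatial markers, fixation, presentation
timing, eccentricity geometry, monitor clipping of extreme luminances
(clipping would distort the noise statistics the estimators assume).
The foveal (temporal 2IFC) and peripheral (spatial 2AFC) protocols are
computationally identical here — both reduce to the difference rule over
two stimuli — and are carried only as a bookkeeping label.

## Model observers

All observers share a front end and a decision stage. The front end
convolves the stimulus with a unit-energy difference-of-Gaussians filter
`f_i = k·φ(x_i, σ1) − φ(x_i, σ2)` (defaults k = 4, σ1 = 5 arcmin,
σ2 = 20 arcmin), sampled every 9 arcmin over 25 taps (±108 arcmin, where
the surround has decayed below 10⁻⁴ of peak); boundaries are zero-padded
(background = 0 in deviation units). The decision stage computes a
scalar r per stimulus and chooses the target-designated stimulus iff
r_target − r_nontarget > 0, ties to the non-target.

Branches, per variant:

- linear branch `b_lin = s * f`; gain-controlled form
  `b_lin / (10 + (Σ b_lin)²)` (signed sum, as printed);
- nonlinear branch `b_nlin = b_lin²` elementwise; gain-controlled form
  `b_nlin / (0.4 + Σ b_nlin)` (pooled output saturates below 1);
- read-out `r = ⟨w, branches + e⟩`, with `w` an amplitude-1 Gaussian
  window over bar positions (SD σ_w = 40 arcmin; not renormalized — any
  rescaling is absorbed by the noise calibration) centered on the target
  bar;
- variants: #1 template (linear only), #2 energy (nonlinear only),
  #3 gain-controlled energy, #4 hybrid with gain control on the
  nonlinear branch only, #5 hybrid with gain control on both (its own
  parameters k = 6, σ1 = 2.5, σ2 = 10, σ_w = 10);
- MAX observer: `r = max(w × b_lin + e)` with σ_w = 40/80/120/160
  arcmin as the contrast level drops from 4 to 1 (an uncertainty model;
  the widening is imposed, not emergent).

Intrinsic noise `e` is iid Gaussian per read-out position, drawn fresh
for every stimulus, with an SD that is fixed per observer. Placements:
late (added after the branch nonlinearities; default), early (added to
the front-end output before squaring), and response-dependent
(|b_i|·e_i at the front-end output). For a purely linear observer these
are distributionally equivalent; they matter only for the nonlinear
branch.

### Noise calibration

The intrinsic-noise SD is set so that mean d′ over the 4×4 grid is ~1
(threshold performance), by bisection on log-SD with a fixed
random-number stream per evaluation (d′ per condition from proportion
correct via d′ = √2·Φ⁻¹(pc)). One wrinkle: the noiseless template
observer's mean d′ ceiling with the default 40-arcmin read-out window is
0.92 — the cosine between its effective template and the target is
0.365, and 2.5 × 0.365 < 1 — so a d′ = 1 target is unreachable for
variant #1 and reachable only degenerately (SD ≈ 0, hence perfect
double-pass agreement) for variant #4 (ceiling 0.94). The calibration
therefore caps its effective target at ceiling/√2: the point at which
internal noise equals the external-noise-driven variability of the
decision variable (N_int ≈ 1), the canonical threshold-regime
convention. The cap binds only when the ceiling is below √2 × target
and emits a warning; a strict mode (`on_low_ceiling="raise"`) errors
instead. Calibration uses 1500 trials per condition and a ±0.05
tolerance on mean d′; because the d′(SD) curve is shallow near
threshold, the returned SD can vary noticeably across calibration seeds
while the behaviour it produces (threshold-level performance) does not.

### Ideal observer

Template matching with `f = t[1] − t[0]` and no intrinsic noise; for the
central-bar tasks this reduces to comparing the central bars, and ideal
d′ equals the stimulus SNR, giving the efficiency denominator
(efficiency = (d′/SNR)²). Undefined for the mixed-polarity task.

## Double-pass internal noise

From pc (fraction correct) and pa (fraction of repeated pairs answered
identically), a two-parameter signal-detection model is inverted:
response = u(d_ext + ε_int), d_ext ~ N(d′_in, 1) fixed per stimulus
pair, ε_int ~ N(0, N_int) fresh per presentation. Forward map:
pc = Φ(d′_in/√(1+N_int²)); pa = E[p² + (1−p)²] with p = Φ(d_ext/N_int),
the expectation over d_ext evaluated by 101-node Gauss–Hermite
quadrature (a Monte-Carlo forward simulation is kept as the test
oracle). Estimation minimizes the squared (pc, pa) error on an 81×81
grid (N_int log-spaced in [0.01, 100], d′_in linear in [0, 10]; the
grid's forward values are cached, being data-independent) followed by
Nelder–Mead refinement on (d′_in, log N_int). Estimates with
1/5 < N_int < 5 are flagged plausible. Response bias is not modelled
(estimates are uncorrected), and the internal-noise distribution is
Gaussian only.

## Descriptors and drives

Noise samples are classified as n[q, z] by interval (q = 1 target) and
outcome (z = 1 correct). First order: h[1] = μ(n[1,1]) − μ(n[1,0]),
h[0] = μ(n[0,0]) − μ(n[0,1]), h = h[1] + h[0]; the Fourier-power variant
replaces each sample with its one-sided DFT power profile (7
frequencies, DC retained; frequency axis in cycles/deg from the
9-arcmin sampling) before the same combination. Second order:
H = cov(n[1,1]) − cov(n[1,0]) − cov(n[0,1]) + cov(n[0,0]), sample
covariances with the n−1 denominator.

The drive λ_d = ln(RMS_d / RMS*_d) measures structured modulation
against the decoupled (response-shuffled) expectation. With
k = √(2/(m·pc·(1−pc))):

- RMS*₁ = k·σ_N for the full h; components h[q] are smaller by √2;
- RMS*₂ = √2·k·σ_N² for the H diagonal; the off-diagonal region is
  smaller by a further √2, so λ₂ is computed over the whole matrix after
  multiplying the off-diagonal by √2 onto the diagonal reference.

These closed forms follow from the sampling variance of differences of
class-conditional means (respectively variances/covariances:
var(s²) = 2σ⁴/(n−1), var(sample cov) = σ⁴/(n−1) for independent
coordinates) and are validated against decoupled Monte-Carlo simulation
in the test suite. Two finite-sample facts worth knowing when reading
drives near zero:

1. RMS* is the root of the *expected mean square*; the expected *RMS*
   of a 13-entry region is ~2–3% lower (Jensen), so decoupled λ₁
   estimates average ≈ −0.02 rather than 0 (λ₂ over the full 169-cell
   matrix: ≈ −0.005). Pooling squared RMS values removes the offset.
2. For strongly driven observers, response conditioning slightly
   shrinks the sampling variance of the classified covariances relative
   to the decoupled null; this biases λ₂ by roughly −0.03 to −0.05,
   independent of m, growing with the external-noise share of the
   decision variable (i.e. with contrast at fixed intrinsic noise).
   The expected *value* of H under a linear observer is still exactly
   zero — the ± combination cancels the conditional-variance
   modulations along the template — so this is purely a null-width
   effect.

Eigen-decomposing H yields filter-like vectors comparable to h.
Significance: eigenvalues are compared against a band of
`threshold_multiplier` (default 3) × the SD of pooled eigenvalues from
decoupled surrogates (responses reassigned to trials; pc preserved
exactly). The null SD is pooled over ranks, not computed per rank (a
flag-worthy alternative; pooled matches the one-band presentation the
method is normally given). Because leading eigenvalues of energy-like
kernels are nearly degenerate, individual eigenvectors rotate freely
within the top subspace from estimate to estimate; `eigen_sharpness`
therefore pools the eigenvalue-weighted power spectra of the top-k
(default 3) eigenvectors before taking the spectral centroid, which is
invariant to such rotations.

## Metrics

- Sharpness: spectral centroid of the unit-sum one-sided power spectrum,
  in cycles/deg; identical code path for first-order descriptors and
  eigenvectors. Caveat (inherent to the estimator): a noise-dominated
  profile has a flat spectrum, so low-information estimates bias the
  centroid toward the middle of the frequency axis.
- Nonlinearity/linearity: marker 1 = λ[1] − λ[0]; marker 2 =
  (λ₁ − λ₂)·sign(λ₂) with sign(0) = 0; aggregate = marker 1 + marker 2;
  linearity = −aggregate. Marker 2 is kept in its printed form; note it
  is non-monotone by construction (positive for λ₂ > λ₁ systems *and*
  for λ₁ ≫ λ₂ > 0 systems) and, through the sign gate, a per-run coin
  flip of amplitude ~λ₁ whenever λ₂ is statistically null — so
  aggregate values are interpretable only on average over runs, which
  is how the package's tests and examples use them.
- Dependence: Pearson correlation between a metric's 16 per-condition
  values and the contrast (or SNR) level index 1–4; correlating against
  the index is identical to correlating against log₂ of the contrast
  multiplier {1,2,4,8} by affine invariance. A raw-multiplier variant
  would differ; index/log spacing is the default here.
- Separability of a 4×4 surface S: marginal prediction
  S*_ij = (row_i)(col_j)/grand total (equal to S iff S is an outer
  product) and the SVD index v₁²/Σv_i² ∈ [0.25, 1] for 4×4.
- d′ = √2·Φ⁻¹(pc), the standard 2AFC difference-rule conversion, with
  pc clipped to [1/(2m), 1−1/(2m)] when a trial count is supplied.
- Wilcoxon signed-rank (two-tailed) and Friedman tests are thin
  scipy.stats wrappers with input validation.

## Experiment drivers

`run_grid` runs one observer over the 16 conditions of a task:
per condition it simulates `n_trials_per_condition` fresh trials
(descriptors, drives, sharpness, linearity, d′, efficiency) and
`n_doublepass_pairs` repeated pairs (pc, pa → internal-noise fit), then
assembles metric surfaces, dependence coefficients and separability
indices. Stimulus generation and responses are vectorized (all trials
of a condition as one matrix product), which is what makes the
acceptance-scale runs (millions of trials) take seconds.

`dipper` measures threshold-versus-pedestal curves on noiseless stimuli:
target = pedestal + Δρ, non-target = pedestal, both at the central bar
only. Per pedestal and simulation, pc(Δρ) is estimated over a geometric
Δρ sweep (absolute steps capped at 5% of the pedestal by densifying the
sweep) and the 75% threshold extracted by linear interpolation of pc
versus log Δρ, with up to 3 automatic sweep widenings; thresholds are
averaged over simulations. The pedestal axis spans two decades anchored
half a decade below the measured detection (pedestal-0) threshold —
no absolute anchor exists, so the curve's shape, not its x-position, is
the meaningful output. Branch-specific curves (`branch_configs`,
`dipper_curves`) treat the linear branch alone (= template variant) and
the gain-controlled nonlinear branch alone (= gain-controlled energy
variant) as observers in their own right, each recalibrated to
threshold: with the hybrid's noise level the saturating nonlinear
branch cannot reach 75% correct at any increment (its response ceiling
is below what the noise requires), which would make its curve
unmeasurable rather than steep. Cells where saturation makes 75%
unreachable are NaN.

`first_trial_filter` retains trial 1 of each block (2% of the data mass
at 50-trial blocks), the subset untouched by within-block feedback.

## What the synthetic data can and cannot show

The generator reproduces the stimulus statistics, condition grid and
double-pass structure of the laboratory protocol exactly, and the model
observers are fully specified — so every estimator in the package can be
validated against known ground truth (known kernels, known internal
noise, known separable surfaces). What passing tests do *not* show is
anything about human vision: simulated observers have no sequential
dependencies, no learning, no lapses, no response bias, and their
"between-subject" spread is just seed-to-seed variation. Model-level
signatures (the hybrid's contrast-driven retuning signs, the dipper
shapes, the MAX model's non-negative second-order diagonal) are
reproduced as qualitative patterns; no human-derived number is targeted.

## Problem sizes and numerical choices

Defaults used by the test suite and acceptance script (chosen as the
package's own working scales): descriptor nulls at 100 × 6000 trials;
decoupled validation at 200 shuffles of 10⁴ trials; grid runs at
6 × 10⁴ trials/condition with 500 double-pass pairs; eigen-recovery at
3 × 10⁵ trials/cell (second-order estimates converge as √m and the
lowest-contrast cell is the binding constraint); dipper at 10 pedestals
× 25 simulations × 1000 trials. Optimizer tolerances: internal-noise
fit refined to 10⁻¹² objective tolerance; calibration bisection stops
within ±0.05 of the d′ target or 40 iterations. Degenerate inputs fail
loudly: empty classification bins, pc ∈ {0, 1}, zero profiles,
asymmetric H, negative noise SDs and invalid conditions all raise
ValueError with a message naming the offending quantity.
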