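# classim

Simulation and reverse-correlation analysis of noisy-bar visual
psychophysics: model observers, double-pass internal-noise estimation,
classification-image descriptors, and a metric suite for
contrast/SNR-dependent tuning — all runnable end-to-end on synthetic
data.

## The problem

A classic paradigm for characterizing human pattern vision presents two
arrays of 13 vertical bars whose luminances are perturbed by Gaussian
noise (SD σ_N = c × 0.3 cd/m², c ∈ {1, 2, 4, 8}); one array additionally
carries a luminance offset ρ = SNR × σ_N on its central bar, and the
observer reports which. Three families of tools then expose the
underlying sensory computation:

- **Double-pass internal noise.** Repeating identical stimulus pairs
  measures response consistency `pa`, which together with accuracy `pc`
  constrains a 2-parameter signal-detection model,
  `response = u(d_ext + ε_int)` with `d_ext ~ N(d′_in, 1)` and
  `ε_int ~ N(0, N_int)` — giving the internal-to-external noise ratio
  `N_int`.
- **Classification images.** Averaging classified noise samples gives
  the first-order descriptor `h = h[1] + h[0]`
  (`h[1] = μ(n[1,1]) − μ(n[1,0])`); the signed sum of class-conditional
  covariances gives the second-order descriptor
  `H = Σ_{q,z} (2δ_qz − 1) cov(n[q,z])`, which exposes energy-like
  (squaring) nonlinearities and is eigen-decomposed into filter-like
  components. The *drive* `λ_d = ln(RMS_d / RMS*_d)` scores each
  descriptor against its decoupled-process expectation
  `RMS*₁ = kσ_N`, `RMS*₂ = √2 kσ_N²` (diagonal), with
  `k = √(2/(m·pc·(1−pc)))`.
- **Tuning metrics.** Spectral-centroid sharpness, a drive-based
  linearity index, Pearson contrast/SNR dependence, separability of 4×4
  metric surfaces (marginal prediction and SVD index), d′ = √2 Φ⁻¹(pc)
  and efficiency against the ideal observer (ideal d′ = SNR).

The package implements all of this plus the model observers the
estimators are validated on: a difference-of-Gaussians front end feeding
a linear branch and a squaring (energy) branch with optional divisive
gain control (`b̂_lin = b_lin/(10 + (Σb_lin)²)`,
`b̂_nlin = b_nlin/(0.4 + Σb_nlin)`), a Gaussian read-out window, a MAX
(uncertainty) rule, and the ideal observer — with intrinsic noise
calibrated to threshold (mean d′ ≈ 1). The headline model-level result
the pipeline reproduces: in the hybrid two-branch observer, gain control
silences the energy branch as contrast rises, so *tuning sharpness and
internal noise fall with contrast while linearity rises*, and the same
model yields the classic dipper (threshold-versus-pedestal) function.

## Worked example

```python
import numpy as np
import classim as ci

rng = np.random.default_rng(2)

# a threshold-calibrated linear template observer
config = ci.calibrated(ci.ObserverConfig.for_variant(1), rng=rng)

# double-pass internal noise across contrast at SNR level 2
for c in (1, 2, 3, 4):
    cond = ci.ConditionSpec(task="bright", contrast_level=c, snr_level=2)
    c1, c2 = ci.simulate_double_pass_pairs(cond, 2000, config, rng)
    summary = ci.summarize_pair_arrays(c1, c2)
    est = ci.estimate_internal_noise(summary)
    print(c, round(summary.pc, 3), round(summary.pa, 3),
          round(est.N_int, 3))
```

prints (seed 2):

```
1 0.567 0.547 2.656
2 0.618 0.654 1.186
3 0.670 0.785 0.603
4 0.689 0.871 0.341
```

Reading: with a fixed late additive intrinsic-noise source, raising
stimulus contrast strengthens the external-noise drive of the decision
variable, so response agreement `pa` climbs from near-chance (0.55) to
0.87 and the fitted internal-to-external noise ratio `N_int` falls from
2.7 to 0.34 — the negative contrast dependence of internal noise that a
fixed-noise observer must show.

The `examples/` directory holds one short script per capability:
protocol + ideal observer, double-pass estimation, classification
images (template vs energy observers), the hybrid model's full
contrast × SNR grid with dependence/separability summaries, and the
branch-by-branch dipper functions. Each prints the numbers it computes
and one line on what they mean. `docs/methods.md` documents the models,
estimators, conventions and limitations.

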