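"""Model observers: two-branch architecture, MAX rule and the ideal observer.

Every observer shares a difference-rule decision stage: it computes a
scalar decision variable r for each of the two stimuli of a trial and
chooses the target-designated stimulus iff r_target - r_nontarget > 0
(ties go to the non-target).

The stimulus first passes a linear front end, a difference-of-Gaussians
(Mexican-hat) filter f applied by convolution:

    b_lin = s * f

The *linear branch* forwards b_lin, optionally divisively normalized:
b_lin / (10 + (sum b_lin)^2).  The *nonlinear branch* squares each
element first, b_nlin = b_lin^2, optionally normalized as
b_nlin / (0.4 + sum b_nlin).  A Gaussian read-out window w (SD sigma_w,
an attentional window over bar positions) pools the branch sum together
with intrinsic noise e:

    r = <w, branches + e>

Variants: #1 template (linear branch only), #2 energy (nonlinear branch
only), #3 gain-controlled energy, #4 hybrid with gain control on the
nonlinear branch only, #5 hybrid with gain control on both.  The MAX
observer instead takes r = max(w x b_lin + e), with a contrast-dependent
window width.

Intrinsic noise is iid Gaussian per read-out position, drawn fresh for
every stimulus, with fixed SD calibrated once per observer so that mean
d' across the condition grid is ~1 (threshold performance).  It can be
placed late (after squaring; default), early (before squaring) or made
response-dependent (scaled by the magnitude of the front-end output).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .stimuli import (BAR_SPACING_ARCMIN, Block, ConditionSpec, StimulusBatch,
                      Trial, full_grid, sample_stimulus_batch)

__all__ = [
    "VARIANTS",
    "VARIANT_NUMBERS",
    "DOGSpec",
    "ObserverConfig",
    "BranchOutputs",
    "ResponseRecord",
    "dog_filter",
    "frontend",
    "gain_control_linear",
    "gain_control_nonlinear",
    "branch_outputs",
    "readout_weights",
    "decision_variable",
    "decision_variables",
    "respond",
    "respond_batch",
    "write_response_log",
    "ideal_respond",
    "ideal_respond_batch",
    "calibrate_noise_sd",
    "calibrated",
    "simulate_session",
    "simulate_condition",
    "simulate_double_pass_pairs",
]

VARIANTS = ("template", "energy", "gc_energy", "hybrid_gc_nlin",
            "hybrid_gc_both", "max")

#: the conventional numbering of the two-branch variants
VARIANT_NUMBERS = {1: "template", 2: "energy", 3: "gc_energy",
                   4: "hybrid_gc_nlin", 5: "hybrid_gc_both"}

_GC_LIN_SEMISAT = 10.0
_GC_NLIN_SEMISAT = 0.4


@dataclass(frozen=True)
class DOGSpec:
    """Difference-of-Gaussians front-end filter.

    f_i = k * phi(x_i, sigma1) - phi(x_i, sigma2), sampled every
    ``spacing`` arcmin over ``support`` taps and normalized to unit
    energy (sum of squared taps = 1).  Defaults give the standard
    center-surround shape with a 5-arcmin excitatory core.
    """

    k: float = 4.0
    sigma1: float = 5.0  # arcmin, positive (center) component
    sigma2: float = 20.0  # arcmin, negative (surround) component
    spacing: float = BAR_SPACING_ARCMIN
    support: int = 25  # taps; +-108 arcmin covers the surround tails

    def __post_init__(self) -> None:
        if not self.sigma1 < self.sigma2:
            raise ValueError("sigma1 must be smaller than sigma2")
        if self.support % 2 == 0 or self.support < 1:
            raise ValueError("support must be a positive odd tap count")


@dataclass(frozen=True)
class ObserverConfig:
    """Full parameterization of one model observer.

    ``noise_sd`` is the SD of the intrinsic noise e; it is fixed for a
    given observer (never adapted per stimulus) and is normally set once
    by :func:`calibrate_noise_sd`.  For the MAX observer the read-out
    window widens as contrast drops, per ``max_sigma_w_by_contrast``.
    """

    variant: str = "template"
    dog: DOGSpec = field(default_factory=DOGSpec)
    sigma_w: float = 40.0  # arcmin
    noise_sd: float = 0.0
    noise_location: str = "late"  # or "early"
    noise_scaling: str = "response_independent"  # or "response_dependent"
    max_sigma_w_by_contrast: tuple = ((1, 160.0), (2, 120.0), (3, 80.0), (4, 40.0))
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.noise_location not in ("late", "early"):
            raise ValueError("noise_location must be 'late' or 'early'")
        if self.noise_scaling not in ("response_independent",
                                      "response_dependent"):
            raise ValueError("bad noise_scaling")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def for_variant(cls, variant, **kwargs) -> "ObserverConfig":
        """Config with the variant's published defaults.

        ``variant`` may be a name or a number 1-5; variant #5 overrides
        the front end to (k=6, sigma1=2.5, sigma2=10) with sigma_w=10.
        """
        if isinstance(variant, int):
            variant = VARIANT_NUMBERS[variant]
        if variant == "hybrid_gc_both":
            kwargs.setdefault("dog", DOGSpec(k=6.0, sigma1=2.5, sigma2=10.0))
            kwargs.setdefault("sigma_w", 10.0)
        return cls(variant=variant, **kwargs)

    def max_sigma_w(self, contrast_level: int) -> float:
        return dict(self.max_sigma_w_by_contrast)[contrast_level]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["dog"] = asdict(self.dog)
        d["max_sigma_w_by_contrast"] = [list(p) for p in
                                        self.max_sigma_w_by_contrast]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ObserverConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["dog"] = DOGSpec(**d["dog"])
        d["max_sigma_w_by_contrast"] = tuple(
            (int(k), float(v)) for k, v in d["max_sigma_w_by_contrast"])
        return cls(**d)


@dataclass
class BranchOutputs:
    """Intermediate branch responses for one stimulus (noiseless)."""

    b_lin: np.ndarray
    b_nlin: np.ndarray
    b_lin_gc: np.ndarray
    b_nlin_gc: np.ndarray


@dataclass
class ResponseRecord:
    """Outcome of one trial: decision variables and the binary choice."""

    trial: Trial
    r0: float
    r1: float
    chose_target: bool
    correct: bool


def dog_filter(spec: DOGSpec = DOGSpec()) -> np.ndarray:
    """Unit-energy difference-of-Gaussians taps, symmetric about center."""
    half = spec.support // 2
    x = spec.spacing * np.arange(-half, half + 1)
    f = (spec.k * stats.norm.pdf(x, 0.0, spec.sigma1)
         - stats.norm.pdf(x, 0.0, spec.sigma2))
    return f / np.sqrt(np.sum(f ** 2))


def _conv_matrix(f: np.ndarray, n: int) -> np.ndarray:
    """Matrix C with C @ s = same-length zero-padded convolution s * f."""
    half = len(f) // 2
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            k = half + i - j
            if 0 <= k < len(f):
                C[i, j] = f[k]
    return C


def frontend(s: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Convolve stimulus rows with the front-end filter.

    Zero padding at the boundaries: stimuli are luminance deviations from
    background, so padding with background is padding with zeros.
    """
    s = np.asarray(s, dtype=float)
    C = _conv_matrix(np.asarray(f, dtype=float), s.shape[-1])
    return s @ C.T


def gain_control_linear(b_lin: np.ndarray) -> np.ndarray:
    """Divisive normalization of the linear branch.

    The pooled (signed) sum is squared inside the denominator:
    b / (10 + (sum b)^2).  Operates row-wise on batches.
    """
    b_lin = np.asarray(b_lin, dtype=float)
    pooled = b_lin.sum(axis=-1, keepdims=True)
    return b_lin / (_GC_LIN_SEMISAT + pooled ** 2)


def gain_control_nonlinear(b_nlin: np.ndarray) -> np.ndarray:
    """Divisive normalization of the (squared, hence >= 0) nonlinear branch:
    b / (0.4 + sum b).  The normalized sum saturates below 1."""
    b_nlin = np.asarray(b_nlin, dtype=float)
    if np.any(b_nlin < 0):
        raise ValueError("nonlinear-branch input must be non-negative")
    pooled = b_nlin.sum(axis=-1, keepdims=True)
    return b_nlin / (_GC_NLIN_SEMISAT + pooled)


def branch_outputs(s: np.ndarray, config: ObserverConfig) -> BranchOutputs:
    """Noiseless branch responses (diagnostic helper)."""
    b_lin = frontend(s, dog_filter(config.dog))
    b_nlin = b_lin ** 2
    return BranchOutputs(b_lin=b_lin, b_nlin=b_nlin,
                         b_lin_gc=gain_control_linear(b_lin),
                         b_nlin_gc=gain_control_nonlinear(b_nlin))


def readout_weights(config: ObserverConfig, n_bars: int,
                    center_index: int,
                    contrast_level: Optional[int] = None) -> np.ndarray:
    """Gaussian attentional window over bar positions (not renormalized)."""
    if config.variant == "max":
        if contrast_level is None:
            raise ValueError("MAX observer needs the trial's contrast level")
        sigma_w = config.max_sigma_w(contrast_level)
    else:
        sigma_w = config.sigma_w
    x = BAR_SPACING_ARCMIN * (np.arange(n_bars) - center_index)
    return np.exp(-0.5 * (x / sigma_w) ** 2)


def decision_variables(S: np.ndarray, config: ObserverConfig,
                       rng: np.random.Generator,
                       contrast_level: Optional[int] = None,
                       center_index: int = 6) -> np.ndarray:
    """Decision variable r for each stimulus row of ``S``.

    Intrinsic noise is drawn fresh per row; its placement follows the
    config (late additive by default; early = added to the front-end
    output before squaring; response-dependent = |b_i| e_i added to the
    front-end output).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m, n = S.shape
    b = frontend(S, dog_filter(config.dog))
    w = readout_weights(config, n, center_index, contrast_level)
    e = rng.normal(0.0, 1.0, size=(m, n)) * config.noise_sd

    if config.variant == "max":
        return np.max(w * b + e, axis=-1)

    late = None
    if config.noise_scaling == "response_dependent":
        b = b + np.abs(b) * e
    elif config.noise_location == "early":
        b = b + e
    else:
        late = e

    if config.variant == "template":
        y = b
    elif config.variant == "energy":
        y = b ** 2
    elif config.variant == "gc_energy":
        y = gain_control_nonlinear(b ** 2)
    elif config.variant == "hybrid_gc_nlin":
        y = b + gain_control_nonlinear(b ** 2)
    elif config.variant == "hybrid_gc_both":
        y = gain_control_linear(b) + gain_control_nonlinear(b ** 2)
    else:  # pragma: no cover - guarded in ObserverConfig
        raise ValueError(f"unknown variant {config.variant!r}")
    if late is not None:
        y = y + late
    return y @ w


def decision_variable(s: np.ndarray, config: ObserverConfig,
                      rng: np.random.Generator,
                      contrast_level: Optional[int] = None,
                      center_index: int = 6) -> float:
    """Scalar decision variable for a single stimulus."""
    return float(decision_variables(s, config, rng, contrast_level,
                                    center_index)[0])


def respond_batch(batch: StimulusBatch, config: ObserverConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Boolean correct/incorrect for every trial of a batch.

    The two stimuli of a trial receive independent intrinsic-noise draws;
    the difference rule with the <=0 tie convention maps r1 - r0 to the
    binary choice.
    """
    c = batch.condition
    r0 = decision_variables(batch.s0, config, rng, c.contrast_level,
                            c.center_index)
    r1 = decision_variables(batch.s1, config, rng, c.contrast_level,
                            c.center_index)
    return (r1 - r0) > 0


def respond(trial: Trial, config: ObserverConfig,
            rng: np.random.Generator) -> ResponseRecord:
    """Run one trial through the observer."""
    c = trial.condition
    r0 = decision_variable(trial.s0, config, rng, c.contrast_level,
                           c.center_index)
    r1 = decision_variable(trial.s1, config, rng, c.contrast_level,
                           c.center_index)
    chose_target = (r1 - r0) > 0
    return ResponseRecord(trial=trial, r0=r0, r1=r1,
                          chose_target=chose_target, correct=chose_target)


def ideal_respond_batch(batch: StimulusBatch) -> np.ndarray:
    """Ideal (noiseless template-matching) observer on a batch.

    The ideal template is t[1] - t[0], nonzero only at the center bar, so
    the rule reduces to the sign of (t1c - t0c) * (s1_center - s0_center).
    Undefined for the mixed-polarity task.
    """
    c = batch.condition
    if c.task == "mixed":
        raise ValueError("the ideal observer is undefined for the "
                         "mixed-polarity task")
    dt = batch.t1_center - batch.t0_center
    ds = batch.s1[:, c.center_index] - batch.s0[:, c.center_index]
    return dt * ds > 0


def ideal_respond(trial: Trial) -> ResponseRecord:
    c = trial.condition
    if c.task == "mixed":
        raise ValueError("the ideal observer is undefined for the "
                         "mixed-polarity task")
    template = trial.t1 - trial.t0
    r0 = float(template @ trial.s0)
    r1 = float(template @ trial.s1)
    chose_target = (r1 - r0) > 0
    return ResponseRecord(trial=trial, r0=r0, r1=r1,
                          chose_target=chose_target, correct=chose_target)


# ---------------------------------------------------------------------------
# calibration


def _dprime_from_pc(pc: float, m: int) -> float:
    pc = min(max(pc, 1.0 / (2 * m)), 1.0 - 1.0 / (2 * m))
    return math.sqrt(2.0) * stats.norm.ppf(pc)


def _mean_dprime(config: ObserverConfig, grid: Sequence[ConditionSpec],
                 n_trials: int, seed_seq: np.random.SeedSequence) -> float:
    total = 0.0
    for cond, child in zip(grid, seed_seq.spawn(len(grid))):
        rng = np.random.default_rng(child)
        batch = sample_stimulus_batch(cond, n_trials, rng)
        pc = float(np.mean(respond_batch(batch, config, rng)))
        total += _dprime_from_pc(pc, n_trials)
    return total / len(grid)


def calibrate_noise_sd(config: ObserverConfig,
                       grid: Optional[Sequence[ConditionSpec]] = None,
                       rng: Optional[np.random.Generator] = None,
                       n_trials_per_condition: int = 1500,
                       target: float = 1.0,
                       tol: float = 0.05,
                       max_iter: int = 40,
                       on_low_ceiling: str = "cap") -> float:
    """Intrinsic-noise SD giving mean d' ~ ``target`` over a condition grid.

    Mean d' decreases monotonically in the noise SD, so the SD is found
    by bisection on log-SD between a quiet bracket (d' above target) and
    a loud one (below).  Stops when mean d' is within ``tol`` of the
    target.

    The effective target is capped at ceiling/sqrt(2), where the ceiling
    is the noiseless observer's mean d': an observer is never calibrated
    into the degenerate near-noiseless corner, but at least to the point
    where internal noise matches the external-noise-driven variability
    (N_int ~ 1, the usual threshold-regime convention).  The cap only
    binds for architectures whose ceiling falls below sqrt(2) x target
    (e.g. the template observer with a 40-arcmin read-out window tops
    out near mean d' = 0.92); a warning is issued when it does.  With
    ``on_low_ceiling="raise"`` a ceiling below ``target - tol`` is a
    hard calibration error instead.
    """
    if grid is None:
        grid = full_grid()
    if len(grid) == 0:
        raise ValueError("calibration grid must not be empty")
    if on_low_ceiling not in ("cap", "raise"):
        raise ValueError("on_low_ceiling must be 'cap' or 'raise'")
    rng = np.random.default_rng() if rng is None else rng
    # one fixed stream per evaluation keeps the objective smooth in SD
    root = np.random.SeedSequence(int(rng.integers(2 ** 31)))

    def mean_d(sd: float) -> float:
        return _mean_dprime(replace(config, noise_sd=sd), grid,
                            n_trials_per_condition, root)

    ceiling = mean_d(0.0)
    if ceiling < target - tol and on_low_ceiling == "raise":
        raise RuntimeError(
            f"calibration failure: noiseless mean d' = {ceiling:.3f} "
            f"is already below the target {target}")
    if ceiling / math.sqrt(2.0) < target:
        import warnings
        target = ceiling / math.sqrt(2.0)
        warnings.warn(
            f"noiseless mean d' = {ceiling:.3f}; capping the calibration "
            f"target at the N_int~1 point (mean d' = {target:.3f})",
            stacklevel=2)

    # scale-free starting point: RMS decision variable of a noiseless run
    lo = 1e-6
    hi = 1.0
    for _ in range(60):
        if mean_d(hi) < target:
            break
        hi *= 4.0
    else:  # pragma: no cover
        raise RuntimeError("calibration failure: could not bracket target")

    sd = hi
    for _ in range(max_iter):
        sd = math.sqrt(lo * hi) if lo > 0 else hi / 2
        d = mean_d(sd)
        if abs(d - target) <= tol:
            return sd
        if d > target:
            lo = max(lo, sd)
        else:
            hi = sd
        if lo > 0 and hi / lo < 1.0001:
            break
    return sd


def calibrated(config: ObserverConfig,
               grid: Optional[Sequence[ConditionSpec]] = None,
               rng: Optional[np.random.Generator] = None,
               **kwargs) -> ObserverConfig:
    """Copy of ``config`` with its intrinsic-noise SD frozen at threshold."""
    sd = calibrate_noise_sd(config, grid, rng, **kwargs)
    return replace(config, noise_sd=sd)


# ---------------------------------------------------------------------------
# session simulation


def simulate_session(blocks: Iterable[Block], config: ObserverConfig,
                     rng: np.random.Generator) -> list:
    """One ResponseRecord per trial, in block order.

    Double-pass repeats reuse the stored stimuli; intrinsic noise is
    drawn fresh for every presentation.
    """
    records = []
    for block in blocks:
        for trial in block.trials:
            records.append(respond(trial, config, rng))
    return records


def write_response_log(records: Sequence, blocks: Iterable[Block],
                       path) -> None:
    """CSV response log aligned with a block list (one row per trial)."""
    import pandas as pd
    rows = []
    it = iter(records)
    for block_id, block in enumerate(blocks):
        for idx in range(len(block.trials)):
            rec = next(it)
            rows.append({"block_id": block_id, "trial_index": idx,
                         "response": int(rec.chose_target),
                         "correct": int(rec.correct)})
    pd.DataFrame(rows).to_csv(path, index=False)


def simulate_condition(condition: ConditionSpec, n_trials: int,
                       config: ObserverConfig, rng: np.random.Generator
                       ) -> tuple:
    """Fast path: ``(batch, correct)`` for many fresh trials at one condition."""
    batch = sample_stimulus_batch(condition, n_trials, rng)
    return batch, respond_batch(batch, config, rng)


def simulate_double_pass_pairs(condition: ConditionSpec, n_pairs: int,
                               config: ObserverConfig,
                               rng: np.random.Generator) -> tuple:
    """Vectorized double-pass run: each stimulus pair presented twice.

    Returns ``(correct_pass1, correct_pass2)`` boolean arrays; intrinsic
    noise is independent between passes while the stimuli are identical.
    """
    batch = sample_stimulus_batch(condition, n_pairs, rng)
    c1 = respond_batch(batch, config, rng)
    c2 = respond_batch(batch, config, rng)
    return c1, c2
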