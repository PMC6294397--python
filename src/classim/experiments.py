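"""In-silico replication pipelines.

``run_grid`` drives a model observer over the full 4x4 contrast x SNR
design of one task: it simulates trials, estimates classification-image
descriptors and their drives, double-pass internal noise, d', efficiency,
sharpness and the linearity index per condition, then assembles metric
surfaces with their contrast/SNR dependence and separability estimates.

``dipper`` measures threshold-versus-pedestal (TvC) curves for the
two-branch model on noiseless bar stimuli: target and non-target differ
only by an increment delta_rho on top of a pedestal rho0; the 75%-correct
increment threshold is extracted per simulation and averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from . import descriptors as dsc
from . import metrics as mtr
from .doublepass import (DoublePassSummary, InternalNoiseEstimate,
                         estimate_internal_noise, summarize_pair_arrays)
from .observers import (ObserverConfig, decision_variables, respond_batch,
                        simulate_double_pass_pairs)
from .stimuli import (Block, ConditionSpec, full_grid, sample_stimulus_batch)

__all__ = [
    "CellResult",
    "GridResult",
    "DipperResult",
    "run_grid",
    "first_trial_filter",
    "dipper",
    "dipper_curves",
    "branch_configs",
]


@dataclass
class CellResult:
    """Everything estimated at one contrast x SNR condition."""

    condition: ConditionSpec
    pc: float
    dprime: float
    efficiency: float
    descriptors: dsc.DescriptorSet
    descriptors_power: dsc.DescriptorSet
    sharpness: float
    nonlinearity: mtr.NonlinearityIndex
    doublepass: Optional[DoublePassSummary] = None
    internal_noise: Optional[InternalNoiseEstimate] = None


@dataclass
class GridResult:
    cells: Dict[Tuple[int, int], CellResult]  # keyed (snr_level, contrast_level)
    surfaces: Dict[str, mtr.MetricSurface]
    dependence: Dict[str, Dict[str, float]]
    separability: Dict[str, Dict[str, float]]

    def save_json(self, path) -> None:
        """Per-condition scalar summaries plus the surface statistics."""
        import json
        cells = {}
        for (s, c), cell in sorted(self.cells.items()):
            entry = {"pc": cell.pc, "dprime": cell.dprime,
                     "efficiency": cell.efficiency,
                     "sharpness": cell.sharpness,
                     "lambda1": cell.descriptors.lambda1,
                     "lambda2": cell.descriptors.lambda2,
                     "linearity": cell.nonlinearity.linearity}
            if cell.doublepass is not None:
                entry.update(pa=cell.doublepass.pa,
                             n_pairs=cell.doublepass.n_pairs)
            if cell.internal_noise is not None:
                entry.update(N_int=cell.internal_noise.N_int,
                             dprime_in=cell.internal_noise.dprime_in,
                             plausible=cell.internal_noise.plausible)
            cells[f"snr{s}_contrast{c}"] = entry
        with open(path, "w") as fh:
            json.dump({"cells": cells, "dependence": self.dependence,
                       "separability": self.separability}, fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (s, c), cell in sorted(self.cells.items()):
            row = {"snr_level": s, "contrast_level": c, "pc": cell.pc,
                   "dprime": cell.dprime, "efficiency": cell.efficiency,
                   "sharpness": cell.sharpness,
                   "lambda1": cell.descriptors.lambda1,
                   "lambda2": cell.descriptors.lambda2,
                   "linearity": cell.nonlinearity.linearity}
            if cell.internal_noise is not None:
                row["N_int"] = cell.internal_noise.N_int
                row["dprime_in"] = cell.internal_noise.dprime_in
            rows.append(row)
        return pd.DataFrame(rows)


def _surface_summaries(surfaces: Dict[str, mtr.MetricSurface]) -> tuple:
    dep: Dict[str, Dict[str, float]] = {}
    sep: Dict[str, Dict[str, float]] = {}
    for name, surf in surfaces.items():
        dep[name] = {}
        for axis in ("contrast", "snr"):
            try:
                dep[name][axis] = mtr.dependence(surf, axis)
            except ValueError:
                dep[name][axis] = math.nan
        entry: Dict[str, float] = {}
        try:
            entry["svd_index"] = mtr.svd_index(surf)
            pred = mtr.separability_prediction(surf)
            entry["marginal_rms_error"] = float(
                np.sqrt(np.mean((surf.values - pred) ** 2)))
        except ValueError:
            entry["svd_index"] = math.nan
            entry["marginal_rms_error"] = math.nan
        sep[name] = entry
    return dep, sep


def run_grid(config: ObserverConfig,
             n_trials_per_condition: int = 6000,
             n_doublepass_pairs: int = 500,
             rng: Optional[np.random.Generator] = None,
             task: str = "bright",
             ideal: bool = False) -> GridResult:
    """Full 4x4 pipeline for one observer on one task.

    ``n_doublepass_pairs`` repeated stimulus pairs per condition feed the
    internal-noise estimate; set it to 0 to skip that stage.  With
    ``ideal=True`` the noiseless ideal observer replaces ``config`` for
    the response stage (descriptor drives are still computed).
    """
    rng = np.random.default_rng() if rng is None else rng
    seeds = np.random.SeedSequence(int(rng.integers(2 ** 31))).spawn(16)
    cells: Dict[Tuple[int, int], CellResult] = {}
    for cond, seed in zip(full_grid(task), seeds):
        crng = np.random.default_rng(seed)
        batch = sample_stimulus_batch(cond, n_trials_per_condition, crng)
        if ideal:
            from .observers import ideal_respond_batch
            correct = ideal_respond_batch(batch)
        else:
            correct = respond_batch(batch, config, crng)
        pc = float(np.mean(correct))
        d = mtr.dprime_from_pc(pc, n_trials_per_condition)
        eff = mtr.efficiency(d, cond.snr)
        cn = dsc.classify_noise(batch.n0, batch.n1, correct, cond.sigma_N)
        ds = dsc.descriptor_set(cn, "space")
        dsp = dsc.descriptor_set(cn, "fourier_power")
        sharp = mtr.sharpness(ds.h)
        nli = mtr.nonlinearity_index(ds.lambda1_tp, ds.lambda1_ta,
                                     ds.lambda1, ds.lambda2)
        dp = est = None
        if n_doublepass_pairs > 0 and not ideal:
            c1, c2 = simulate_double_pass_pairs(cond, n_doublepass_pairs,
                                                config, crng)
            dp = summarize_pair_arrays(c1, c2)
            if 0.0 < dp.pc < 1.0:
                est = estimate_internal_noise(dp)
        cells[(cond.snr_level, cond.contrast_level)] = CellResult(
            condition=cond, pc=pc, dprime=d, efficiency=eff,
            descriptors=ds, descriptors_power=dsp, sharpness=sharp,
            nonlinearity=nli, doublepass=dp, internal_noise=est)

    def surf(name, getter):
        vals = np.full((4, 4), np.nan)
        for (s, c), cell in cells.items():
            vals[s - 1, c - 1] = getter(cell)
        if np.any(~np.isfinite(vals)):
            return None
        return mtr.MetricSurface(vals, name)

    candidates = {
        "dprime": lambda cell: cell.dprime,
        "efficiency": lambda cell: cell.efficiency,
        "sharpness": lambda cell: cell.sharpness,
        "linearity": lambda cell: cell.nonlinearity.linearity,
        "lambda1": lambda cell: cell.descriptors.lambda1,
        "lambda2": lambda cell: cell.descriptors.lambda2,
        "internal_noise": lambda cell: (math.nan if cell.internal_noise is None
                                        else cell.internal_noise.N_int),
    }
    surfaces = {}
    for name, getter in candidates.items():
        s = surf(name, getter)
        if s is not None:
            surfaces[name] = s
    dep, sep = _surface_summaries(surfaces)
    return GridResult(cells=cells, surfaces=surfaces, dependence=dep,
                      separability=sep)


def first_trial_filter(blocks: Iterable[Block]) -> list:
    """Only the first trial of every block (the pre-feedback subset).

    At 50-trial blocks this retains 2% of the data mass; useful to test
    whether within-block learning shapes the descriptors.
    """
    return [b.trials[0] for b in blocks if len(b.trials) > 0]


# ---------------------------------------------------------------------------
# dipper (threshold versus pedestal)


@dataclass
class DipperResult:
    pedestals: np.ndarray  # first entry is 0 (detection)
    thresholds: np.ndarray  # mean 75%-correct increment per pedestal
    threshold_sd: np.ndarray  # across-simulation SD
    branch: str

    @property
    def detection_threshold(self) -> float:
        return float(self.thresholds[0])


_BRANCH_VARIANTS = {"hybrid": "hybrid_gc_nlin", "linear": "template",
                    "nonlinear": "gc_energy"}


def _pedestal_pc(config: ObserverConfig, pedestal: float, delta: np.ndarray,
                 n_trials: int, rng: np.random.Generator,
                 n_bars: int = 13, center: int = 6) -> np.ndarray:
    """pc(delta) on noiseless pedestal stimuli, one sweep vectorized."""
    pcs = np.empty(delta.size)
    for i, d in enumerate(delta):
        s0 = np.zeros((n_trials, n_bars))
        s0[:, center] = pedestal
        s1 = np.zeros((n_trials, n_bars))
        s1[:, center] = pedestal + d
        r0 = decision_variables(s0, config, rng, contrast_level=4,
                                center_index=center)
        r1 = decision_variables(s1, config, rng, contrast_level=4,
                                center_index=center)
        pcs[i] = np.mean((r1 - r0) > 0)
    return pcs


def _threshold_once(config: ObserverConfig, pedestal: float, guess: float,
                    n_trials: int, n_sweep: int,
                    rng: np.random.Generator,
                    criterion: float = 0.75,
                    max_expansions: int = 3) -> float:
    """One simulation's 75% increment threshold at one pedestal.

    Geometric delta sweep around ``guess``, widened up to
    ``max_expansions`` times if the psychometric range does not bracket
    the criterion; linear interpolation on pc versus log delta.
    """
    lo, hi = guess / 6.0, guess * 6.0
    for expansion in range(max_expansions + 1):
        n = n_sweep
        if pedestal > 0:
            # keep absolute steps below 5% of the pedestal intensity
            ratio_cap = 1.0 + 0.05 * pedestal / hi
            if ratio_cap > 1.0:
                needed = 1 + math.ceil(math.log(hi / lo) / math.log(ratio_cap))
                n = int(min(max(n, needed), 200))
        delta = np.geomspace(lo, hi, n)
        pcs = _pedestal_pc(config, pedestal, delta, n_trials, rng)
        above = np.nonzero(pcs >= criterion)[0]
        if above.size == 0:
            hi *= 8.0
            continue
        i = above[0]
        if i == 0:
            lo /= 8.0
            continue
        x0, x1 = math.log(delta[i - 1]), math.log(delta[i])
        y0, y1 = pcs[i - 1], pcs[i]
        return math.exp(x0 + (criterion - y0) * (x1 - x0) / (y1 - y0))
    raise RuntimeError(
        f"could not bracket the {criterion:.0%} threshold at pedestal "
        f"{pedestal} after {max_expansions} sweep expansions")


def dipper(config: ObserverConfig,
           rng: Optional[np.random.Generator] = None,
           branch: Optional[str] = None,
           n_pedestals: int = 50,
           n_sims: int = 100,
           n_trials: int = 1000,
           n_sweep: int = 20,
           pedestal_decades: float = 2.0) -> DipperResult:
    """Threshold-versus-pedestal (TvC) curve for one observer.

    ``config`` is a calibrated observer; by convention the reference
    model is the hybrid (variant #4), and passing ``branch`` simply
    labels the result.  Pedestals span ``pedestal_decades`` log units
    anchored half a decade below the detection (pedestal-0) threshold,
    plus the detection point itself.
    """
    if config.noise_sd <= 0:
        raise ValueError("dipper needs a calibrated (noisy) observer config")
    cfg = config
    rng = np.random.default_rng() if rng is None else rng
    seeds = np.random.SeedSequence(int(rng.integers(2 ** 31)))

    def thresholds_at(pedestal: float, guess: float) -> np.ndarray:
        # a saturating branch can make 75% unreachable at large
        # pedestals; such cells are recorded as NaN, not errors
        out = np.full(n_sims, np.nan)
        for k, seed in enumerate(seeds.spawn(n_sims)):
            try:
                out[k] = _threshold_once(cfg, pedestal, guess, n_trials,
                                         n_sweep, np.random.default_rng(seed))
            except RuntimeError:
                pass
        return out

    # detection threshold anchors the pedestal axis
    guess = 1.0
    det = thresholds_at(0.0, guess)
    if np.all(np.isnan(det)):
        raise RuntimeError("could not measure the detection threshold; "
                           "is the observer calibrated sensibly?")
    thr0 = float(np.nanmean(det))
    peds = np.geomspace(thr0 * 10 ** -0.5,
                        thr0 * 10 ** (pedestal_decades - 0.5),
                        n_pedestals)
    pedestals = [0.0]
    means = [thr0]
    sds = [float(np.nanstd(det))]
    guess = thr0
    for p in peds:
        t = thresholds_at(float(p), guess)
        pedestals.append(float(p))
        with np.errstate(all="ignore"):
            means.append(float(np.nanmean(t)) if np.any(np.isfinite(t))
                         else math.nan)
            sds.append(float(np.nanstd(t)) if np.any(np.isfinite(t))
                       else math.nan)
        if math.isfinite(means[-1]):
            guess = means[-1]
    return DipperResult(pedestals=np.asarray(pedestals),
                        thresholds=np.asarray(means),
                        threshold_sd=np.asarray(sds),
                        branch=branch or config.variant)


def branch_configs(config: ObserverConfig,
                   rng: Optional[np.random.Generator] = None,
                   **calib_kwargs) -> Dict[str, ObserverConfig]:
    """The hybrid and its two isolated branches, each calibrated.

    The linear branch alone is the template variant; the nonlinear
    branch alone is the gain-controlled energy variant.  Front-end and
    gain-control parameters are shared with ``config``; each branch is
    treated as an observer in its own right, so its intrinsic-noise SD
    is recalibrated to threshold performance (the hybrid's noise level
    would leave the saturating nonlinear branch unable to reach 75%
    correct at any increment).
    """
    rng = np.random.default_rng() if rng is None else rng
    from .observers import calibrate_noise_sd
    out = {}
    for label, variant in _BRANCH_VARIANTS.items():
        cfg = replace(config, variant=variant)
        if label != "hybrid" or config.noise_sd <= 0:
            cfg = replace(cfg, noise_sd=0.0)
            cfg = replace(cfg, noise_sd=calibrate_noise_sd(cfg, rng=rng,
                                                           **calib_kwargs))
        out[label] = cfg
    return out


def dipper_curves(config: ObserverConfig,
                  branches: Iterable[str] = ("hybrid", "linear", "nonlinear"),
                  rng: Optional[np.random.Generator] = None,
                  **kwargs) -> Dict[str, DipperResult]:
    """TvC curves for the hybrid model and its isolated branches."""
    rng = np.random.default_rng() if rng is None else rng
    cfgs = branch_configs(config, rng)
    return {b: dipper(cfgs[b], rng, branch=b, **kwargs) for b in branches}
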