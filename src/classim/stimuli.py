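"""Noisy-bar stimuli and the 2AFC trial protocol.

A stimulus is a row of 13 adjacent vertical bars whose luminances deviate
from a uniform 30 cd/m^2 background.  All stimulus values in this package
are luminance deviations in cd/m^2 (the background is 0), so the noise SD
is sigma_N = c x 0.3 cd/m^2 with contrast multiplier c in {1, 2, 4, 8},
and the target offset equals ``snr_level * sigma_N``.  Keeping physical
units matters downstream: the divisive gain-control constants of the
model observers (10 and 0.4) sit inside the operating range of pooled
filter responses only on this scale.

Each 2AFC trial presents two stimuli, a target and a non-target, each the
sum of a fresh Gaussian noise vector ``n`` and a deterministic signal
vector ``t`` that is zero everywhere except the central bar:

    s[q] = n[q] + t[q],   q = 1 (target) or 0 (non-target)

Four task variants differ only in the central offsets (rho[1], rho[0]):
bright-bar detection (rho[1] > 0, rho[0] = 0), dark-bar detection
(rho[1] < 0), mixed-polarity detection (sign of rho[1] random per trial)
and polarity discrimination (rho[0] = -rho[1]).

Blocks hold 50 trials; double-pass blocks repeat the stimuli of trials
1-25 in trials 26-50 in permuted order, which is the raw material for
internal-noise estimation.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "CONTRAST_MULTIPLIERS",
    "N_BARS",
    "CENTER_INDEX",
    "UNIT_CONTRAST_CD",
    "BACKGROUND_CD",
    "BAR_SPACING_ARCMIN",
    "BLOCK_LENGTH",
    "ConditionSpec",
    "Trial",
    "Block",
    "StimulusBatch",
    "noise_profile",
    "target_profile",
    "target_pair",
    "make_trial",
    "make_block",
    "make_double_pass_block",
    "make_session",
    "sample_stimulus_batch",
    "full_grid",
    "trials_to_frame",
    "write_trial_log",
    "read_trial_log",
    "write_session_config",
    "read_session_config",
]

TASKS = ("bright", "dark", "mixed", "polarity")

#: contrast level (1-4) -> noise-SD multiplier c (sigma_N = c x 0.3 cd/m^2)
CONTRAST_MULTIPLIERS = {1: 1.0, 2: 2.0, 3: 4.0, 4: 8.0}

N_BARS = 13
CENTER_INDEX = 6  # 0-based index of the central (7th) bar
UNIT_CONTRAST_CD = 0.3  # cd/m^2 per contrast unit
BACKGROUND_CD = 30.0
BAR_SPACING_ARCMIN = 9.0  # bar width ~0.15 deg
BLOCK_LENGTH = 50


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the task x contrast x SNR design.

    Parameters
    ----------
    task : {"bright", "dark", "mixed", "polarity"}
    contrast_level : int in 1..4, mapping to noise-SD multiplier c in
        {1, 2, 4, 8} (log-spaced contrast).
    snr_level : int in 1..4; the target offset magnitude is
        ``snr_level * sigma_N`` so the nominal stimulus SNR equals the level.
    protocol : bookkeeping label only ("peripheral" spatial 2AFC or
        "foveal" temporal 2IFC); the analysis treats both identically.
    """

    task: str = "bright"
    contrast_level: int = 1
    snr_level: int = 1
    n_bars: int = N_BARS
    center_index: int = CENTER_INDEX
    protocol: str = "peripheral"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.contrast_level not in CONTRAST_MULTIPLIERS:
            raise ValueError("contrast_level must be an integer in 1..4")
        if self.snr_level not in (1, 2, 3, 4):
            raise ValueError("snr_level must be an integer in 1..4")
        if self.n_bars < 1 or not 0 <= self.center_index < self.n_bars:
            raise ValueError("center_index must index into the bar array")

    @property
    def contrast_multiplier(self) -> float:
        return CONTRAST_MULTIPLIERS[self.contrast_level]

    @property
    def sigma_N(self) -> float:
        """Noise SD in cd/m^2 (c x 0.3)."""
        return self.contrast_multiplier * UNIT_CONTRAST_CD

    @property
    def rho_magnitude(self) -> float:
        """|rho[1]|, the target-offset magnitude in cd/m^2."""
        return self.snr_level * self.sigma_N

    @property
    def snr(self) -> float:
        """rho[1]/sigma_N, numerically equal to snr_level."""
        return float(self.snr_level)


@dataclass
class Trial:
    """One 2AFC presentation: two stimuli, each noise + central signal."""

    n0: np.ndarray
    n1: np.ndarray
    t0: np.ndarray
    t1: np.ndarray
    condition: ConditionSpec
    presented_side: str = "AB"  # which stimulus is shown first/left; bookkeeping
    pass_mate: Optional[int] = None  # within-block index of the double-pass partner

    @property
    def s0(self) -> np.ndarray:
        return self.n0 + self.t0

    @property
    def s1(self) -> np.ndarray:
        return self.n1 + self.t1


@dataclass
class Block:
    """An ordered run of trials sharing one condition."""

    trials: list
    condition: ConditionSpec
    seed: Optional[int] = None
    double_pass: bool = False

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class StimulusBatch:
    """Vectorized trial container used by the simulation engine.

    Signal vectors are zero off-center, so only the central offsets are
    stored (``t0_center``, ``t1_center``; shape ``(m,)``).
    """

    n0: np.ndarray  # (m, n_bars)
    n1: np.ndarray
    t0_center: np.ndarray  # (m,)
    t1_center: np.ndarray
    condition: ConditionSpec

    @property
    def m(self) -> int:
        return self.n0.shape[0]

    def _with_signal(self, n: np.ndarray, t_center: np.ndarray) -> np.ndarray:
        s = n.copy()
        s[:, self.condition.center_index] += t_center
        return s

    @property
    def s0(self) -> np.ndarray:
        return self._with_signal(self.n0, self.t0_center)

    @property
    def s1(self) -> np.ndarray:
        return self._with_signal(self.n1, self.t1_center)


def noise_profile(sigma_N: float, n_bars: int = N_BARS,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw one noise vector: iid zero-mean Gaussian, SD ``sigma_N`` per bar."""
    if sigma_N < 0:
        raise ValueError("sigma_N must be non-negative")
    if n_bars < 1:
        raise ValueError("n_bars must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    return rng.normal(0.0, sigma_N, size=n_bars)


def _rho_pair(condition: ConditionSpec, rng: Optional[np.random.Generator]) -> tuple:
    """(rho0, rho1) central offsets for one trial, resolving the task rules."""
    rho = condition.rho_magnitude
    if condition.task == "bright":
        return 0.0, rho
    if condition.task == "dark":
        return 0.0, -rho
    if condition.task == "polarity":
        return -rho, rho
    # mixed polarity: target sign is an iid fair coin per trial
    rng = np.random.default_rng() if rng is None else rng
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return 0.0, sign * rho


def target_pair(condition: ConditionSpec,
                rng: Optional[np.random.Generator] = None) -> tuple:
    """Both signal vectors (t0, t1) of one trial, with one shared sign draw."""
    rho0, rho1 = _rho_pair(condition, rng)
    t0 = np.zeros(condition.n_bars)
    t1 = np.zeros(condition.n_bars)
    t0[condition.center_index] = rho0
    t1[condition.center_index] = rho1
    return t0, t1


def target_profile(condition: ConditionSpec, q: int,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Signal vector t[q] for one interval (q=1 target, q=0 non-target).

    For the mixed task the sign of rho[1] is drawn fresh on every call;
    use :func:`target_pair` when both intervals of a trial are needed.
    """
    if q not in (0, 1):
        raise ValueError("q must be 0 (non-target) or 1 (target)")
    t0, t1 = target_pair(condition, rng)
    return t1 if q == 1 else t0


def make_trial(condition: ConditionSpec,
               rng: Optional[np.random.Generator] = None) -> Trial:
    """One trial: fresh noise in both intervals plus the task's signals."""
    rng = np.random.default_rng() if rng is None else rng
    t0, t1 = target_pair(condition, rng)
    n0 = noise_profile(condition.sigma_N, condition.n_bars, rng)
    n1 = noise_profile(condition.sigma_N, condition.n_bars, rng)
    side = "AB" if rng.random() < 0.5 else "BA"
    return Trial(n0=n0, n1=n1, t0=t0, t1=t1, condition=condition,
                 presented_side=side)


def make_block(condition: ConditionSpec,
               rng: Optional[np.random.Generator] = None,
               n_trials: int = BLOCK_LENGTH) -> Block:
    """A plain (non-double-pass) block of fresh trials."""
    rng = np.random.default_rng() if rng is None else rng
    return Block(trials=[make_trial(condition, rng) for _ in range(n_trials)],
                 condition=condition, double_pass=False)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def make_double_pass_block(condition: ConditionSpec,
                           rng: Optional[np.random.Generator] = None) -> Block:
    """A 50-trial double-pass block.

    Trials 26-50 re-present the stimuli of trials 1-25 in randomly
    permuted order; the permutation is drawn without fixed points so a
    repeat never occupies the same within-half position as its original.
    ``pass_mate`` links each trial to its partner (a bijection between
    halves).
    """
    rng = np.random.default_rng() if rng is None else rng
    half = BLOCK_LENGTH // 2
    first = [make_trial(condition, rng) for _ in range(half)]
    perm = _derangement(half, rng)
    second = []
    for j, src in enumerate(perm):
        proto = first[src]
        side = "AB" if rng.random() < 0.5 else "BA"
        second.append(Trial(n0=proto.n0.copy(), n1=proto.n1.copy(),
                            t0=proto.t0.copy(), t1=proto.t1.copy(),
                            condition=condition, presented_side=side,
                            pass_mate=int(src)))
        first[src].pass_mate = half + j
    return Block(trials=first + second, condition=condition, double_pass=True)


def make_session(conditions: Sequence[ConditionSpec],
                 n_blocks_per_condition: int = 1,
                 rng: Optional[np.random.Generator] = None,
                 double_pass: bool = False) -> list:
    """Blocks covering every supplied condition, in randomized order.

    The condition (contrast, SNR, task) is fixed within each block, as in
    a session where levels are reassigned only at block boundaries.
    """
    if len(conditions) == 0:
        raise ValueError("condition list must not be empty")
    if n_blocks_per_condition < 1:
        raise ValueError("n_blocks_per_condition must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    maker = make_double_pass_block if double_pass else make_block
    schedule = [c for c in conditions for _ in range(n_blocks_per_condition)]
    order = rng.permutation(len(schedule))
    return [maker(schedule[i], rng) for i in order]


def full_grid(task: str = "bright", protocol: str = "peripheral") -> list:
    """All 16 contrast x SNR conditions for one task."""
    return [ConditionSpec(task=task, contrast_level=c, snr_level=s,
                          protocol=protocol)
            for s in (1, 2, 3, 4) for c in (1, 2, 3, 4)]


def sample_stimulus_batch(condition: ConditionSpec, n_trials: int,
                          rng: Optional[np.random.Generator] = None
                          ) -> StimulusBatch:
    """Vectorized equivalent of ``n_trials`` calls to :func:`make_trial`.

    This is the fast path used for the large simulations behind
    descriptor estimation; the per-trial objects are retained for the
    protocol-faithful (block-structured) pathway.
    """
    rng = np.random.default_rng() if rng is None else rng
    sigma = condition.sigma_N
    n0 = rng.normal(0.0, sigma, size=(n_trials, condition.n_bars))
    n1 = rng.normal(0.0, sigma, size=(n_trials, condition.n_bars))
    rho = condition.rho_magnitude
    if condition.task == "bright":
        t0 = np.zeros(n_trials)
        t1 = np.full(n_trials, rho)
    elif condition.task == "dark":
        t0 = np.zeros(n_trials)
        t1 = np.full(n_trials, -rho)
    elif condition.task == "polarity":
        t0 = np.full(n_trials, -rho)
        t1 = np.full(n_trials, rho)
    else:  # mixed
        sign = np.where(rng.random(n_trials) < 0.5, 1.0, -1.0)
        t0 = np.zeros(n_trials)
        t1 = sign * rho
    return StimulusBatch(n0=n0, n1=n1, t0_center=t0, t1_center=t1,
                         condition=condition)


# ---------------------------------------------------------------------------
# trial-log serialization


def trials_to_frame(blocks: Iterable[Block]) -> pd.DataFrame:
    """Flatten blocks into the canonical trial-log table."""
    rows = []
    for block_id, block in enumerate(blocks):
        c = block.condition
        for idx, tr in enumerate(block.trials):
            row = {
                "block_id": block_id,
                "trial_index": idx,
                "task": c.task,
                "contrast_level": c.contrast_level,
                "snr_level": c.snr_level,
                "pass_mate": -1 if tr.pass_mate is None else tr.pass_mate,
                "side": tr.presented_side,
            }
            for i in range(c.n_bars):
                row[f"n0_{i + 1}"] = tr.n0[i]
            row["t0_center"] = tr.t0[c.center_index]
            for i in range(c.n_bars):
                row[f"n1_{i + 1}"] = tr.n1[i]
            row["t1_center"] = tr.t1[c.center_index]
            rows.append(row)
    return pd.DataFrame(rows)


def write_trial_log(blocks: Iterable[Block], path) -> None:
    # %.17g guarantees a bit-exact float64 round trip through the CSV
    trials_to_frame(blocks).to_csv(path, index=False, float_format="%.17g")


def read_trial_log(path) -> list:
    """Rebuild blocks from a trial-log CSV (bit-exact round trip)."""
    df = pd.read_csv(path, float_precision="round_trip")
    blocks = []
    for block_id, g in df.groupby("block_id", sort=True):
        g = g.sort_values("trial_index")
        first = g.iloc[0]
        cond = ConditionSpec(task=first["task"],
                             contrast_level=int(first["contrast_level"]),
                             snr_level=int(first["snr_level"]))
        n_cols0 = [f"n0_{i + 1}" for i in range(cond.n_bars)]
        n_cols1 = [f"n1_{i + 1}" for i in range(cond.n_bars)]
        trials = []
        for _, row in g.iterrows():
            t0 = np.zeros(cond.n_bars)
            t1 = np.zeros(cond.n_bars)
            t0[cond.center_index] = row["t0_center"]
            t1[cond.center_index] = row["t1_center"]
            mate = int(row["pass_mate"])
            trials.append(Trial(n0=row[n_cols0].to_numpy(dtype=float),
                                n1=row[n_cols1].to_numpy(dtype=float),
                                t0=t0, t1=t1, condition=cond,
                                presented_side=row["side"],
                                pass_mate=None if mate < 0 else mate))
        has_mates = any(t.pass_mate is not None for t in trials)
        blocks.append(Block(trials=trials, condition=cond,
                            double_pass=has_mates))
    return blocks


def write_session_config(path, tasks, contrast_levels, snr_levels,
                         n_blocks: int, seed: int) -> None:
    with open(path, "w") as fh:
        json.dump({"tasks": list(tasks),
                   "contrast_levels": list(contrast_levels),
                   "snr_levels": list(snr_levels),
                   "n_blocks": n_blocks,
                   "seed": seed}, fh, indent=2)


def read_session_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
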