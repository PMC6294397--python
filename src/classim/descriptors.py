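"""Reverse-correlation descriptors of the perceptual filter.

After each 2AFC trial the two noise samples can be indexed n[q, z] by
interval (q = 1 target, 0 non-target) and outcome (z = 1 correct, 0
incorrect).  From these classified samples:

first order (classification image)
    h[1] = mean(n[1,1]) - mean(n[1,0])   (target-present)
    h[0] = mean(n[0,0]) - mean(n[0,1])   (target-absent)
    h    = h[1] + h[0]

second order
    H = cov(n[1,1]) - cov(n[1,0]) - cov(n[0,1]) + cov(n[0,0])

i.e. the same +/- combination with the mean replaced by the sample
covariance.  A frequency-domain variant replaces every noise sample by
its one-sided Fourier power profile before averaging.

The *drive* lambda_d = log(RMS_d / RMS*_d) compares a descriptor's RMS
amplitude against the RMS expected from a decoupled process (responses
randomly reassigned to trials), for which the expected drive is 0.  With
m trials at proportion correct pc and noise SD sigma_N, writing
k = sqrt(2 / (m pc (1 - pc))):

    RMS*_1 = k sigma_N            (full h; components h[q]: k sigma_N / sqrt 2)
    RMS*_2 = sqrt(2) k sigma_N^2  (H diagonal; off-diagonal smaller by sqrt 2)

These closed forms follow from the sampling variance of a difference of
class means (respectively of class variances/covariances) and are
verified against decoupled Monte-Carlo simulation in the test suite.
lambda_2 is computed over the whole matrix after multiplying the
off-diagonal region by sqrt(2), which puts it on the diagonal reference.

Eigen-decomposing H yields filter-like eigenvectors comparable to h;
their significance is judged against the spread of eigenvalues from
decoupled (response-shuffled) surrogates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Optional, Sequence

import numpy as np

from .stimuli import BAR_SPACING_ARCMIN

__all__ = [
    "ClassifiedNoise",
    "DescriptorSet",
    "EigenDecomposition",
    "classify_noise",
    "classify_records",
    "first_order",
    "first_order_power",
    "second_order",
    "power_profile",
    "frequency_axis",
    "rms",
    "rms_star",
    "drive",
    "descriptor_set",
    "decouple",
    "null_drives",
    "null_second_order",
    "eigendecompose",
]


@dataclass(frozen=True)
class ClassifiedNoise:
    """Noise samples of a session together with the response labels.

    Stores the raw per-trial arrays so that decoupled (shuffled)
    surrogates can be generated; the four classified bins are derived
    views.
    """

    n0: np.ndarray  # (m, n_bars) non-target-interval noise
    n1: np.ndarray  # (m, n_bars) target-interval noise
    correct: np.ndarray  # (m,) bool
    sigma_N: float

    def __post_init__(self) -> None:
        if self.n0.shape != self.n1.shape or self.n0.shape[0] != self.correct.shape[0]:
            raise ValueError("noise arrays and response vector are misaligned")

    @property
    def m(self) -> int:
        return int(self.correct.size)

    @property
    def pc(self) -> float:
        return float(np.mean(self.correct))

    # bins indexed [q, z]: interval q, outcome z
    @property
    def n11(self) -> np.ndarray:
        return self.n1[self.correct]

    @property
    def n10(self) -> np.ndarray:
        return self.n1[~self.correct]

    @property
    def n01(self) -> np.ndarray:
        return self.n0[self.correct]

    @property
    def n00(self) -> np.ndarray:
        return self.n0[~self.correct]

    @property
    def counts(self) -> dict:
        nc = int(np.sum(self.correct))
        return {(1, 1): nc, (0, 1): nc,
                (1, 0): self.m - nc, (0, 0): self.m - nc}


@dataclass
class DescriptorSet:
    """First- and second-order descriptors of one session plus drives."""

    h: np.ndarray
    h1: np.ndarray
    h0: np.ndarray
    H: np.ndarray
    domain: str  # "space" or "fourier_power"
    lambda1: float
    lambda2: float
    lambda1_tp: float  # target-present component drive
    lambda1_ta: float  # target-absent component drive
    m: int
    pc: float
    sigma_N: float

    def to_json(self, path) -> None:
        import json
        payload = {"domain": self.domain, "m": self.m, "pc": self.pc,
                   "sigma_N": self.sigma_N,
                   "lambda1": self.lambda1, "lambda2": self.lambda2,
                   "lambda1_tp": self.lambda1_tp,
                   "lambda1_ta": self.lambda1_ta,
                   "h": self.h.tolist(), "h1": self.h1.tolist(),
                   "h0": self.h0.tolist(), "H": self.H.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DescriptorSet":
        import json
        with open(path) as fh:
            d = json.load(fh)
        for key in ("h", "h1", "h0", "H"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)

    def export_csv(self, h_path, H_path) -> None:
        """Plain CSV export of h (with components) and H for plotting."""
        import pandas as pd
        pd.DataFrame({"h": self.h, "h1": self.h1, "h0": self.h0}).to_csv(
            h_path, index=False)
        pd.DataFrame(self.H).to_csv(H_path, index=False, header=False)


@dataclass
class EigenDecomposition:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    null_sd: float
    threshold_multiplier: float
    significant_pos: int
    significant_neg: int

    @property
    def leading(self) -> np.ndarray:
        """Eigenvector of the largest-magnitude eigenvalue."""
        i = int(np.argmax(np.abs(self.eigenvalues)))
        return self.eigenvectors[:, i]


def classify_noise(n0: np.ndarray, n1: np.ndarray, correct: np.ndarray,
                   sigma_N: float) -> ClassifiedNoise:
    """Bundle per-trial noise with responses (arrays must align by trial)."""
    return ClassifiedNoise(n0=np.asarray(n0, dtype=float),
                           n1=np.asarray(n1, dtype=float),
                           correct=np.asarray(correct, dtype=bool),
                           sigma_N=float(sigma_N))


def classify_records(trials: Sequence, records: Sequence,
                     sigma_N: Optional[float] = None) -> ClassifiedNoise:
    """Build a :class:`ClassifiedNoise` from Trial / ResponseRecord lists."""
    if len(trials) != len(records):
        raise ValueError("trials and records are misaligned")
    n0 = np.stack([t.n0 for t in trials])
    n1 = np.stack([t.n1 for t in trials])
    correct = np.array([r.correct for r in records], dtype=bool)
    if sigma_N is None:
        sigma_N = trials[0].condition.sigma_N
    return classify_noise(n0, n1, correct, sigma_N)


def _check_bins(cn: ClassifiedNoise, min_count: int) -> None:
    for qz, count in cn.counts.items():
        if count < min_count:
            raise ValueError(
                f"bin q={qz[0]}, z={qz[1]} has {count} samples "
                f"(need >= {min_count}); descriptor undefined")


def first_order(cn: ClassifiedNoise) -> tuple:
    """(h, h1, h0) spatial classification images."""
    _check_bins(cn, 1)
    h1 = cn.n11.mean(axis=0) - cn.n10.mean(axis=0)
    h0 = cn.n00.mean(axis=0) - cn.n01.mean(axis=0)
    return h1 + h0, h1, h0


def power_profile(n: np.ndarray) -> np.ndarray:
    """One-sided Fourier power of each row (7 frequencies for 13 bars)."""
    return np.abs(np.fft.rfft(np.atleast_2d(n), axis=-1)) ** 2


def frequency_axis(n_bars: int = 13,
                   spacing_arcmin: float = BAR_SPACING_ARCMIN) -> np.ndarray:
    """One-sided DFT frequencies in cycles/deg for the bar sampling grid."""
    return np.fft.rfftfreq(n_bars, d=spacing_arcmin / 60.0)


def first_order_power(cn: ClassifiedNoise) -> tuple:
    """(h, h1, h0) in the Fourier-power domain.

    The combination rule is unchanged; each noise sample is replaced by
    its power profile first.  Amplitudes may be negative because bins are
    subtracted.
    """
    _check_bins(cn, 1)
    h1 = (power_profile(cn.n11).mean(axis=0)
          - power_profile(cn.n10).mean(axis=0))
    h0 = (power_profile(cn.n00).mean(axis=0)
          - power_profile(cn.n01).mean(axis=0))
    return h1 + h0, h1, h0


def _cov(x: np.ndarray) -> np.ndarray:
    return np.cov(x, rowvar=False, ddof=1)


def second_order(cn: ClassifiedNoise) -> np.ndarray:
    """Signed sum of the four bin covariance matrices (symmetric)."""
    _check_bins(cn, 2)
    return _cov(cn.n11) - _cov(cn.n10) - _cov(cn.n01) + _cov(cn.n00)


def rms(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take the RMS of an empty region")
    return float(np.sqrt(np.mean(values ** 2)))


def rms_star(order: int, m: int, pc: float, sigma_N: float,
             region: str = "full") -> float:
    """Expected descriptor RMS under a decoupled process.

    ``region`` selects the part of the descriptor: for order 1, "full"
    (h) or "component" (h[1] or h[0] alone); for order 2, "diagonal",
    "offdiagonal", or "full" meaning the whole matrix with the
    off-diagonal pre-scaled by sqrt(2) onto the diagonal reference.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if not 0.0 < pc < 1.0:
        raise ValueError("descriptor noise level undefined for pc of 0 or 1")
    k = math.sqrt(2.0 / (m * pc * (1.0 - pc)))
    if order == 1:
        base = k * sigma_N
        if region == "full":
            return base
        if region == "component":
            return base / math.sqrt(2.0)
    elif order == 2:
        base = math.sqrt(2.0) * k * sigma_N ** 2
        if region in ("diagonal", "full"):
            return base
        if region == "offdiagonal":
            return base / math.sqrt(2.0)
    else:
        raise ValueError("order must be 1 or 2")
    raise ValueError(f"unknown region {region!r} for order {order}")


def drive(descriptor_region: np.ndarray, rms_star_value: float) -> float:
    """lambda = log(RMS(region) / RMS*), natural log."""
    if rms_star_value <= 0:
        raise ValueError("rms_star_value must be positive")
    return math.log(rms(descriptor_region) / rms_star_value)


def _lambda2(H: np.ndarray, m: int, pc: float, sigma_N: float) -> float:
    scaled = H * (math.sqrt(2.0) * (1.0 - np.eye(H.shape[0])) + np.eye(H.shape[0]))
    return drive(scaled, rms_star(2, m, pc, sigma_N, "full"))


def descriptor_set(cn: ClassifiedNoise, domain: str = "space") -> DescriptorSet:
    """Full descriptor bundle (h, h1, h0, H) with drives.

    Drives are defined on the spatial descriptors; the Fourier-power
    variant carries the spatial drives alongside its profiles.
    """
    if domain == "space":
        h, h1, h0 = first_order(cn)
    elif domain == "fourier_power":
        h, h1, h0 = first_order_power(cn)
    else:
        raise ValueError("domain must be 'space' or 'fourier_power'")
    H = second_order(cn)
    hs, hs1, hs0 = (h, h1, h0) if domain == "space" else first_order(cn)
    m, pc, s = cn.m, cn.pc, cn.sigma_N
    return DescriptorSet(
        h=h, h1=h1, h0=h0, H=H, domain=domain,
        lambda1=drive(hs, rms_star(1, m, pc, s, "full")),
        lambda2=_lambda2(H, m, pc, s),
        lambda1_tp=drive(hs1, rms_star(1, m, pc, s, "component")),
        lambda1_ta=drive(hs0, rms_star(1, m, pc, s, "component")),
        m=m, pc=pc, sigma_N=s)


def decouple(cn: ClassifiedNoise, rng: np.random.Generator) -> ClassifiedNoise:
    """Surrogate with responses randomly reassigned to trials.

    Marginal statistics of both stimuli and responses are untouched (pc
    is preserved exactly); only their coupling is destroyed.
    """
    if cn.m < 2:
        raise ValueError("decoupling needs at least 2 trials")
    return replace(cn, correct=cn.correct[rng.permutation(cn.m)])


def null_drives(cn: ClassifiedNoise, n_shuffles: int,
                rng: np.random.Generator) -> dict:
    """Drives of decoupled surrogates; the null reference for lambda.

    Returns arrays of length ``n_shuffles`` for each drive, plus the
    measured/expected RMS ratios that validate the RMS* closed forms.
    """
    out = {"lambda1": [], "lambda2": [], "lambda1_tp": [], "lambda1_ta": [],
           "rms_ratio_1": [], "rms_ratio_2_diag": []}
    star1 = rms_star(1, cn.m, cn.pc, cn.sigma_N, "full")
    star2 = rms_star(2, cn.m, cn.pc, cn.sigma_N, "diagonal")
    for _ in range(n_shuffles):
        d = descriptor_set(decouple(cn, rng))
        out["lambda1"].append(d.lambda1)
        out["lambda2"].append(d.lambda2)
        out["lambda1_tp"].append(d.lambda1_tp)
        out["lambda1_ta"].append(d.lambda1_ta)
        out["rms_ratio_1"].append(rms(d.h) / star1)
        out["rms_ratio_2_diag"].append(rms(np.diag(d.H)) / star2)
    return {k: np.asarray(v) for k, v in out.items()}


def null_second_order(cn: ClassifiedNoise, n_shuffles: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Stack of second-order descriptors from decoupled surrogates."""
    return np.stack([second_order(decouple(cn, rng))
                     for _ in range(n_shuffles)])


def eigendecompose(H: np.ndarray,
                   null_H: Optional[np.ndarray] = None,
                   threshold_multiplier: float = 3.0) -> EigenDecomposition:
    """Symmetric eigen-decomposition of H with a decoupled null band.

    The null band is ``threshold_multiplier`` times the SD of the pooled
    eigenvalues of the decoupled surrogates ``null_H`` (e.g. from
    :func:`null_second_order`); eigenvalues outside the band are counted
    as significant (positive / negative separately).
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1] or not np.allclose(H, H.T):
        raise ValueError("H must be a symmetric square matrix")
    evals, evecs = np.linalg.eigh(H)
    null_sd = math.nan
    n_pos = n_neg = 0
    if null_H is not None:
        null_H = np.asarray(null_H, dtype=float)
        if null_H.ndim != 3 or null_H.shape[0] < 1:
            raise ValueError("null_H must be a stack of matrices")
        import warnings
        if null_H.shape[0] < 10:
            warnings.warn("fewer than 10 decoupled surrogates; the null "
                          "band will be poorly estimated", stacklevel=2)
        null_evals = np.linalg.eigvalsh(null_H).ravel()
        null_sd = float(np.std(null_evals))
        band = threshold_multiplier * null_sd
        n_pos = int(np.sum(evals > band))
        n_neg = int(np.sum(evals < -band))
    return EigenDecomposition(eigenvalues=evals, eigenvectors=evecs,
                              null_sd=null_sd,
                              threshold_multiplier=threshold_multiplier,
                              significant_pos=n_pos, significant_neg=n_neg)
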