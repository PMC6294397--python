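"""Scalar tuning metrics and their contrast/SNR structure.

sharpness
    spectral centroid of a spatial profile's one-sided power spectrum
    (unit-sum normalized), in cycles/deg; higher = more bandpass.
nonlinearity / linearity index
    two drive-based markers of departure from the template matcher:
    marker 1 = lambda[1] - lambda[0] (target-present vs target-absent
    first-order drives); marker 2 = (lambda_1 - lambda_2) * sign(lambda_2)
    (second- against first-order structure, gated by the sign of
    lambda_2 so that a system whose second-order drive has null
    expectation scores ~0 on average).  Aggregate nonlinearity =
    marker1 + marker2; the linearity index is its negation.
dependence
    Pearson correlation between a metric's per-condition values and the
    corresponding contrast (or SNR) level indices 1-4.
separability
    two estimators over the 4x4 contrast x SNR surface S: the marginal
    prediction S*_ij = (row_i sum)(col_j sum)/(grand sum), which equals S
    iff S is an outer product, and the SVD index v1^2 / sum(v_i^2) over
    singular values (1 for a separable surface).
performance
    d' = sqrt(2) Phi^-1(pc) for the 2AFC difference rule; efficiency =
    (d'_human / d'_ideal)^2 with ideal d' equal to the stimulus SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .descriptors import frequency_axis
from .stimuli import BAR_SPACING_ARCMIN

__all__ = [
    "MetricSurface",
    "NonlinearityIndex",
    "sharpness",
    "eigen_sharpness",
    "nonlinearity_index",
    "dependence",
    "separability_prediction",
    "svd_index",
    "dprime_from_pc",
    "efficiency",
    "wilcoxon_signed_rank",
    "friedman_trend",
]

LEVELS = np.array([1, 2, 3, 4], dtype=float)


@dataclass
class MetricSurface:
    """A scalar metric on the 4x4 grid; values[i, j] = (snr i+1, contrast j+1)."""

    values: np.ndarray
    metric_name: str = ""
    n_per_cell: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4, 4):
            raise ValueError("a metric surface must be 4x4 (SNR x contrast)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("metric surface has missing cells")


@dataclass(frozen=True)
class NonlinearityIndex:
    marker1: float  # lambda[1] - lambda[0]
    marker2: float  # (lambda2 - lambda1) * sign(lambda2)
    aggregate: float  # marker1 + marker2; > 0 = nonlinear
    linearity: float  # -aggregate


def sharpness(profile: np.ndarray,
              spacing_arcmin: float = BAR_SPACING_ARCMIN) -> float:
    """Spectral centroid (cycles/deg) of a 1D spatial profile.

    Works identically on first-order descriptors and on second-order
    eigenvectors, which is what makes the two comparable.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("sharpness is defined for 1D profiles")
    p = np.abs(np.fft.rfft(profile)) ** 2
    total = p.sum()
    if total == 0:
        raise ValueError("sharpness undefined for an identically zero profile")
    x = frequency_axis(profile.size, spacing_arcmin)
    return float((p / total) @ x)


def eigen_sharpness(eigenvalues: np.ndarray, eigenvectors: np.ndarray,
                    k: int = 3,
                    spacing_arcmin: float = BAR_SPACING_ARCMIN) -> float:
    """Spectral centroid of the pooled power of the top-k eigenvectors.

    Leading eigenvalues of second-order descriptors are often nearly
    degenerate, so individual eigenvectors rotate freely within the top
    subspace from one estimate to the next.  Pooling the
    eigenvalue-weighted power spectra of the top ``k`` (largest
    positive) eigenvectors before taking the centroid is invariant to
    such rotations, making second-order tuning comparable across
    conditions.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    idx = np.argsort(-eigenvalues)[:k]
    if eigenvalues[idx[0]] <= 0:
        raise ValueError("no positive eigenvalues to pool")
    pooled = np.zeros(eigenvectors.shape[0] // 2 + 1)
    for lam, v in zip(eigenvalues[idx], eigenvectors[:, idx].T):
        if lam <= 0:
            continue
        pooled = pooled + lam * np.abs(np.fft.rfft(v)) ** 2
    x = frequency_axis(eigenvectors.shape[0], spacing_arcmin)
    return float((pooled / pooled.sum()) @ x)


def nonlinearity_index(l1_tp: float, l1_ta: float, l1: float, l2: float
                       ) -> NonlinearityIndex:
    """Combine the two nonlinearity markers (positive = more nonlinear).

    ``sign(0) = 0`` so a system whose second-order drive has null
    expectation scores 0 on marker 2, keeping the template matcher at an
    aggregate of ~0 regardless of its internal-noise level.
    """
    for v in (l1_tp, l1_ta, l1, l2):
        if not math.isfinite(v):
            raise ValueError("drives must be finite")
    marker1 = l1_tp - l1_ta
    marker2 = (l1 - l2) * float(np.sign(l2))
    aggregate = marker1 + marker2
    return NonlinearityIndex(marker1=marker1, marker2=marker2,
                             aggregate=aggregate, linearity=-aggregate)


def dependence(surface, axis: str) -> float:
    """Pearson correlation of a metric with contrast or SNR level.

    ``surface`` may be a :class:`MetricSurface` (all 16 cells enter) or a
    plain sequence of values paired with levels 1..len(values) (the
    stratified variant).  Correlating against level index is equivalent
    to correlating against log2 of the contrast multiplier {1,2,4,8}
    (Pearson r is affine-invariant).
    """
    if isinstance(surface, MetricSurface):
        vals = surface.values
        if axis == "contrast":
            levels = np.broadcast_to(LEVELS, (4, 4)).ravel()
        elif axis == "snr":
            levels = np.broadcast_to(LEVELS[:, None], (4, 4)).ravel()
        else:
            raise ValueError("axis must be 'contrast' or 'snr'")
        vals = vals.ravel()
    else:
        vals = np.asarray(surface, dtype=float)
        levels = np.arange(1, vals.size + 1, dtype=float)
    if vals.size < 3:
        raise ValueError("dependence needs at least 3 paired values")
    if np.ptp(vals) == 0:
        raise ValueError("dependence undefined for a constant metric")
    return float(stats.pearsonr(vals, levels).statistic)


def separability_prediction(S) -> np.ndarray:
    """Normalized outer product of marginals; equals S iff S is separable."""
    values = S.values if isinstance(S, MetricSurface) else np.asarray(S, float)
    grand = values.sum()
    if grand == 0:
        raise ValueError("separability prediction undefined for zero-sum S")
    return np.outer(values.sum(axis=1), values.sum(axis=0)) / grand


def svd_index(S) -> float:
    """v1^2 / sum(v_i^2) over singular values; 1 = fully separable."""
    values = S.values if isinstance(S, MetricSurface) else np.asarray(S, float)
    if not np.any(values):
        raise ValueError("SVD index undefined for an all-zero surface")
    v = np.linalg.svd(values, compute_uv=False)
    return float(v[0] ** 2 / np.sum(v ** 2))


def dprime_from_pc(pc: float, m: Optional[int] = None) -> float:
    """2AFC percent correct -> d' via sqrt(2) Phi^-1(pc).

    With a trial count ``m``, pc is clipped to [1/(2m), 1 - 1/(2m)] to
    keep perfect scores finite.
    """
    if m is not None:
        pc = min(max(pc, 1.0 / (2 * m)), 1.0 - 1.0 / (2 * m))
    if not 0.0 < pc < 1.0:
        raise ValueError("pc must lie strictly in (0, 1); pass m to clip")
    return math.sqrt(2.0) * float(stats.norm.ppf(pc))


def efficiency(d_human: float, snr: float) -> float:
    """Square ratio of observed to ideal d'; ideal d' equals the SNR."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return (d_human / snr) ** 2


def wilcoxon_signed_rank(x: Sequence, y: Optional[Sequence] = None) -> float:
    """Two-tailed Wilcoxon signed-rank p value (paired, or x against 0)."""
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(d, zero_method="wilcox").pvalue)


def friedman_trend(data: np.ndarray) -> float:
    """Friedman-test p value for a subjects x levels repeated-measures table."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 3:
        raise ValueError("need a 2D table with >= 2 subjects and >= 3 levels")
    return float(stats.friedmanchisquare(*data.T).pvalue)
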