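"""Restricted mutual information between two index-color images.

Plain mutual information between the label images X (fixed/template) and Y
(moving, resampled onto the template grid) suffers from *background
attraction* in template matching: large empty regions of the slide produce
spuriously high scores.  Restricted mutual information (RMI) injects the
prior knowledge that label 0 means "background" in both modalities by
adjusting the estimated joint distribution with a factor alpha in [0, 1]:

    p_a(x, 0) = (1 - alpha) p(x, 0)            for x != 0
    p_a(0, y) = (1 - alpha) p(0, y)            for y != 0
    p_a(0, 0) = (1 - alpha) p(0, 0) + alpha [P(X=0) + P(Y=0) - p(0, 0)]

i.e. a fraction alpha of all background-mismatch mass is rerouted to the
background-background cell; all foreground-foreground cells are untouched
and the adjusted table still sums to one.  The score is then

    I_a(X, Y) = H(X) + H(Y) - H_a(X, Y),
    H_a(X, Y) = - sum_xy p(x, y) log p_a(x, y),

a cross-entropy of the observed joint against the adjusted one.  alpha = 0
recovers ordinary mutual information; by Gibbs' inequality I_a <= I_0.
Logarithms are base 2 by default, so scores are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import IndexImage

__all__ = [
    "JointDistribution",
    "AdjustedDistribution",
    "joint_histogram",
    "joint_counts",
    "adjust_distribution",
    "adjusted_joint",
    "restricted_mi",
    "restricted_mi_from_counts",
    "standard_mi",
]


def _entropy(p: np.ndarray, log_base: float) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


@dataclass
class JointDistribution:
    """Joint label counts of overlapping pixel pairs plus derived quantities.

    Rows index the fixed-image label x in 0..k_X, columns the moving-image
    label y in 0..k_Y.  Zero-count rows/columns are retained so that label 0
    keeps its background identity.
    """

    counts: np.ndarray
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("empty joint table")

    @property
    def m(self) -> int:
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def marginal_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def entropy_x(self) -> float:
        return _entropy(self.marginal_x, self.log_base)

    @property
    def entropy_y(self) -> float:
        return _entropy(self.marginal_y, self.log_base)


@dataclass
class AdjustedDistribution:
    """Background-adjusted joint probabilities p_alpha."""

    p_alpha: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.p_alpha = np.asarray(self.p_alpha, dtype=np.float64)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def joint_counts(fixed_labels: np.ndarray, moving_labels: np.ndarray,
                 n_x: int, n_y: int) -> np.ndarray:
    """Raw (n_x x n_y) contingency table of overlapping label pairs."""
    if fixed_labels.shape != moving_labels.shape:
        raise ValueError("label grids must have the same shape")
    pair = fixed_labels.astype(np.int64).ravel() * n_y + moving_labels.astype(np.int64).ravel()
    return np.bincount(pair, minlength=n_x * n_y).reshape(n_x, n_y)


def joint_histogram(
    fixed: IndexImage, moving_sampled: IndexImage, log_base: float = 2.0
) -> JointDistribution:
    """Joint distribution of labels over all overlapping pixel pairs.

    ``moving_sampled`` must already live on the fixed image's grid, so every
    fixed pixel contributes exactly one pair and m equals the template size.
    """
    if fixed.shape != moving_sampled.shape:
        raise ValueError("images must have the same shape (sample the moving image first)")
    counts = joint_counts(fixed.labels, moving_sampled.labels, fixed.k + 1, moving_sampled.k + 1)
    return JointDistribution(counts, log_base=log_base)


def adjusted_joint(p: np.ndarray, alpha: float) -> np.ndarray:
    """Apply the background adjustment to a joint probability table."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    p = np.asarray(p, dtype=np.float64)
    p_a = p.copy()
    px0 = p[0, :].sum()  # P(X=0)
    py0 = p[:, 0].sum()  # P(Y=0)
    p_a[1:, 0] = (1.0 - alpha) * p[1:, 0]
    p_a[0, 1:] = (1.0 - alpha) * p[0, 1:]
    p_a[0, 0] = (1.0 - alpha) * p[0, 0] + alpha * (px0 + py0 - p[0, 0])
    return p_a


def adjust_distribution(jd: JointDistribution, alpha: float) -> AdjustedDistribution:
    """Background-adjusted joint distribution p_alpha of a joint table."""
    return AdjustedDistribution(adjusted_joint(jd.p, alpha), alpha)


def restricted_mi_from_counts(
    counts: np.ndarray, alpha: float, log_base: float = 2.0
) -> float:
    """RMI in one shot from a raw contingency table (registration hot path)."""
    total = counts.sum()
    p = counts / total
    p_a = adjusted_joint(p, alpha)
    log_scale = np.log(log_base)
    hx = _entropy(p.sum(axis=1), log_base)
    hy = _entropy(p.sum(axis=0), log_base)
    support = p > 0
    if np.any(p_a[support] == 0):
        # only possible at alpha=1 with observed background-mismatch pairs
        return float("-inf")
    h_a = float(-(p[support] * (np.log(p_a[support]) / log_scale)).sum())
    return hx + hy - h_a


def restricted_mi(jd: JointDistribution, alpha: float) -> float:
    """I_alpha = H(X) + H(Y) - H_alpha(X, Y), in units of log_base.

    Cells with p(x, y) = 0 contribute nothing regardless of p_alpha; a cell
    with p > 0 but p_alpha = 0 (alpha = 1 on a border cell) makes the score
    -inf, which any caller treats as worst-possible.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return restricted_mi_from_counts(jd.counts, alpha, jd.log_base)


def standard_mi(jd: JointDistribution) -> float:
    """Ordinary mutual information I = H(X) + H(Y) - H(X, Y)."""
    return restricted_mi_from_counts(jd.counts, 0.0, jd.log_base)
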