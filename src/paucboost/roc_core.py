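"""Empirical and smoothed partial AUC.

The partial AUC (pAUC) is the area under the ROC curve restricted to a
false-positive-rate window [alpha1, alpha2]; its maximum attainable value is
``alpha2 - alpha1``.  Empirically it is the pairwise sum over cases and the
controls whose attained FPR falls inside the window:

    pAUC = (1/(n0*n1)) * sum_i sum_{j: c2_hat <= s0_j < c1_hat} H(s1_i - s0_j)

with the Heaviside convention H(0) = 1 applied throughout (a sample scoring
exactly at a threshold counts as positive).  Geometrically this area splits
into a rectangle below the curve's height at the lower-FPR threshold and a
fan-shaped cap above it; the pairwise sum covers both at once.  Because the
in-window controls are exactly the order statistics at the attained FPR
levels k/n0, the sum is equivalently a Riemann sum of the ROC staircase
over those levels:

    pAUC = (1/n0) * sum_{k = k1+1}^{k2} TPR(c_k),   FPR(c_k) = k/n0.

The smoothed (approximate) pAUC is built from this level form with the
normal CDF H_sigma(z) = Phi(z/sigma) replacing H everywhere: each level
threshold c_k solves the *smoothed* FPR equation
(1/n0) sum_j Phi((s0_j - c)/sigma) = (k - 1/2)/n0 (the half-step target
makes c_k harden to the k-th largest control score as sigma -> 0), and the
TPR is smoothed the same way.  This makes the quantity differentiable in any coefficient entering
the score linearly, gives it the null value (alpha2^2 - alpha1^2)/2 for a
score collapsing to a constant, makes it *increase* with the overall scale
of the score toward the empirical pAUC (the monotone-limit property that
justifies optimizing the smoothed objective and lets sigma stay fixed at 1
with the scale free), and recovers the empirical form as sigma -> 0.
Smoothing only the pairwise comparisons while keeping hard thresholds would
instead start a near-zero score at Phi(0) times the window width — above
any attainable pAUC at a narrow window — so maximization would shrink the
score; smoothing the thresholds but keeping a hard control subset would
leave a fresh unit-scale score with an empty window and a zero gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi(z: np.ndarray) -> np.ndarray:
    """Standard normal density."""
    return np.exp(-0.5 * np.square(z)) / _SQRT2PI

__all__ = [
    "PAUCConfig",
    "ScorePair",
    "ThresholdPair",
    "SmoothedBand",
    "empirical_fpr_tpr",
    "select_thresholds",
    "smoothed_band",
    "empirical_pauc",
    "approximate_pauc",
    "roc_curve",
]


@dataclass(frozen=True)
class PAUCConfig:
    """FPR window [alpha1, alpha2] and smoothing scale sigma.

    ``sigma`` only enters the smoothed pAUC; the objective is invariant to a
    joint rescaling of all score coefficients and 1/sigma, so boosting fixes
    sigma = 1 without loss of generality.
    """

    alpha1: float = 0.0
    alpha2: float = 0.1
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha1 < self.alpha2 <= 1.0):
            raise ValueError(
                f"require 0 <= alpha1 < alpha2 <= 1, got ({self.alpha1}, {self.alpha2})"
            )
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ScorePair:
    """Scores of controls (class 0) and cases (class 1) under one score function."""

    scores0: np.ndarray
    scores1: np.ndarray

    def __post_init__(self) -> None:
        s0 = np.asarray(self.scores0, dtype=float)
        s1 = np.asarray(self.scores1, dtype=float)
        if s0.ndim != 1 or s1.ndim != 1:
            raise ValueError("scores must be 1-D arrays")
        if s0.size == 0 or s1.size == 0:
            raise ValueError("each class needs at least one sample")
        if not (np.isfinite(s0).all() and np.isfinite(s1).all()):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores0", s0)
        object.__setattr__(self, "scores1", s1)

    @property
    def n0(self) -> int:
        return self.scores0.size

    @property
    def n1(self) -> int:
        return self.scores1.size

    @classmethod
    def from_labels(cls, scores: np.ndarray, labels: np.ndarray) -> "ScorePair":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        return cls(scores[labels == 0], scores[labels == 1])


@dataclass(frozen=True)
class ThresholdPair:
    """Data-driven thresholds attaining empirical FPRs nearest the targets.

    ``c2_hat <= c1_hat`` and ``alpha1_hat <= alpha2_hat``; attained FPRs are
    multiples of 1/n0.  When ``alpha1_hat == 0`` the upper threshold sits an
    infinitesimal step above the largest control score (implemented by a
    strict comparison, never by perturbing the data) and the rectangle term
    of the pAUC vanishes.
    """

    c1_hat: float
    c2_hat: float
    alpha1_hat: float
    alpha2_hat: float
    # strict flags realize the "+epsilon above the top control score" threshold
    # (attained FPR 0) by a strict comparison instead of perturbing values
    c1_strict: bool = field(default=False)
    c2_strict: bool = field(default=False)


def _attained_fprs(scores0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate thresholds (unique control scores, descending) and their FPRs.

    FPR at threshold c is #{controls >= c}/n0; FPR 0 is attainable by a
    threshold strictly above the maximum and is handled by the caller.
    """
    vals, counts = np.unique(scores0, return_counts=True)
    vals, counts = vals[::-1], counts[::-1]  # descending values
    fprs = np.cumsum(counts) / scores0.size  # #{>= vals[i]} / n0
    return vals, fprs


def _nearest_fpr(
    thr_vals: np.ndarray, fprs: np.ndarray, target: float, max0: float
) -> tuple[float, float, bool]:
    """Pick (threshold, attained FPR, strict-flag) with FPR nearest the target.

    Candidates are the attained FPRs plus 0; on a distance tie the smaller
    FPR (more conservative threshold) wins.  FPR 0 is realized by a strict
    comparison against the maximum control score.
    """
    # fprs ascend along descending thresholds; prepend FPR 0 (above-max threshold)
    cand_fpr = np.concatenate(([0.0], fprs))
    cand_thr = np.concatenate(([max0], thr_vals))
    strict = np.zeros(cand_fpr.size, dtype=bool)
    strict[0] = True
    dist = np.abs(cand_fpr - target)
    # ties (to within rounding) go to the smaller FPR = more specific threshold
    best = int(np.flatnonzero(dist <= dist.min() + 1e-12)[0])
    return float(cand_thr[best]), float(cand_fpr[best]), bool(strict[best])


def select_thresholds(pair: ScorePair, cfg: PAUCConfig) -> ThresholdPair:
    """Thresholds whose attained control FPRs are closest to alpha1 and alpha2."""
    thr_vals, fprs = _attained_fprs(pair.scores0)
    max0 = float(pair.scores0.max())
    if cfg.alpha1 == 0.0:
        c1, a1, strict1 = max0, 0.0, True
    else:
        c1, a1, strict1 = _nearest_fpr(thr_vals, fprs, cfg.alpha1, max0)
    c2, a2, strict2 = _nearest_fpr(thr_vals, fprs, cfg.alpha2, max0)
    if a2 < a1:  # cannot happen with a monotone nearest rule; guard anyway
        c2, a2, strict2 = c1, a1, strict1
    return ThresholdPair(
        c1_hat=c1, c2_hat=c2, alpha1_hat=a1, alpha2_hat=a2,
        c1_strict=strict1, c2_strict=strict2,
    )


@dataclass(frozen=True)
class SmoothedBand:
    """Smoothed-FPR thresholds at the attained FPR levels inside the window.

    ``levels[k]`` is an FPR level k/n0 in (alpha1_hat, alpha2_hat] and
    ``thresholds[k]`` solves the smoothed FPR equation at that level.
    ``width`` is (k2 - k1)/n0, the total FPR mass the levels stand for; the
    smoothed pAUC is width times the mean smoothed TPR over the levels, so
    the level grid may be subsampled at large n0 without changing scale.
    """

    levels: np.ndarray
    thresholds: np.ndarray
    alpha1_hat: float
    alpha2_hat: float
    width: float


def _nearest_level(n0: int, alpha: float) -> int:
    """Integer k with k/n0 nearest alpha; distance ties go to the smaller k."""
    return int(np.floor(alpha * n0 + 0.5 - 1e-12))


def _solve_smoothed_fpr(s0: np.ndarray, targets: np.ndarray, sigma: float) -> np.ndarray:
    """Thresholds c with (1/n0) sum_j Phi((s0_j - c)/sigma) = target, per target.

    Vectorized bisection; the smoothed FPR is continuous and strictly
    decreasing in c, so each root is unique.
    """
    targets = np.asarray(targets, dtype=float)
    lo = np.full(targets.shape, float(s0.min()) - 12.0 * sigma)
    hi = np.full(targets.shape, float(s0.max()) + 12.0 * sigma)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f = ndtr((s0[None, :] - mid[:, None]) / sigma).mean(axis=1)
        too_low = f > targets  # threshold too small -> FPR too big -> move up
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def smoothed_band(
    pair: ScorePair, cfg: PAUCConfig, max_levels: int | None = None
) -> SmoothedBand:
    """Window structure of the smoothed pAUC for a given score.

    The FPR levels are the attained multiples of 1/n0 whose nearest-target
    selection mirrors the empirical thresholds.  Each level's threshold
    solves the smoothed FPR equation at (k - 1/2)/n0: the half-step target
    makes the root converge to the k-th largest control score as sigma -> 0
    (that control contributes exactly Phi(0) = 1/2 there), so the smoothed
    quantity hardens into the empirical fan + rectangle form, and the top
    level k = n0 needs no special handling.
    """
    n0 = pair.n0
    k1 = _nearest_level(n0, cfg.alpha1) if cfg.alpha1 > 0.0 else 0
    k2 = _nearest_level(n0, cfg.alpha2)
    k2 = max(k2, k1)
    ks = np.arange(k1 + 1, k2 + 1, dtype=float)
    if max_levels is not None and ks.size > max_levels:
        # evenly spaced quadrature sub-grid; the width factor keeps the scale
        ks = np.quantile(ks, np.linspace(0, 1, max_levels))
    targets = (ks - 0.5) / n0
    thresholds = (
        _solve_smoothed_fpr(pair.scores0, targets, cfg.sigma)
        if ks.size
        else np.empty(0)
    )
    return SmoothedBand(
        levels=ks / n0,
        thresholds=thresholds,
        alpha1_hat=k1 / n0,
        alpha2_hat=k2 / n0,
        width=(k2 - k1) / n0,
    )


def empirical_fpr_tpr(pair: ScorePair, c: float) -> tuple[float, float]:
    """(FPR, TPR) at threshold c with the >= positivity convention."""
    if not np.isfinite(c):
        raise ValueError("threshold must be finite")
    fpr = float(np.count_nonzero(pair.scores0 >= c)) / pair.n0
    tpr = float(np.count_nonzero(pair.scores1 >= c)) / pair.n1
    return fpr, tpr


def _band_mask(scores0: np.ndarray, thr: ThresholdPair) -> np.ndarray:
    """Controls inside the FPR window: c2_hat <= score < c1_hat (strict-aware)."""
    upper = scores0 <= thr.c1_hat if thr.c1_strict else scores0 < thr.c1_hat
    lower = scores0 > thr.c2_hat if thr.c2_strict else scores0 >= thr.c2_hat
    return lower & upper


def empirical_pauc(
    pair: ScorePair, cfg: PAUCConfig, thr: ThresholdPair | None = None
) -> float:
    """Empirical pAUC: pairwise count over the controls inside the window."""
    if thr is None:
        thr = select_thresholds(pair, cfg)
    band = pair.scores0[_band_mask(pair.scores0, thr)]
    if not band.size:
        return 0.0
    total = np.count_nonzero(pair.scores1[:, None] >= band[None, :])
    return float(total) / (pair.n0 * pair.n1)


def approximate_pauc(
    pair: ScorePair, cfg: PAUCConfig, band: SmoothedBand | None = None
) -> float:
    """Smoothed pAUC: Heaviside replaced by Phi(z/sigma) throughout.

    Sums the smoothed TPR over the smoothed-FPR thresholds of the attained
    levels in the window.  Pass ``band`` to evaluate at frozen thresholds
    (as the one-step Newton update does); by default the band is recomputed
    for the given scores.
    """
    if band is None:
        band = smoothed_band(pair, cfg)
    if not band.thresholds.size:
        return 0.0
    z = (pair.scores1[:, None] - band.thresholds[None, :]) / cfg.sigma
    tpr_mean = float(ndtr(z).mean())
    return band.width * tpr_mean


def roc_curve(pair: ScorePair) -> np.ndarray:
    """Staircase ROC: (FPR, TPR) at every attained threshold, (0,0) to (1,1).

    Thresholds sweep the unique pooled scores from above the maximum down to
    the minimum, with the same >= convention as :func:`empirical_fpr_tpr`.
    """
    pooled = np.unique(np.concatenate([pair.scores0, pair.scores1]))[::-1]
    pts = [(0.0, 0.0)]
    for c in pooled:
        pts.append(empirical_fpr_tpr(pair, float(c)))
    pts = np.asarray(pts)
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:  # always reached at the minimum
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def pauc_upper_bound(cfg: PAUCConfig) -> float:
    """Maximum attainable pAUC over the window, alpha2 - alpha1."""
    return cfg.alpha2 - cfg.alpha1


def null_pauc(cfg: PAUCConfig) -> float:
    """Population pAUC of an uninformative score (diagonal ROC)."""
    return 0.5 * (cfg.alpha2**2 - cfg.alpha1**2)


def smoothed_pauc_derivatives(
    base1: np.ndarray,
    f1: np.ndarray,
    beta: float,
    band: SmoothedBand,
    sigma: float = 1.0,
) -> tuple[float, float]:
    """First and second derivative in beta of the smoothed pAUC of base + beta*f.

    The band (level thresholds) is held fixed, as in the one-step Newton
    update of the boosting loop; with frozen thresholds only the case
    scores ``base1 + beta * f1`` move.
    """
    if not band.thresholds.size:
        return 0.0, 0.0
    z = (base1[:, None] + beta * f1[:, None] - band.thresholds[None, :]) / sigma
    pdf = _phi(z)
    scale = band.width / pdf.size  # width times the mean over (cases, levels)
    d1 = scale * float((pdf * f1[:, None]).sum()) / sigma
    d2 = scale * float((-z * pdf * f1[:, None] ** 2).sum()) / sigma**2
    return d1, d2
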