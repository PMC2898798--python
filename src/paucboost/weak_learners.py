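"""Weak-classifier dictionaries: natural cubic spline bases and decision stumps.

Continuous markers get the m-function natural cubic spline basis on knots
placed at equally spaced quantiles; discrete/ordinal markers get threshold
stumps at midpoints between consecutive unique values; categorical markers
get one-vs-rest stumps.  Every dictionary element is standardized so that
its maximum absolute value over the training samples is 1, which puts the
boosting coefficients of all learners on a common height scale.

The roughness penalty of a spline component F_k is the integrated squared
second derivative, a quadratic form beta' Omega beta; Omega is computed in
closed form (second derivatives of natural cubic splines are piecewise
linear between the knots and vanish outside them).  Linear functions lie in
the nullspace of Omega and are never penalized; stumps contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NaturalSplineFamily",
    "SplineBasis",
    "Stump",
    "build_spline_dictionary",
    "build_stump_dictionary",
    "penalty_of",
]


class NaturalSplineFamily:
    """The m-dimensional natural cubic spline space on given knots.

    Basis (with knots xi_1 < ... < xi_m):

        N_1(x) = 1,  N_2(x) = x,
        N_{l+2}(x) = d_l(x) - d_{m-1}(x),  l = 1..m-2,
        d_l(x) = [ (x - xi_l)_+^3 - (x - xi_m)_+^3 ] / (xi_m - xi_l)

    Each N_{l+2} is linear outside [xi_1, xi_m] (natural boundary).
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError("need at least 2 knots")
        if not np.all(np.diff(knots) > 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        self.m = knots.size
        self._omega = None

    def design(self, x: np.ndarray) -> np.ndarray:
        """Raw (unstandardized) basis values, shape (len(x), m)."""
        x = np.asarray(x, dtype=float)
        xi = self.knots
        m = self.m
        out = np.empty((x.size, m))
        out[:, 0] = 1.0
        out[:, 1] = x
        if m > 2:
            pm = np.maximum(x - xi[m - 1], 0.0) ** 3
            dlast = (np.maximum(x - xi[m - 2], 0.0) ** 3 - pm) / (xi[m - 1] - xi[m - 2])
            for l in range(m - 2):
                dl = (np.maximum(x - xi[l], 0.0) ** 3 - pm) / (xi[m - 1] - xi[l])
                out[:, l + 2] = dl - dlast
        return out

    def second_derivative_at_knots(self) -> np.ndarray:
        """N_l'' evaluated at the knots, shape (m, m); rows follow the basis."""
        xi = self.knots
        m = self.m
        d2 = np.zeros((m, m))
        if m > 2:
            # d_l''(x) = 6 (x - xi_l)_+ / (xi_m - xi_l) for x <= xi_m
            dd = np.zeros((m - 1, m))
            for l in range(m - 1):
                dd[l] = 6.0 * np.maximum(xi - xi[l], 0.0) / (xi[m - 1] - xi[l])
            for l in range(m - 2):
                d2[l + 2] = dd[l] - dd[m - 2]
        return d2

    @property
    def omega(self) -> np.ndarray:
        """Raw penalty matrix Omega_ab = integral of N_a'' N_b'' (exact)."""
        if self._omega is None:
            xi = self.knots
            m = self.m
            d2 = self.second_derivative_at_knots()
            omega = np.zeros((m, m))
            # second derivatives are piecewise linear on knot intervals and 0
            # outside, so Simpson-exact interval formula applies
            for i in range(m - 1):
                h = xi[i + 1] - xi[i]
                a0, a1 = d2[:, i], d2[:, i + 1]
                omega += (h / 6.0) * (
                    2.0 * np.outer(a0, a0)
                    + np.outer(a0, a1)
                    + np.outer(a1, a0)
                    + 2.0 * np.outer(a1, a1)
                )
            self._omega = omega
        return self._omega


@dataclass(frozen=True)
class SplineBasis:
    """One standardized natural-spline basis element for one marker."""

    marker_index: int
    basis_id: int
    family: NaturalSplineFamily
    z_norm: float  # max |N| over training samples; divides the raw basis

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.family.design(np.atleast_1d(x))[:, self.basis_id] / self.z_norm

    @property
    def sort_key(self) -> tuple:
        return (self.marker_index, 0, self.basis_id)


@dataclass(frozen=True)
class Stump:
    """Single-split rule on one marker, output in {0, 1}.

    Threshold stump: 1 if x >= split (orientation +1) or x < split (-1).
    Categorical stump: 1 if x in the category set (orientation +1) or not (-1).
    """

    marker_index: int
    split: float | None = None
    categories: frozenset = field(default_factory=frozenset)
    orientation: int = 1

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.split is not None:
            ind = x >= self.split
        else:
            ind = np.isin(x, sorted(self.categories))
        out = ind.astype(float)
        return out if self.orientation > 0 else 1.0 - out

    @property
    def sort_key(self) -> tuple:
        key = self.split if self.split is not None else min(self.categories)
        return (self.marker_index, 1, key, -self.orientation)


def build_spline_dictionary(
    x: np.ndarray, m: int = 5, marker_index: int = 0
) -> list[SplineBasis]:
    """Standardized natural-spline basis for one continuous marker.

    Knots at m equally spaced quantiles of the observed values; if fewer
    distinct values exist, m is reduced with a warning.
    """
    x = np.asarray(x, dtype=float)
    n_unique = np.unique(x).size
    if n_unique < 2:
        logger.warning("marker %d constant; empty spline dictionary", marker_index)
        return []
    if n_unique < m:
        logger.warning(
            "marker %d has %d distinct values < %d knots; reducing",
            marker_index,
            n_unique,
            m,
        )
        m = n_unique
    qs = np.linspace(0.0, 1.0, m)
    knots = np.quantile(x, qs)
    knots = np.unique(knots)
    if knots.size < m:
        logger.warning(
            "marker %d: quantile knots collapsed to %d", marker_index, knots.size
        )
        m = knots.size
    family = NaturalSplineFamily(knots)
    design = family.design(x)
    z = np.abs(design).max(axis=0)
    z[z == 0] = 1.0
    return [
        SplineBasis(marker_index=marker_index, basis_id=l, family=family, z_norm=float(z[l]))
        for l in range(m)
    ]


def build_stump_dictionary(
    x: np.ndarray, marker_index: int = 0, categorical: bool = False
) -> list[Stump]:
    """All stumps for one discrete/categorical marker, both orientations.

    Ordered discrete: one split per midpoint between consecutive unique
    values (2(u-1) stumps).  Categorical: one-vs-rest per category (2u).
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size < 2:
        logger.warning("marker %d constant; empty stump dictionary", marker_index)
        return []
    stumps: list[Stump] = []
    if categorical:
        for v in uniq:
            for o in (1, -1):
                stumps.append(
                    Stump(
                        marker_index=marker_index,
                        categories=frozenset([float(v)]),
                        orientation=o,
                    )
                )
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        for s in mids:
            for o in (1, -1):
                stumps.append(
                    Stump(marker_index=marker_index, split=float(s), orientation=o)
                )
    return stumps


def spline_penalty_matrix(learners: list[SplineBasis]) -> np.ndarray:
    """Penalty matrix in the standardized coordinates of the given elements."""
    if not learners:
        return np.zeros((0, 0))
    family = learners[0].family
    ids = [wl.basis_id for wl in learners]
    z = np.array([wl.z_norm for wl in learners])
    omega = family.omega[np.ix_(ids, ids)]
    return omega / np.outer(z, z)


def penalty_of(score, lam: float) -> float:
    """Roughness penalty lam * sum_k beta_k' Omega_k beta_k of an additive score.

    ``score`` is any object exposing ``spline_groups()`` yielding
    (coefficient vector, standardized penalty matrix) per continuous marker.
    Stump components contribute zero.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 0.0
    total = 0.0
    for beta, omega in score.spline_groups():
        total += float(beta @ omega @ beta)
    return lam * total
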