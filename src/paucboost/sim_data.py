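"""Synthetic-data generators for the simulation designs.

Two families of generators:

* Single-marker mixture-normal scenarios.  Controls are N(0,1); cases
  follow one of four canonical shapes: (1) a clean mean shift with little
  overlap, (2) a screening-type mixture in which a small case fraction
  separates cleanly on one side, (3) cases concentrated inside the control
  range, (4) a two-sided variant of (2) with case mass escaping on both
  tails.  Shapes 2 and 4 are the ones that make the pAUC at low FPR
  informative while the full AUC is not.

* Correlated gene blocks.  p genes per class drawn from a multivariate
  normal whose correlation comes from a normalized Wishart draw
  (Sigma = 0.95*W + 0.05*I, unit diagonal), contaminated by independently
  replacing a fraction of case samples per gene with draws from a shifted
  normal, plus optional noninformative genes sharing one distribution
  across classes.

The mixture component placements are provisional defaults (a 3-SD shift
for the separated case fraction); they are exposed on the spec objects so
studies can pin their own values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .cli_io import MarkerMatrix
from .roc_core import PAUCConfig, ScorePair, approximate_pauc

logger = logging.getLogger(__name__)

__all__ = [
    "Mixture",
    "ScenarioSpec",
    "GeneBlockSpec",
    "generate_scenario",
    "generate_two_marker",
    "generate_gene_block",
    "likelihood_ratio",
    "two_marker_optimal_score",
    "psi_curve",
]


@dataclass(frozen=True)
class Mixture:
    """Finite normal mixture: (weight, mean, sd) components."""

    components: tuple  # of (weight, mean, sd)

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(m), float(s)) for (w, m, s) in self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        wsum = sum(w for w, _, _ in comps)
        if not np.isclose(wsum, 1.0):
            raise ValueError(f"mixture weights must sum to 1, got {wsum}")
        if any(w < 0 or s <= 0 for w, _, s in comps):
            raise ValueError("weights must be >= 0 and sds > 0")
        object.__setattr__(self, "components", comps)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ws = np.array([w for w, _, _ in self.components])
        which = rng.choice(len(ws), size=n, p=ws)
        means = np.array([m for _, m, _ in self.components])[which]
        sds = np.array([s for _, _, s in self.components])[which]
        return rng.normal(means, sds)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in self.components:
            out += w * norm.pdf(x, loc=m, scale=s)
        return out


STANDARD_NORMAL = Mixture(((1.0, 0.0, 1.0),))

# shift of the separated case fraction, in control SDs (provisional default)
CASE_SHIFT = 3.0

# case distributions of the four canonical scenarios
SCENARIO_CASES: dict[int, Mixture] = {
    1: Mixture(((1.0, CASE_SHIFT, 1.0),)),
    2: Mixture(((0.9, 0.0, 1.0), (0.1, CASE_SHIFT, 1.0))),
    3: Mixture(((1.0, 0.0, 0.5),)),
    4: Mixture(((0.9, 0.0, 1.0), (0.05, -CASE_SHIFT, 1.0), (0.05, CASE_SHIFT, 1.0))),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One-marker scenario: control and case mixtures plus sample sizes."""

    scenario: int = 2
    n0: int = 50
    n1: int = 50
    seed: int = 0
    control: Mixture = STANDARD_NORMAL
    case: Mixture | None = None  # None -> canonical mixture for the scenario

    def case_mixture(self) -> Mixture:
        if self.case is not None:
            return self.case
        if self.scenario not in SCENARIO_CASES:
            raise ValueError(f"unknown scenario {self.scenario}")
        return SCENARIO_CASES[self.scenario]


def generate_scenario(spec: ScenarioSpec) -> MarkerMatrix:
    """One-marker matrix with n0 controls then n1 cases."""
    rng = np.random.default_rng(spec.seed)
    x0 = spec.control.sample(spec.n0, rng)
    x1 = spec.case_mixture().sample(spec.n1, rng)
    values = np.concatenate([x0, x1])[:, None]
    labels = np.concatenate([np.zeros(spec.n0, int), np.ones(spec.n1, int)])
    return MarkerMatrix(
        values=values, labels=labels, marker_names=["x"], kinds=["continuous"]
    )


def generate_two_marker(
    setting: str = "nonlinear", n0: int = 50, n1: int = 50, seed: int = 0
) -> MarkerMatrix:
    """The two-marker comparison design: x2 screening-type, x4 per setting.

    ``nonlinear``: x4's case distribution is the two-sided mixture, so the
    optimal component score in x4 is nonmonotone and a linear combination
    cannot capture it.  ``linear``: x4 gets the same one-sided mixture as
    x2 and a linear score is (near-)optimal.  Markers are independent given
    the class.
    """
    if setting not in ("nonlinear", "linear"):
        raise ValueError(f"unknown setting {setting!r}")
    rng = np.random.default_rng(seed)
    case2 = SCENARIO_CASES[2]
    case4 = SCENARIO_CASES[4] if setting == "nonlinear" else SCENARIO_CASES[2]
    x2 = np.concatenate(
        [STANDARD_NORMAL.sample(n0, rng), case2.sample(n1, rng)]
    )
    x4 = np.concatenate(
        [STANDARD_NORMAL.sample(n0, rng), case4.sample(n1, rng)]
    )
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    return MarkerMatrix(
        values=np.column_stack([x2, x4]),
        labels=labels,
        marker_names=["x2", "x4"],
        kinds=["continuous", "continuous"],
    )


def likelihood_ratio(x: np.ndarray, case: Mixture, control: Mixture = STANDARD_NORMAL) -> np.ndarray:
    """Pointwise density ratio g1(x)/g0(x) for one marker."""
    return case.pdf(x) / control.pdf(x)


def two_marker_optimal_score(x2: np.ndarray, x4: np.ndarray, setting: str = "nonlinear") -> np.ndarray:
    """log of the joint likelihood ratio — an optimal score for the design.

    Any strictly increasing transform of the likelihood ratio maximizes the
    pAUC at every FPR window, so the log is taken for numerical comfort.
    """
    case4 = SCENARIO_CASES[4] if setting == "nonlinear" else SCENARIO_CASES[2]
    lr = likelihood_ratio(np.asarray(x2, float), SCENARIO_CASES[2]) * likelihood_ratio(
        np.asarray(x4, float), case4
    )
    return np.log(lr)


@dataclass(frozen=True)
class GeneBlockSpec:
    """Correlated informative gene block plus optional noninformative genes."""

    p: int = 50
    n0: int = 50
    n1: int = 50
    wishart_df: int = 10
    wishart_weight: float = 0.95
    identity_weight: float = 0.05
    contamination: float = 0.10
    case_shift: float = CASE_SHIFT
    n_noninformative: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must be in [0,1]")
        if self.p < 1:
            raise ValueError("need at least one gene")


def _wishart_correlation(p: int, df: int, w: float, eye_w: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-diagonal correlation from Sigma = w*W + eye_w*I, W ~ Wishart(I, df)."""
    for _ in range(10):
        g = rng.standard_normal((p, df))
        sigma = w * (g @ g.T) + eye_w * np.eye(p)
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        try:
            np.linalg.cholesky(corr)
            return corr
        except np.linalg.LinAlgError:
            logger.warning("non-PD correlation after normalization; resampling")
    raise RuntimeError("could not draw a positive-definite correlation matrix")


def generate_gene_block(spec: GeneBlockSpec) -> MarkerMatrix:
    """Draw one repetition of the correlated gene-block design.

    Fresh Wishart correlations per call (per class, and one more shared by
    both classes for the noninformative block); case contamination replaces
    round(contamination * n1) samples per gene, chosen independently per
    gene, with draws from N(case_shift, 1).
    """
    rng = np.random.default_rng(spec.seed)
    corr0 = _wishart_correlation(
        spec.p, spec.wishart_df, spec.wishart_weight, spec.identity_weight, rng
    )
    corr1 = _wishart_correlation(
        spec.p, spec.wishart_df, spec.wishart_weight, spec.identity_weight, rng
    )
    x0 = rng.multivariate_normal(np.zeros(spec.p), corr0, size=spec.n0, method="cholesky")
    x1 = rng.multivariate_normal(np.zeros(spec.p), corr1, size=spec.n1, method="cholesky")
    n_cont = int(round(spec.contamination * spec.n1))
    for j in range(spec.p):
        if n_cont:
            rows = rng.choice(spec.n1, size=n_cont, replace=False)
            x1[rows, j] = rng.normal(spec.case_shift, 1.0, size=n_cont)
    blocks0, blocks1 = [x0], [x1]
    names = [f"g{j+1}" for j in range(spec.p)]
    if spec.n_noninformative:
        q = spec.n_noninformative
        corr_n = _wishart_correlation(
            q, spec.wishart_df, spec.wishart_weight, spec.identity_weight, rng
        )
        blocks0.append(
            rng.multivariate_normal(np.zeros(q), corr_n, size=spec.n0, method="cholesky")
        )
        blocks1.append(
            rng.multivariate_normal(np.zeros(q), corr_n, size=spec.n1, method="cholesky")
        )
        names += [f"noise{j+1}" for j in range(q)]
    values = np.vstack(
        [np.hstack(blocks0), np.hstack(blocks1)]
    )
    labels = np.concatenate([np.zeros(spec.n0, int), np.ones(spec.n1, int)])
    return MarkerMatrix(
        values=values,
        labels=labels,
        marker_names=names,
        kinds=["continuous"] * len(names),
    )


def psi_curve(
    pair: ScorePair,
    gammas: np.ndarray,
    cfg: PAUCConfig,
    max_levels: int | None = 64,
) -> np.ndarray:
    """Smoothed pAUC of gamma * score over a gamma grid.

    With ``pair`` holding m(Lambda) scores on a large Monte-Carlo sample,
    this estimates the map from the coefficient scale to the smoothed
    objective, which increases in gamma and approaches the empirical pAUC
    of m(Lambda) as gamma grows.  The same sample is used at every gamma;
    at large n0 the FPR-level grid is subsampled to ``max_levels``
    quadrature points.
    """
    from .roc_core import smoothed_band

    gammas = np.asarray(gammas, dtype=float)
    out = np.empty(gammas.size)
    for i, g in enumerate(gammas):
        scaled = ScorePair(g * pair.scores0, g * pair.scores1)
        band = smoothed_band(scaled, cfg, max_levels=max_levels)
        out[i] = approximate_pauc(scaled, cfg, band=band)
    return out
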