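"""Componentwise boosting of the penalized smoothed pAUC.

The score function is additive over markers, F(x) = sum_k F_k(x_k), built
forward-stagewise from a dictionary of standardized weak learners (natural
cubic spline basis elements for continuous markers, decision stumps for
discrete/categorical ones).  Each boosting iteration:

1. for every candidate learner f (each kept alive with a positive-start and
   a negative-start coefficient stream), compute the empirical FPR
   thresholds of the provisional score F_{t-1} + beta_{t-1}(f) * f;
2. update beta_{t-1}(f) by a single Newton-Raphson step against the
   penalized smoothed pAUC, with the thresholds held fixed (analytic
   gradient and Hessian of the Phi-smoothed level sum minus the quadratic
   roughness-penalty derivative);
3. pick the (beta, f) pair whose updated score maximizes the penalized
   smoothed pAUC — each candidate judged at its own thresholds — and set
   F_t = F_{t-1} + beta * f.

Setting the FPR window to (0, 1) turns every pAUC into an AUC and the
procedure into AUC boosting.  The smoothing scale is fixed at sigma = 1:
the objective only depends on the product of the coefficient scale and
1/sigma, so sigma is not a free parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .cli_io import MarkerMatrix
from .roc_core import (
    PAUCConfig,
    ScorePair,
    approximate_pauc,
    empirical_pauc,
    smoothed_band,
    smoothed_pauc_derivatives,
)
from .weak_learners import (
    NaturalSplineFamily,
    SplineBasis,
    Stump,
    build_spline_dictionary,
    build_stump_dictionary,
    spline_penalty_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["BoostConfig", "AdditiveScore", "fit", "build_dictionary", "initial_coefficients", "newton_update"]


@dataclass(frozen=True)
class BoostConfig:
    """Boosting hyperparameters.

    lam: roughness-penalty weight (>= 0); n_iter: boosting iterations T;
    step_cap: bound on a single Newton step; fallback_step: gradient-sign
    step size used where the smoothed objective is locally non-concave;
    guard: stop early rather than accept an update that lowers the
    penalized training objective (disable to mimic fixed-T runs).
    """

    pauc: PAUCConfig = field(default_factory=PAUCConfig)
    lam: float = 1e-4
    n_iter: int = 50
    step_cap: float = 10.0
    fallback_step: float = 0.1
    guard: bool = True
    knots: int = 5
    weak_learner: str = "auto"  # spline | stump | auto
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.weak_learner not in ("spline", "stump", "auto"):
            raise ValueError(f"unknown weak_learner {self.weak_learner!r}")


def build_dictionary(data: MarkerMatrix, cfg: BoostConfig):
    """Weak-learner dictionary for a marker matrix under the configured mode.

    Basis elements that are constant over the training samples (the
    intercept element of each spline basis) are dropped: the ROC curve is
    invariant to adding a constant, so they carry no information and would
    only tie the objective.
    """
    learners = []
    for k in range(data.n_markers):
        x = data.marker(k)
        kind = data.kinds[k]
        use_spline = cfg.weak_learner == "spline" or (
            cfg.weak_learner == "auto" and kind == "continuous"
        )
        if use_spline:
            learners.extend(build_spline_dictionary(x, m=cfg.knots, marker_index=k))
        else:
            learners.extend(
                build_stump_dictionary(
                    x, marker_index=k, categorical=(kind == "categorical")
                )
            )
    kept = []
    for wl in learners:
        vals = wl(data.values[:, wl.marker_index])
        if np.ptp(vals) > 0:
            kept.append(wl)
    kept.sort(key=lambda wl: wl.sort_key)
    return kept


def initial_coefficients(dictionary) -> np.ndarray:
    """Per-learner starting coefficients, one +1 and one -1 stream each.

    Both signs enter candidate evaluation so the initial provisional scores
    have positive or negative derivatives; shape (len(dictionary), 2).
    """
    return np.tile(np.array([1.0, -1.0]), (len(dictionary), 1))


def newton_update(beta_prev: float, d1: float, d2: float, cfg: BoostConfig) -> float:
    """One Newton-Raphson coefficient step against the frozen-band objective.

    ``d1``/``d2`` are the first and second derivative of the penalized
    smoothed pAUC at ``beta_prev`` (thresholds fixed).  Where the surrogate
    is locally concave the step is -d1/d2 clipped to ``cfg.step_cap``;
    otherwise a short gradient-sign step of ``cfg.fallback_step`` is taken.
    A stationary point (d1 = 0) leaves the coefficient unchanged.
    """
    if d2 < 0:
        step = float(np.clip(-d1 / d2, -cfg.step_cap, cfg.step_cap))
    else:
        step = cfg.fallback_step * float(np.sign(d1))
    return beta_prev + step


@dataclass
class TraceStep:
    t: int
    learner_index: int
    sign_slot: int
    beta: float
    objective: float


@dataclass
class AdditiveScore:
    """Fitted additive score with its dictionary, coefficients and trace."""

    dictionary: list
    coef: np.ndarray
    marker_names: list[str]
    kinds: list[str]
    config: BoostConfig
    trace: list[TraceStep] = field(default_factory=list)
    marker_range: np.ndarray | None = None  # (p, 2) training min/max per marker

    # -- evaluation ---------------------------------------------------

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Score new samples; NaN marker values contribute 0 to their component."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.zeros(x.shape[0])
        for wl, b in zip(self.dictionary, self.coef):
            if b == 0.0:
                continue
            col = x[:, wl.marker_index]
            ok = np.isfinite(col)
            if not ok.all():
                logger.warning(
                    "marker %s missing for %d samples; component set to 0",
                    self.marker_names[wl.marker_index],
                    int((~ok).sum()),
                )
            vals = np.zeros(x.shape[0])
            vals[ok] = wl(col[ok])
            out += b * vals
        return out

    def predict_data(self, data: MarkerMatrix) -> np.ndarray:
        return self.predict(data.values)

    def component(self, k: int, x: np.ndarray) -> np.ndarray:
        """F_k evaluated on a grid of marker-k values."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros(x.size)
        for wl, b in zip(self.dictionary, self.coef):
            if b != 0.0 and wl.marker_index == k:
                out += b * wl(x)
        return out

    # -- structure ----------------------------------------------------

    def selected_markers(self) -> list[int]:
        """Marker indices in order of first selection."""
        seen: list[int] = []
        for step in self.trace:
            k = self.dictionary[step.learner_index].marker_index
            if k not in seen:
                seen.append(k)
        return seen

    def score_plots(self, n_grid: int = 100):
        """Per-marker (x_k, F_k(x_k)) tables, ordered by first selection.

        Markers never selected are omitted.  Continuous markers use an even
        grid over the training range; discrete ones use their split-adjacent
        values.
        """
        import pandas as pd

        out = []
        for k in self.selected_markers():
            if self.marker_range is not None:
                lo, hi = self.marker_range[k]
            else:
                pts = [wl.family.knots for wl in self.dictionary
                       if isinstance(wl, SplineBasis) and wl.marker_index == k]
                lo, hi = (pts[0].min(), pts[0].max()) if pts else (0.0, 1.0)
            if self.kinds[k] == "continuous":
                grid = np.linspace(lo, hi, n_grid)
            else:
                splits = sorted(
                    {wl.split for wl in self.dictionary
                     if isinstance(wl, Stump) and wl.marker_index == k
                     and wl.split is not None}
                )
                grid = np.unique(np.concatenate([[lo, hi], splits]))
            tab = pd.DataFrame({"x": grid, "F_k": self.component(k, grid)})
            out.append((self.marker_names[k], tab))
        return out

    def spline_groups(self):
        """(coefficient vector, standardized penalty matrix) per spline marker."""
        by_marker: dict[int, list[int]] = {}
        for e, wl in enumerate(self.dictionary):
            if isinstance(wl, SplineBasis):
                by_marker.setdefault(wl.marker_index, []).append(e)
        for k, idx in by_marker.items():
            learners = [self.dictionary[e] for e in idx]
            yield self.coef[idx], spline_penalty_matrix(learners)

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        learners = []
        for wl in self.dictionary:
            if isinstance(wl, SplineBasis):
                learners.append(
                    {
                        "type": "spline",
                        "marker_index": wl.marker_index,
                        "basis_id": wl.basis_id,
                        "knots": wl.family.knots.tolist(),
                        "z_norm": wl.z_norm,
                    }
                )
            else:
                learners.append(
                    {
                        "type": "stump",
                        "marker_index": wl.marker_index,
                        "split": wl.split,
                        "categories": sorted(wl.categories),
                        "orientation": wl.orientation,
                    }
                )
        doc = {
            "format": "paucboost-model",
            "version": 1,
            "marker_names": self.marker_names,
            "kinds": self.kinds,
            "learners": learners,
            "coef": self.coef.tolist(),
            "marker_range": None
            if self.marker_range is None
            else self.marker_range.tolist(),
            "config": {
                "alpha1": self.config.pauc.alpha1,
                "alpha2": self.config.pauc.alpha2,
                "sigma": self.config.pauc.sigma,
                "lambda": self.config.lam,
                "n_iter": self.config.n_iter,
                "step_cap": self.config.step_cap,
                "fallback_step": self.config.fallback_step,
                "guard": self.config.guard,
                "knots": self.config.knots,
                "weak_learner": self.config.weak_learner,
                "seed": self.config.seed,
            },
            "trace": [
                {
                    "t": s.t,
                    "learner_index": s.learner_index,
                    "sign_slot": s.sign_slot,
                    "beta": s.beta,
                    "objective": s.objective,
                }
                for s in self.trace
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AdditiveScore":
        doc = json.loads(text)
        if doc.get("format") != "paucboost-model":
            raise ValueError("not a paucboost model document")
        families: dict[tuple, NaturalSplineFamily] = {}
        dictionary = []
        for spec in doc["learners"]:
            if spec["type"] == "spline":
                key = tuple(spec["knots"])
                fam = families.setdefault(key, NaturalSplineFamily(np.array(spec["knots"])))
                dictionary.append(
                    SplineBasis(
                        marker_index=spec["marker_index"],
                        basis_id=spec["basis_id"],
                        family=fam,
                        z_norm=spec["z_norm"],
                    )
                )
            else:
                dictionary.append(
                    Stump(
                        marker_index=spec["marker_index"],
                        split=spec["split"],
                        categories=frozenset(spec["categories"]),
                        orientation=spec["orientation"],
                    )
                )
        c = doc["config"]
        cfg = BoostConfig(
            pauc=PAUCConfig(c["alpha1"], c["alpha2"], c["sigma"]),
            lam=c["lambda"],
            n_iter=c["n_iter"],
            step_cap=c["step_cap"],
            fallback_step=c["fallback_step"],
            guard=c["guard"],
            knots=c["knots"],
            weak_learner=c["weak_learner"],
            seed=c["seed"],
        )
        return cls(
            dictionary=dictionary,
            coef=np.array(doc["coef"], dtype=float),
            marker_names=doc["marker_names"],
            kinds=doc["kinds"],
            config=cfg,
            trace=[TraceStep(**s) for s in doc["trace"]],
            marker_range=None
            if doc["marker_range"] is None
            else np.array(doc["marker_range"]),
        )


class _Fitter:
    """One boosting run; holds the precomputed design and penalty blocks."""

    def __init__(self, data: MarkerMatrix, cfg: BoostConfig):
        data.require_both_classes()
        self.data = data
        self.cfg = cfg
        self.dictionary = build_dictionary(data, cfg)
        if not self.dictionary:
            raise ValueError("empty weak-learner dictionary")
        d = len(self.dictionary)
        n = data.n_samples
        self.phi = np.empty((n, d))
        for e, wl in enumerate(self.dictionary):
            self.phi[:, e] = wl(data.values[:, wl.marker_index])
        self.is0 = data.labels == 0
        self.is1 = data.labels == 1
        # standardized penalty blocks per spline marker
        self.pen_block: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        by_marker: dict[int, list[int]] = {}
        for e, wl in enumerate(self.dictionary):
            if isinstance(wl, SplineBasis):
                by_marker.setdefault(wl.marker_index, []).append(e)
        for k, idx in by_marker.items():
            omega = spline_penalty_matrix([self.dictionary[e] for e in idx])
            self.pen_block[k] = (np.array(idx), omega)
        # position of element e inside its marker's penalty block
        self.pen_pos = {}
        for k, (idx, _) in self.pen_block.items():
            for pos, e in enumerate(idx):
                self.pen_pos[e] = (k, pos)

    def penalty_total(self, coef: np.ndarray) -> float:
        tot = 0.0
        for idx, omega in self.pen_block.values():
            v = coef[idx]
            tot += float(v @ omega @ v)
        return tot

    def run(self) -> AdditiveScore:
        cfg = self.cfg
        d = len(self.dictionary)
        coef = np.zeros(d)
        beta_state = initial_coefficients(self.dictionary)
        F = np.zeros(self.data.n_samples)
        trace: list[TraceStep] = []
        lam = cfg.lam
        F0, F1 = F[self.is0], F[self.is1]
        obj_prev = approximate_pauc(ScorePair(F0, F1), cfg.pauc) - lam * self.penalty_total(coef)

        for t in range(1, cfg.n_iter + 1):
            best = None  # (obj, e, s, beta_new)
            F0, F1 = F[self.is0], F[self.is1]
            for e in range(d):
                f0 = self.phi[self.is0, e]
                f1 = self.phi[self.is1, e]
                pen_info = self.pen_pos.get(e)
                for s in range(2):
                    b_prev = beta_state[e, s]
                    pair_prev = ScorePair(F0 + b_prev * f0, F1 + b_prev * f1)
                    band = smoothed_band(pair_prev, cfg.pauc)
                    d1, d2 = smoothed_pauc_derivatives(
                        F1, f1, b_prev, band, cfg.pauc.sigma
                    )
                    if lam > 0 and pen_info is not None:
                        k, pos = pen_info
                        idx, omega = self.pen_block[k]
                        v = coef[idx]
                        d1 -= lam * 2.0 * (float(omega[pos] @ v) + b_prev * omega[pos, pos])
                        d2 -= lam * 2.0 * omega[pos, pos]
                    if not (np.isfinite(d1) and np.isfinite(d2)):
                        logger.warning("non-finite derivative for learner %d; skipped", e)
                        continue
                    b_new = newton_update(b_prev, d1, d2, cfg)
                    beta_state[e, s] = b_new
                    # objective of the updated candidate at its own thresholds
                    pair_new = ScorePair(F0 + b_new * f0, F1 + b_new * f1)
                    pen_new = self.penalty_total(coef)
                    if lam > 0 and pen_info is not None:
                        k, pos = pen_info
                        idx, omega = self.pen_block[k]
                        v = coef[idx]
                        pen_new += 2.0 * b_new * float(omega[pos] @ v) + b_new**2 * omega[pos, pos]
                    obj = approximate_pauc(pair_new, cfg.pauc) - lam * pen_new
                    if best is None or obj > best[0]:
                        best = (obj, e, s, b_new)
            if best is None:
                logger.warning("no evaluable candidate at t=%d; stopping", t)
                break
            obj_best, e_best, s_best, b_best = best
            if cfg.guard and obj_best < obj_prev - 1e-12:
                logger.info("objective would decrease at t=%d; early stop", t)
                break
            coef[e_best] += b_best
            F = F + b_best * self.phi[:, e_best]
            obj_prev = obj_best
            trace.append(
                TraceStep(t=t, learner_index=e_best, sign_slot=s_best, beta=b_best, objective=obj_best)
            )

        rng = np.stack([self.data.values.min(axis=0), self.data.values.max(axis=0)], axis=1)
        return AdditiveScore(
            dictionary=self.dictionary,
            coef=coef,
            marker_names=list(self.data.marker_names),
            kinds=list(self.data.kinds),
            config=cfg,
            trace=trace,
            marker_range=rng,
        )


def fit(data: MarkerMatrix, cfg: BoostConfig | None = None) -> AdditiveScore:
    """Run the boosting loop for cfg.n_iter iterations; deterministic."""
    return _Fitter(data, cfg or BoostConfig()).run()


def training_pauc(model: AdditiveScore, data: MarkerMatrix, empirical: bool = True) -> float:
    """Convenience: (p)AUC of the fitted score on a data set."""
    pair = ScorePair.from_labels(model.predict_data(data), data.labels)
    f = empirical_pauc if empirical else approximate_pauc
    return f(pair, model.config.pauc)
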