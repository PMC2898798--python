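"""Comparison methods: SDF linear combination and stump AdaBoost.

The SDF comparator maximizes the empirical pAUC over linear combinations
of exactly two markers.  The search runs over an angle grid theta in
(-pi/2, pi/2] with score cos(theta)*x2 + sin(theta)*x4, which covers every
direction up to the positive scaling the ROC curve is invariant to; the
result is reported as coefficients (1, tan theta) when cos(theta) != 0.

AdaBoost combines decision stumps (output -1/+1) by exponential-loss
reweighting; its margin is reused as a score function so it can be judged
on the same pAUC metric as the boosted spline score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cli_io import MarkerMatrix
from .roc_core import PAUCConfig, ScorePair, empirical_pauc
from .weak_learners import Stump, build_stump_dictionary

__all__ = ["LinearCombo", "AdaBoostModel", "sdf_fit", "adaboost_fit", "false_discovery_pct"]

_BETA_CAP = 10.0  # coefficient bound when a stump classifies perfectly


@dataclass(frozen=True)
class LinearCombo:
    """Best linear two-marker score found by the angle-grid search."""

    theta: float
    pauc: float

    @property
    def coefficients(self) -> tuple[float, float]:
        """(coef_x2, coef_x4); (1, tan theta) when cos theta != 0, else (0, 1)."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        if abs(c) < 1e-12:
            return (0.0, 1.0)
        return (1.0, s / c)

    def predict(self, x2: np.ndarray, x4: np.ndarray) -> np.ndarray:
        return math.cos(self.theta) * np.asarray(x2) + math.sin(self.theta) * np.asarray(x4)


def sdf_fit(
    x2: np.ndarray,
    x4: np.ndarray,
    labels: np.ndarray,
    cfg: PAUCConfig,
    n_angles: int = 2000,
) -> LinearCombo:
    """Exhaustive angle-grid maximization of the empirical pAUC.

    Ties in the objective go to the smallest |theta| (the most x2-dominant
    direction among the maximizers).
    """
    x2 = np.asarray(x2, dtype=float)
    x4 = np.asarray(x4, dtype=float)
    labels = np.asarray(labels)
    thetas = -np.pi / 2 + np.pi * np.arange(1, n_angles + 1) / n_angles
    thetas = thetas[np.argsort(np.abs(thetas), kind="stable")]  # small |theta| first
    best_theta, best_obj = 0.0, -np.inf
    for th in thetas:
        score = math.cos(th) * x2 + math.sin(th) * x4
        obj = empirical_pauc(ScorePair.from_labels(score, labels), cfg)
        if obj > best_obj + 1e-15:
            best_theta, best_obj = float(th), obj
    return LinearCombo(theta=best_theta, pauc=best_obj)


@dataclass
class AdaBoostModel:
    """Stump ensemble with its per-round coefficients and error trace."""

    stumps: list[Stump]
    betas: list[float]
    errors: list[float]
    marker_names: list[str]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Ensemble margin sum_t beta_t f_t(x); stumps output -1/+1."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.zeros(x.shape[0])
        for wl, b in zip(self.stumps, self.betas):
            out += b * (2.0 * wl(x[:, wl.marker_index]) - 1.0)
        return out

    def selected_markers(self) -> list[int]:
        seen: list[int] = []
        for wl in self.stumps:
            if wl.marker_index not in seen:
                seen.append(wl.marker_index)
        return seen

    def to_json(self) -> str:
        """Self-describing JSON in the same dialect as the boosted models."""
        import json

        doc = {
            "format": "paucboost-adaboost",
            "version": 1,
            "marker_names": self.marker_names,
            "learners": [
                {
                    "type": "stump",
                    "marker_index": wl.marker_index,
                    "split": wl.split,
                    "categories": sorted(wl.categories),
                    "orientation": wl.orientation,
                }
                for wl in self.stumps
            ],
            "betas": list(self.betas),
            "errors": list(self.errors),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AdaBoostModel":
        import json

        doc = json.loads(text)
        if doc.get("format") != "paucboost-adaboost":
            raise ValueError("not an adaboost model document")
        stumps = [
            Stump(
                marker_index=s["marker_index"],
                split=s["split"],
                categories=frozenset(s["categories"]),
                orientation=s["orientation"],
            )
            for s in doc["learners"]
        ]
        return cls(
            stumps=stumps,
            betas=list(doc["betas"]),
            errors=list(doc["errors"]),
            marker_names=doc["marker_names"],
        )


def adaboost_fit(
    data: MarkerMatrix, n_iter: int, dictionary: list[Stump] | None = None
) -> AdaBoostModel:
    """Discrete AdaBoost with stumps at all midpoints of every marker.

    Labels are recoded to -1/+1 internally.  A round with weighted error 0
    adds the perfect stump at a capped coefficient and stops; a round where
    no stump beats error 0.5 stops without adding.
    """
    data.require_both_classes()
    if dictionary is None:
        dictionary = []
        for k in range(data.n_markers):
            dictionary.extend(build_stump_dictionary(data.marker(k), marker_index=k))
    if not dictionary:
        raise ValueError("empty stump dictionary")
    y = 2.0 * data.labels - 1.0
    n = data.n_samples
    # stump predictions in -1/+1, (n, d)
    pred = np.empty((n, len(dictionary)))
    for e, wl in enumerate(dictionary):
        pred[:, e] = 2.0 * wl(data.values[:, wl.marker_index]) - 1.0
    miss = pred != y[:, None]  # (n, d)
    w = np.full(n, 1.0 / n)
    stumps, betas, errors = [], [], []
    for _ in range(n_iter):
        eps = w @ miss  # weighted error per stump
        e_best = int(np.argmin(eps))
        eps_t = float(eps[e_best])
        if eps_t >= 0.5:
            break
        beta_t = 0.5 * math.log((1.0 - eps_t) / max(eps_t, 1e-10))
        beta_t = min(beta_t, _BETA_CAP)
        stumps.append(dictionary[e_best])
        betas.append(beta_t)
        errors.append(eps_t)
        if eps_t == 0.0:
            break
        w = w * np.exp(-beta_t * y * pred[:, e_best])
        w /= w.sum()
    return AdaBoostModel(
        stumps=stumps, betas=betas, errors=errors, marker_names=list(data.marker_names)
    )


def false_discovery_pct(selected, noninformative) -> float:
    """Fraction of selected markers that are noninformative; NaN if none selected."""
    selected = list(selected)
    if not selected:
        return float("nan")
    bad = set(noninformative)
    return sum(1 for s in selected if s in bad) / len(selected)
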