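"""K-fold cross-validation over a (lambda, T) grid.

pAUC_cv(lambda, T) is the sum over folds of the held-out empirical pAUC of
the score fitted without that fold.  The T dimension is obtained by
truncating a single run at T_max per (lambda, fold) — boosting is forward
stagewise, so the truncated path equals independent shorter runs.  Folds
are stratified by class; with small case counts an unstratified split can
leave a fold without cases, making the held-out pAUC undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .boost_engine import BoostConfig, fit
from .cli_io import MarkerMatrix
from .roc_core import ScorePair, empirical_pauc

__all__ = ["CVGrid", "cv_objective", "select_parameters", "stratified_folds"]


@dataclass(frozen=True)
class CVGrid:
    """Grid of penalty weights and iteration counts, with fold layout."""

    lam_values: tuple = (0.0, 1e-6, 1e-4, 1e-2, 1.0)
    t_values: tuple = tuple(range(5, 101, 5))
    k: int = 10
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam_values", tuple(float(v) for v in self.lam_values))
        object.__setattr__(self, "t_values", tuple(int(t) for t in self.t_values))
        if self.k < 2:
            raise ValueError("need K >= 2 folds")
        if any(v < 0 for v in self.lam_values):
            raise ValueError("lambda values must be >= 0")
        if any(t < 1 for t in self.t_values):
            raise ValueError("T values must be >= 1")


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition sample indices into k folds, stratified by class."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} samples < {k} folds; data unstratifiable"
            )
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.sort(np.array(f)) for f in folds]


def _heldout_path(
    data: MarkerMatrix, train_rows: np.ndarray, test_rows: np.ndarray, cfg: BoostConfig
) -> np.ndarray:
    """Held-out score path: scores of the test rows after each iteration.

    Returns an array of shape (T_completed + 1, n_test); row t is the score
    after t boosting steps (row 0 is the zero score).
    """
    model = fit(data.subset(train_rows), cfg)
    xtest = data.values[test_rows]
    path = np.zeros((len(model.trace) + 1, xtest.shape[0]))
    for r, step in enumerate(model.trace, start=1):
        wl = model.dictionary[step.learner_index]
        col = wl(xtest[:, wl.marker_index])
        path[r] = path[r - 1] + step.beta * col
    return path


def cv_objective(data: MarkerMatrix, cfg_base: BoostConfig, grid: CVGrid) -> pd.DataFrame:
    """pAUC_cv(lambda, T) table, averaged over repeats.

    Columns: lam, T, pauc_cv (sum over the K held-out folds, averaged over
    repeated random fold assignments).
    """
    data.require_both_classes()
    t_max = max(grid.t_values)
    acc = np.zeros((len(grid.lam_values), len(grid.t_values)))
    for r in range(grid.repeats):
        rng = np.random.default_rng([grid.seed, r])
        folds = stratified_folds(data.labels, grid.k, rng)
        all_rows = np.arange(data.n_samples)
        for fold in folds:
            train_rows = np.setdiff1d(all_rows, fold)
            y_test = data.labels[fold]
            for a, lam in enumerate(grid.lam_values):
                cfg = replace(cfg_base, lam=lam, n_iter=t_max)
                path = _heldout_path(data, train_rows, fold, cfg)
                for b, t in enumerate(grid.t_values):
                    row = min(t, path.shape[0] - 1)  # guard-stopped runs stay flat
                    pair = ScorePair.from_labels(path[row], y_test)
                    acc[a, b] += empirical_pauc(pair, cfg_base.pauc)
    acc /= grid.repeats
    rows = [
        {"lam": lam, "T": t, "pauc_cv": acc[a, b]}
        for a, lam in enumerate(grid.lam_values)
        for b, t in enumerate(grid.t_values)
    ]
    return pd.DataFrame(rows)


def select_parameters(table: pd.DataFrame) -> tuple[float, int]:
    """(lambda*, T*) at the maximum of pAUC_cv; ties prefer smaller T, then larger lambda."""
    if table.empty:
        raise ValueError("empty pAUC_cv table")
    # idxmax takes the first maximum, so ordering encodes the tie preference
    ordered = table.sort_values(["T", "lam"], ascending=[True, False]).reset_index(drop=True)
    top = ordered.loc[ordered["pauc_cv"].idxmax()]
    return float(top["lam"]), int(top["T"])
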