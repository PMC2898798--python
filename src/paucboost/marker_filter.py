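"""Single-marker pAUC ranking and bootstrap selection probability.

Each marker is scored by its own raw values (trying both orientations and
keeping the better one), ranked by pAUC over the configured FPR window.
The stability of the ranking is summarized by P_g(k): the fraction of
stratified bootstrap resamples in which marker g lands in the top k.  A
strict cutoff on P_g(k) then yields a filtered marker subset to hand to
the boosting stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cli_io import MarkerMatrix
from .roc_core import PAUCConfig, ScorePair, empirical_pauc

__all__ = ["FilterReport", "rank_markers", "selection_probability", "selection_report", "apply_cutoff"]


@dataclass
class FilterReport:
    """Table-style per-marker report plus the parameters that produced it."""

    table: pd.DataFrame  # columns: rank, marker, P_g, pauc, auc, orientation
    k: int
    n_boot: int
    seed: int
    cfg: PAUCConfig


def _marker_pauc(values: np.ndarray, labels: np.ndarray, cfg: PAUCConfig) -> tuple[float, int]:
    """(pAUC, orientation) of a single marker scored by its raw values."""
    best = (-1.0, 1)
    for orient in (1, -1):
        pair = ScorePair.from_labels(orient * values, labels)
        p = empirical_pauc(pair, cfg)
        if p > best[0]:
            best = (p, orient)
    return best


def rank_markers(data: MarkerMatrix, cfg: PAUCConfig) -> pd.DataFrame:
    """Markers in descending single-marker pAUC order.

    Ties break by AUC (same orientation) and then by marker index; AUC is
    the full-window pAUC of the pAUC-optimal orientation.
    """
    data.require_both_classes()
    full = PAUCConfig(0.0, 1.0, cfg.sigma)
    rows = []
    for j in range(data.n_markers):
        pauc, orient = _marker_pauc(data.marker(j), data.labels, cfg)
        pair = ScorePair.from_labels(orient * data.marker(j), data.labels)
        auc = empirical_pauc(pair, full)
        rows.append(
            {"marker": data.marker_names[j], "index": j, "pauc": pauc, "auc": auc, "orientation": orient}
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["pauc", "auc", "index"], ascending=[False, False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def _bootstrap_top_indices(
    data: MarkerMatrix, cfg: PAUCConfig, n_boot: int, seed: int
) -> np.ndarray:
    """Marker indices ordered by rank for each bootstrap resample, (B, p).

    Resampling is with replacement within each class, preserving n0/n1 so
    the pAUC thresholds keep their meaning.
    """
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(data.labels == 0)
    idx1 = np.flatnonzero(data.labels == 1)
    out = np.empty((n_boot, data.n_markers), dtype=int)
    for b in range(n_boot):
        rows = np.concatenate(
            [rng.choice(idx0, size=idx0.size, replace=True),
             rng.choice(idx1, size=idx1.size, replace=True)]
        )
        sub = data.subset(rows)
        out[b] = rank_markers(sub, cfg)["index"].to_numpy()
    return out


def selection_probability(
    data: MarkerMatrix,
    cfg: PAUCConfig,
    k: int | list[int],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """P_g(k) per marker: bootstrap probability of ranking in the top k.

    ``k`` may be a list; the same resamples are reused for every k, which
    makes P_g(k) monotone nondecreasing in k by construction.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    ks = [k] if np.isscalar(k) else list(k)
    if any(kk > data.n_markers or kk < 1 for kk in ks):
        raise ValueError("k must be in 1..n_markers")
    order = _bootstrap_top_indices(data, cfg, n_boot, seed)
    out = pd.DataFrame({"marker": data.marker_names})
    for kk in ks:
        counts = np.zeros(data.n_markers)
        tops = order[:, :kk]
        for j in range(data.n_markers):
            counts[j] = np.count_nonzero((tops == j).any(axis=1))
        out[f"P_g({kk})"] = counts / n_boot
    return out


def selection_report(
    data: MarkerMatrix, cfg: PAUCConfig, k: int = 100, n_boot: int = 1000, seed: int = 0
) -> FilterReport:
    """Ranked marker table with P_g(k), pAUC and AUC columns."""
    k = min(k, data.n_markers)
    ranked = rank_markers(data, cfg)
    probs = selection_probability(data, cfg, k, n_boot=n_boot, seed=seed)
    merged = ranked.merge(probs, on="marker")
    merged = merged.rename(columns={f"P_g({k})": "P_g"})
    table = merged[["rank", "marker", "P_g", "pauc", "auc", "orientation"]]
    table = table.sort_values(["P_g", "pauc"], ascending=False, kind="mergesort").reset_index(drop=True)
    return FilterReport(table=table, k=k, n_boot=n_boot, seed=seed, cfg=cfg)


def apply_cutoff(report: FilterReport, threshold: float) -> list[str]:
    """Markers with P_g(k) strictly above the threshold."""
    t = report.table
    return t.loc[t["P_g"] > threshold, "marker"].tolist()
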