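import numpy as np
import pytest

from paucboost import MarkerMatrix, PAUCConfig, ScorePair


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def window():
    """The screening window used throughout: FPR in [0, 0.1]."""
    return PAUCConfig(alpha1=0.0, alpha2=0.1)


@pytest.fixture
def full_window():
    return PAUCConfig(alpha1=0.0, alpha2=1.0)


def make_pair(rng, n0=20, n1=15, shift=1.0):
    return ScorePair(rng.normal(0, 1, n0), rng.normal(shift, 1, n1))


@pytest.fixture
def toy_matrix(rng):
    """Small two-class matrix with one informative and one noise marker."""
    n0 = n1 = 25
    informative = np.concatenate([rng.normal(0, 1, n0), rng.normal(2, 1, n1)])
    noise = rng.normal(0, 1, n0 + n1)
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    return MarkerMatrix(
        values=np.column_stack([informative, noise]),
        labels=labels,
        marker_names=["good", "noise"],
        kinds=["continuous", "continuous"],
    )


def pauc_pairwise_oracle(scores0, scores1, alpha1, alpha2):
    """Brute-force empirical pAUC: explicit loops, nearest attained FPRs.

    Independent of the package implementation: enumerates attainable FPRs
    directly, resolves distance ties toward the smaller FPR, and counts
    concordant pairs one by one.
    """
    s0 = sorted(scores0)
    n0, n1 = len(scores0), len(scores1)

    def fpr_of(c, strict):
        if strict:
            return sum(1 for v in scores0 if v > c) / n0
        return sum(1 for v in scores0 if v >= c) / n0

    # candidate thresholds: each unique control value, plus "above max"
    cands = [(max(s0), True)] + [(v, False) for v in sorted(set(s0), reverse=True)]
    levels = [(fpr_of(c, st), c, st) for c, st in cands]

    def nearest(target):
        best = None
        for fpr, c, st in sorted(levels):
            d = abs(fpr - target)
            if best is None or d < best[0] - 1e-12:
                best = (d, fpr, c, st)
        return best[1], best[2], best[3]

    if alpha1 == 0.0:
        a1, c1, st1 = 0.0, max(s0), True
    else:
        a1, c1, st1 = nearest(alpha1)
    a2, c2, st2 = nearest(alpha2)
    total = 0
    for v0 in scores0:
        below_c1 = v0 <= c1 if st1 else v0 < c1
        above_c2 = v0 > c2 if st2 else v0 >= c2
        if not (below_c1 and above_c2):
            continue
        for v1 in scores1:
            if v1 >= v0:
                total += 1
    return total / (n0 * n1)
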