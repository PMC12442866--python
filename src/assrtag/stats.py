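"""Group-level inference: permutation tests, FDR, correlations, normality.

Permutation p-values use the add-one estimator (b + 1)/(m + 1), which is
valid (never anti-conservative) for any number of Monte-Carlo shuffles.
The one-sample comparison of per-subject AUCs against the 0.5 chance
level exchanges each subject's condition labels, which for a
chance-referenced AUC reduces to randomly sign-flipping the per-subject
deviations from chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

TAILS = ("one", "two")


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p: float
    n_shuffles: int
    tail: str


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str


def _p_value(null: np.ndarray, observed: float, tail: str) -> float:
    if tail == "one":
        b = int(np.sum(null >= observed))
    elif tail == "two":
        b = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    return (b + 1) / (len(null) + 1)


def perm_test_vs_chance(
    values: Sequence[float],
    chance: float = 0.5,
    tail: str = "one",
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Sign-flip permutation test of per-subject values against chance.

    Statistic: mean deviation from chance.  The null is built by randomly
    flipping the sign of each subject's deviation, i.e. exchanging that
    subject's condition labels.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    d = values - chance
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_shuffles, d.size))
    null = (signs * d).mean(axis=1)
    return PermutationResult(observed, _p_value(null, observed, tail), n_shuffles, tail)


def perm_test_groups(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two",
    n_shuffles: int = 10_000,
    paired: bool = False,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the difference in group means, x minus y.

    Unpaired: group labels are shuffled across the pooled sample.  Paired
    (within-subject contrast): each subject's pair is randomly swapped,
    equivalent to sign-flipping the paired differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    rng = np.random.default_rng(seed)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal group sizes")
        d = x - y
        # observed from the same arithmetic path as the null, so that
        # identity permutations tie with it exactly
        observed = float(d.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_shuffles, d.size))
        null = (signs * d).mean(axis=1)
    else:
        observed = float(x.mean() - y.mean())
        pooled = np.concatenate([x, y])
        nx = x.size
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            perm = rng.permutation(pooled)
            null[i] = perm[:nx].mean() - perm[nx:].mean()
    return PermutationResult(observed, _p_value(null, observed, tail), n_shuffles, tail)


def fdr_correct(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Output is order-preserving with the input, never below the raw
    p-values, and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson or Kendall tau-b correlation with a two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroDivisionError("zero variance in correlation input")
    if method == "pearson":
        res = _sps.pearsonr(x, y)
    elif method == "kendall":
        res = _sps.kendalltau(x, y, variant="b")
    else:
        raise ValueError(f"method must be 'pearson' or 'kendall', got {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size), method)


def normality_check(values: Sequence[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk statistic, p-value, and a non-normality flag (p < alpha)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("constant input has no distribution to test")
    stat, p = _sps.shapiro(values)
    return float(stat), float(p), bool(p < alpha)
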