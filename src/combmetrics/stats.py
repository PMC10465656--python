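"""Statistical comparisons between real-stimulus and control populations.

The pipeline's inference layer: an unpaired two-tailed t test (Welch by
default, pooled available) for the rim-overlap experiment, Mann-Whitney /
Wilcoxon rank tests for the divergence and proximity experiments, Spearman
rank correlation and a through-origin orientation ratio for the pair
experiment, and a paired rank test for the hybrid experiment.

Conventions worth stating once:

* The rank-sum statistic reported is the Mann-Whitney U of the *first*
  group (number of (x, y) pairs with x > y, ties counted half); under this
  min-rank convention U = 0 when every x is below every y.
* The orientation ratio compares two undirected orientations in [0, 180);
  each pair is first unwrapped to the 180-deg representation that minimizes
  its angular difference, then a least-squares slope through the origin is
  fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .geometry import norm180


class StatsError(ValueError):
    """Input unusable for the requested test."""


@dataclass
class ComparisonResult:
    """Outcome of one real-vs-control (or paired) comparison."""

    experiment: str
    metric: str
    n_real: int
    n_control: int
    mean_real: float
    sd_real: float
    mean_control: float
    sd_control: float
    test_name: str
    statistic: float
    p_value: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")

    def summary(self) -> str:
        lines = [
            f"{self.experiment} — {self.metric}",
            f"  real    n={self.n_real:<4d} mean={self.mean_real:8.3f}  sd={self.sd_real:7.3f}",
            f"  control n={self.n_control:<4d} mean={self.mean_control:8.3f}  sd={self.sd_control:7.3f}",
            f"  {self.test_name}: statistic={self.statistic:.4g}  p={self.p_value:.3g}",
        ]
        for k, v in self.extras.items():
            lines.append(f"  {k} = {v:.4g}" if isinstance(v, float) else f"  {k} = {v}")
        return "\n".join(lines)


def _describe(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def _as_array(x, name: str, min_n: int) -> np.ndarray:
    a = np.asarray(list(x), dtype=float)
    if a.ndim != 1 or len(a) < min_n:
        raise StatsError(f"{name}: need at least {min_n} values, got {len(a)}")
    if not np.all(np.isfinite(a)):
        raise StatsError(f"{name}: non-finite values present")
    return a


def t_test_unpaired(x, y, variant: str = "welch", *,
                    experiment: str = "", metric: str = "") -> ComparisonResult:
    """Two-tailed unpaired t test between two measurement populations.

    ``variant`` selects Welch (unequal variances, the default) or the
    pooled-variance Student form.  Degrees of freedom are reported in
    ``extras['df']``.
    """
    x = _as_array(x, "x", 2)
    y = _as_array(y, "y", 2)
    if variant not in ("welch", "pooled"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        raise StatsError("zero variance in both groups; t statistic undefined")
    equal_var = variant == "pooled"
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df)
    mx, sx = _describe(x)
    my, sy = _describe(y)
    return ComparisonResult(
        experiment=experiment, metric=metric,
        n_real=len(x), n_control=len(y),
        mean_real=mx, sd_real=sx, mean_control=my, sd_control=sy,
        test_name=f"t-test ({variant}, unpaired, two-tailed)",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        extras={"df": df, "variant": variant},
    )


def rank_sum_test(x, y, *, experiment: str = "", metric: str = "") -> ComparisonResult:
    """Two-sided unpaired rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups are small and tie-free,
    otherwise the normal approximation with tie correction — the behaviour of
    the R-style unpaired ``wilcox.test``.  The statistic is the U of the
    first group (min-rank convention: all x below all y gives U = 0).
    """
    x = _as_array(x, "x", 1)
    y = _as_array(y, "y", 1)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    mx, sx = _describe(x)
    my, sy = _describe(y)
    exact = (len(x) <= 8 and len(y) <= 8
             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    return ComparisonResult(
        experiment=experiment, metric=metric,
        n_real=len(x), n_control=len(y),
        mean_real=mx, sd_real=sx, mean_control=my, sd_control=sy,
        test_name="rank-sum (Mann-Whitney, two-sided)",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        extras={"method": "exact" if exact else "normal-approx"},
    )


def signed_rank_test(x, y, *, experiment: str = "", metric: str = "") -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test on matched measurements."""
    x = _as_array(x, "x", 2)
    y = _as_array(y, "y", 2)
    if len(x) != len(y):
        raise StatsError("paired test requires equal-length samples")
    d = x - y
    if np.all(d == 0.0):
        raise StatsError("all paired differences are zero")
    res = sps.wilcoxon(x, y, alternative="two-sided")
    mx, sx = _describe(x)
    my, sy = _describe(y)
    return ComparisonResult(
        experiment=experiment, metric=metric,
        n_real=len(x), n_control=len(y),
        mean_real=mx, sd_real=sx, mean_control=my, sd_control=sy,
        test_name="signed-rank (Wilcoxon, paired, two-sided)",
        statistic=float(res.statistic), p_value=float(res.pvalue),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = _as_array(x, "x", 3)
    y = _as_array(y, "y", 3)
    if len(x) != len(y):
        raise StatsError("spearman requires paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant input: ranks undefined")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def unwrap_orientation_pairs(built, predicted) -> tuple[np.ndarray, np.ndarray]:
    """Unwrap each (built, predicted) orientation pair for regression.

    Both inputs are undirected orientations; each built value is moved by
    a multiple of 180 deg to the representative closest to its predicted
    partner, so that e.g. (2 deg, 178 deg) regresses as (182, 178) rather
    than as a 176-deg disagreement.
    """
    b = np.array([norm180(v) for v in np.asarray(built, dtype=float)])
    t = np.array([norm180(v) for v in np.asarray(predicted, dtype=float)])
    shift = np.round((t - b) / 180.0) * 180.0
    return b + shift, t


def orientation_ratio(built, predicted) -> float:
    """Least-squares slope through the origin of built vs predicted orientation.

    A ratio of 1 means built walls track the predicted guide orientation
    one-for-one.  Pairs are unwrapped (mod 180) before the fit.
    """
    b, t = unwrap_orientation_pairs(built, predicted)
    denom = float(np.dot(t, t))
    if denom == 0.0:
        raise StatsError("all predicted orientations are zero; slope undefined")
    return float(np.dot(t, b) / denom)


__all__ = [
    "StatsError", "ComparisonResult", "t_test_unpaired", "rank_sum_test",
    "signed_rank_test", "spearman", "unwrap_orientation_pairs",
    "orientation_ratio",
]
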