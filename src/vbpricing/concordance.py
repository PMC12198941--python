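"""Concordance between estimated value-based prices and real prices.

Across a cohort, each device for which the algorithm produced a price
contributes one (real price, VBP) pair. Agreement is summarised by
Pearson's product-moment correlation with a Fisher z-transform confidence
interval, a two-sided t-test of the null r = 0, and the ordinary
least-squares line of VBP (y) on real price (x).

The Fisher interval is ``tanh(arctanh(r) -+ z_crit / sqrt(n - 3))``; the
significance test refers ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` to a
Student t distribution with n - 2 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import CohortResult
from .errors import InsufficientDataError, ZeroVarianceError
from .model import Cohort

__all__ = [
    "ConcordanceResult",
    "pair_for_concordance",
    "pearson_r",
    "fisher_ci",
    "correlation_p_value",
    "ols_fit",
    "analyse_concordance",
]

#: fewer priced devices than this and the analysis is refused outright
MIN_PAIRS = 3


@dataclass
class ConcordanceResult:
    """Summary of the VBP-vs-real-price agreement over n priced devices."""

    n: int
    r: float
    ci_low: float
    ci_high: float
    ci_level: float
    p_value: float
    slope: float
    intercept: float

    def as_dict(self) -> dict:
        return {"n": self.n, "r": self.r, "r_squared": self.r ** 2,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "ci_level": self.ci_level, "p_value": self.p_value,
                "slope": self.slope, "intercept": self.intercept}


def pair_for_concordance(cohort_result: CohortResult,
                         cohort: Cohort) -> list[tuple[float, float]]:
    """(real price, VBP) pairs for the priced devices, in input order.

    Includes exactly the devices whose status is priced (computed or
    external-CEA); every failure is excluded. Raises
    :class:`InsufficientDataError` below 3 pairs.
    """
    prices = {rec.code: rec.costs.device_price for rec in cohort.records}
    pairs = []
    for res in cohort_result.results:
        if res.status.priced:
            if res.code not in prices:
                raise KeyError(f"result code {res.code!r} not present in the cohort")
            pairs.append((prices[res.code], res.vbp))
    if len(pairs) < MIN_PAIRS:
        raise InsufficientDataError(
            f"concordance needs at least {MIN_PAIRS} priced devices, got {len(pairs)}")
    return pairs


def _split(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (x, y) tuples")
    return arr[:, 0], arr[:, 1]


def pearson_r(pairs) -> float:
    """Pearson product-moment correlation of (x, y) pairs."""
    x, y = _split(pairs)
    if len(x) < 2:
        raise InsufficientDataError("correlation needs at least 2 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: a coordinate is constant")
    return float(stats.pearsonr(x, y).statistic)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a correlation coefficient.

    ``z = arctanh(r)`` is treated as normal with standard error
    ``1/sqrt(n - 3)``; the bounds are mapped back through ``tanh``.
    A degenerate ``|r| = 1`` returns ``(r, r)`` with a warning.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if abs(r) > 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        warnings.warn("degenerate |r| = 1: returning a zero-width interval",
                      stacklevel=2)
        return (r, r)
    if n < 4:
        raise InsufficientDataError(f"Fisher interval needs n >= 4, got {n}")
    z = math.atanh(r)
    half_width = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half_width), math.tanh(z + half_width))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for H0: r = 0, via the t-test with n - 2 df."""
    if abs(r) > 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if n < MIN_PAIRS:
        raise InsufficientDataError(f"p-value needs n >= {MIN_PAIRS}, got {n}")
    if abs(r) == 1.0:
        warnings.warn("degenerate |r| = 1: p-value is 0", stacklevel=2)
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def ols_fit(pairs) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    x, y = _split(pairs)
    if len(x) < 2:
        raise InsufficientDataError("regression needs at least 2 pairs")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("regression undefined: x is constant")
    fit = stats.linregress(x, y)
    return (float(fit.slope), float(fit.intercept))


def analyse_concordance(pairs, level: float = 0.95) -> ConcordanceResult:
    """Full concordance summary of (real price, VBP) pairs."""
    if len(pairs) < MIN_PAIRS:
        raise InsufficientDataError(
            f"concordance needs at least {MIN_PAIRS} pairs, got {len(pairs)}")
    r = pearson_r(pairs)
    if abs(r) == 1.0:
        ci_low = ci_high = r
        p = 0.0
        warnings.warn("perfect correlation: degenerate interval and p = 0",
                      stacklevel=2)
    else:
        ci_low, ci_high = fisher_ci(r, len(pairs), level)
        p = correlation_p_value(r, len(pairs))
    slope, intercept = ols_fit(pairs)
    return ConcordanceResult(n=len(pairs), r=r, ci_low=ci_low, ci_high=ci_high,
                             ci_level=level, p_value=p, slope=slope,
                             intercept=intercept)


def scatter_plot(pairs, result: ConcordanceResult, path) -> None:
    """Save a VBP-vs-real-price scatter with the fitted regression line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _split(pairs)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, y, color="tab:blue", zorder=3)
    grid = np.linspace(0.0, float(x.max()) * 1.05, 50)
    ax.plot(grid, result.slope * grid + result.intercept, color="tab:red",
            label=f"y = {result.slope:.4f}x {result.intercept:+.4f}")
    ax.set_xlabel("Real price (EUR/patient)")
    ax.set_ylabel("Value-based price (EUR/patient)")
    ax.set_title(f"n = {result.n}, r = {result.r:.3f} "
                 f"({result.ci_level:.0%} CI {result.ci_low:.4f}-{result.ci_high:.4f})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
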