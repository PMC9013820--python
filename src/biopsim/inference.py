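"""Inferential toolkit backing the workflow analysis.

Four pieces of statistics recur in the capacity study and are collected
here: a chi-square goodness-of-fit test for binned counts, an
Anderson-Darling normality acceptance check, the paired confidence
interval used to validate a simulation model against observed throughput,
and exact noncentral-t power / minimal sample size for a one-sample
two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "GofResult",
    "NormalityResult",
    "ValidationResult",
    "PowerQuery",
    "chi_square_gof",
    "chi_square_normal_gof",
    "normality_check",
    "validation_interval",
    "power_one_sample_t",
    "sample_size_one_sample_t",
]


@dataclass(frozen=True)
class GofResult:
    chi2: float
    k: int
    v: int  # degrees of freedom, k - 1
    p: float
    observed: np.ndarray
    expected: np.ndarray


@dataclass(frozen=True)
class NormalityResult:
    A2: float
    p: float
    alpha: float
    accepted: bool  # p > alpha


@dataclass(frozen=True)
class ValidationResult:
    X_bar: float
    Y_bar: float
    var_diff: float
    t_quantile: float
    interval: tuple[float, float]
    contains_zero: bool
    alpha: float


@dataclass(frozen=True)
class PowerQuery:
    """Detectable difference ``delta`` at standard deviation ``sd`` (minutes)."""

    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.95

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.sd <= 0:
            raise ValueError("delta and sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0,1)")


def chi_square_gof(observed, expected) -> GofResult:
    """Pearson chi-square statistic ``sum (o_i - e_i)^2 / e_i`` over k cells.

    Degrees of freedom are k - 1 (no parameters adjusted here; callers
    fitting parameters before binning should interpret p accordingly).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.ndim != 1:
        raise ValueError("observed and expected must be 1-D of equal length")
    if o.size < 2:
        raise ValueError("need at least 2 cells")
    if np.any(e <= 0):
        raise ValueError("expected counts must all be > 0")
    chi2 = float(np.sum((o - e) ** 2 / e))
    v = o.size - 1
    return GofResult(chi2=chi2, k=o.size, v=v, p=float(stats.chi2.sf(chi2, v)), observed=o, expected=e)


def chi_square_normal_gof(samples, k: int | None = None) -> GofResult:
    """Chi-square GOF of a continuous sample against a fitted normal.

    Bins are equal-probability under the fitted N(mean, sd), with
    ``k = max(2, min(20, n // 5))`` by default so every expected count is
    at least 5.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for a binned GOF")
    if k is None:
        k = max(2, min(20, n // 5))
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("sample is constant; GOF against a normal is undefined")
    edges = stats.norm.ppf(np.linspace(0, 1, k + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(x, bins=np.concatenate(([-np.inf], edges[1:-1], [np.inf])))
    expected = np.full(k, n / k)
    return chi_square_gof(observed, expected)


def normality_check(samples, alpha: float = 0.05) -> NormalityResult:
    """Anderson-Darling test against a normal with estimated parameters.

    ``accepted`` is True when p > alpha, i.e. normality is not rejected.
    Needs at least 8 observations and a non-constant sample.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise ValueError(f"need at least 8 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; the normality statistic is undefined")
    a2, p = normal_ad(x)
    return NormalityResult(A2=float(a2), p=float(p), alpha=alpha, accepted=bool(p > alpha))


def validation_interval(X, Y, alpha: float = 0.05) -> ValidationResult:
    """Paired confidence interval for the mean difference of real vs simulated.

    With nu paired periods the interval is
    ``(Xbar - Ybar) -/+ t_{nu-1, 1-alpha} * sqrt(var(d)/nu)`` where d are the
    paired differences.  The model is considered consistent with the real
    system when the interval contains zero.
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("X and Y must be 1-D of equal length (paired by period)")
    nu = x.size
    if nu < 2:
        raise ValueError("need at least 2 paired periods")
    d = x - y
    var_diff = float(d.var(ddof=1) / nu)
    tq = float(stats.t.ppf(1 - alpha, nu - 1))
    center = float(d.mean())
    half = tq * np.sqrt(var_diff)
    lo, hi = center - half, center + half
    return ValidationResult(
        X_bar=float(x.mean()),
        Y_bar=float(y.mean()),
        var_diff=var_diff,
        t_quantile=tq,
        interval=(lo, hi),
        contains_zero=bool(lo <= 0.0 <= hi),
        alpha=alpha,
    )


def power_one_sample_t(n: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided one-sample t-test at sample size ``n``.

    Uses the noncentral-t distribution with noncentrality
    ``delta / sd * sqrt(n)`` — no normal approximation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    tc = stats.t.ppf(1 - alpha / 2, df)
    nc = delta / sd * np.sqrt(n)
    return float(1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))


def sample_size_one_sample_t(q: PowerQuery, n_max: int = 10**6) -> int:
    """Smallest n whose exact noncentral-t power reaches ``q.power``."""
    n = 2
    while n <= n_max:
        if power_one_sample_t(n, q.delta, q.sd, q.alpha) >= q.power:
            return n
        n += 1
    raise ValueError(f"target power {q.power} not reachable within n <= {n_max}")
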