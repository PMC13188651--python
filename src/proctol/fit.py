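"""Candidate time distributions and goodness-of-fit scoring.

Fits two-parameter log-normal and Weibull models to positive procedure
times, scores adequacy with the Shapiro-Wilk test (on log times for the
log-normal hypothesis, raw times for the normal hypothesis) and a Pearson
chi-square test on equal-probability bins, and emits probability-plot
coordinates for visual assessment.

The Shapiro-Wilk statistic and p-value are computed from Royston's
published AS R94 approximation (valid for 3 <= n <= 5000) so the numbers
are fully specified by this module rather than delegated; a reference
implementation serves as a cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FitError",
    "LogNormalParams",
    "WeibullParams",
    "FitTestResult",
    "FitReport",
    "fit_lognormal",
    "fit_weibull",
    "shapiro_wilk",
    "pearson_chisq_gof",
    "probability_plot_coords",
    "shapiro_power_sim",
    "compare_distributions",
]


class FitError(ValueError):
    """Fitting or test preconditions violated."""


@dataclass(frozen=True)
class LogNormalParams:
    """Two-parameter log-normal on the log scale: log-time ~ N(mu, sigma^2)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise FitError(f"sigma must be > 0, got {self.sigma}")

    @property
    def median(self) -> float:
        """Median of the time distribution, exp(mu)."""
        return math.exp(self.mu)

    @property
    def cv(self) -> float:
        """Coefficient of variation, sqrt(exp(sigma^2) - 1)."""
        return math.sqrt(math.expm1(self.sigma**2))


@dataclass(frozen=True)
class WeibullParams:
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise FitError("Weibull shape and scale must be > 0")


@dataclass(frozen=True)
class FitTestResult:
    """One goodness-of-fit test outcome.

    ``transform`` records whether the test ran on raw values ("identity")
    or log values ("log"); ``df`` is None for the Shapiro-Wilk test.
    """

    test_name: str
    statistic: float
    p_value: float
    df: int | None = None
    transform: str = "identity"


@dataclass(frozen=True)
class FitReport:
    """Per-distribution fit entries on one value collection, plus a winner.

    ``entries`` maps distribution label -> (params, tuple of FitTestResult).
    The winner is the distribution with the highest Shapiro-Wilk p-value on
    its matching transform, chi-square p as tiebreaker; purely a reporting
    convenience.
    """

    n: int
    entries: dict
    winner: str


def _positive(times) -> np.ndarray:
    x = np.asarray(times, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise FitError("all times must be positive and finite")
    return x


def fit_lognormal(times) -> LogNormalParams:
    """Log-normal fit: mu = mean of logs, sigma = SD of logs (n-1 denominator).

    The n-1 denominator matches the pivotal exceedance inference, which
    consumes these same sufficient statistics.
    """
    x = _positive(times)
    if x.size < 2:
        raise FitError("need at least 2 values")
    logs = np.log(x)
    sigma = float(np.std(logs, ddof=1))
    if sigma == 0.0:
        raise FitError("degenerate sample: all values equal (sigma = 0)")
    return LogNormalParams(mu=float(np.mean(logs)), sigma=sigma)


def fit_weibull(times, tol: float = 1e-10, max_expand: int = 60) -> WeibullParams:
    """Weibull maximum likelihood via the one-dimensional profile score.

    The shape k solves  sum(x^k ln x)/sum(x^k) - 1/k - mean(ln x) = 0,
    a monotone-in-k equation solved by bracketed root finding; the scale
    is then (mean(x^k))^(1/k) in closed form.
    """
    x = _positive(times)
    if x.size < 2:
        raise FitError("need at least 2 values")
    logs = np.log(x)
    if np.ptp(x) == 0:
        raise FitError("degenerate sample: all values equal")
    mean_log = logs.mean()
    # Work with scaled data for numerical stability; shape is scale-free.
    xs = x / np.exp(mean_log)
    logs_s = np.log(xs)

    def score(k: float) -> float:
        w = xs**k
        return float(np.sum(w * logs_s) / np.sum(w) - 1.0 / k)

    lo, hi = 1e-3, 2.0
    n_expand = 0
    while score(hi) < 0:
        hi *= 2.0
        n_expand += 1
        if n_expand > max_expand:
            raise FitError("Weibull shape root not bracketed (score < 0 at huge k)")
    while score(lo) > 0:
        lo /= 2.0
        n_expand += 1
        if n_expand > max_expand:
            raise FitError("Weibull shape root not bracketed (score > 0 at tiny k)")
    shape = float(optimize.brentq(score, lo, hi, xtol=tol, rtol=8.9e-16))
    scale = float(np.mean(x**shape) ** (1.0 / shape))
    return WeibullParams(shape=shape, scale=scale)


# ---------------------------------------------------------------------------
# Shapiro-Wilk, Royston (1995) AS R94 approximation.

def _sw_coefficients(n: int) -> np.ndarray:
    """Weights a_i for the ordered sample (full length-n vector, antisymmetric)."""
    i = np.arange(1, n + 1)
    m = special.ndtri((i - 0.375) / (n + 0.25))
    mm = float(m @ m)
    a = np.empty(n)
    if n == 3:
        a[:] = (-math.sqrt(0.5), 0.0, math.sqrt(0.5))
        return a
    u = 1.0 / math.sqrt(n)
    c = m / math.sqrt(mm)
    a_n = (
        c[-1]
        + 0.221157 * u
        - 0.147981 * u**2
        - 2.071190 * u**3
        + 4.434685 * u**4
        - 2.706056 * u**5
    )
    if n <= 5:
        phi = (mm - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * a_n**2)
        a[1:-1] = m[1:-1] / math.sqrt(phi)
        a[-1] = a_n
        a[0] = -a_n
    else:
        a_n1 = (
            c[-2]
            + 0.042981 * u
            - 0.293762 * u**2
            - 1.752461 * u**3
            + 5.682633 * u**4
            - 3.582633 * u**5
        )
        phi = (mm - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2) / (
            1.0 - 2.0 * a_n**2 - 2.0 * a_n1**2
        )
        a[2:-2] = m[2:-2] / math.sqrt(phi)
        a[-1], a[-2] = a_n, a_n1
        a[0], a[1] = -a_n, -a_n1
    return a


def _sw_pvalue(w: float, n: int) -> float:
    if n == 3:
        # Exact small-sample distribution of W for n = 3.
        p = 6.0 / math.pi * (math.asin(math.sqrt(w)) - math.asin(math.sqrt(0.75)))
        return min(max(p, 0.0), 1.0)
    one_minus_w = max(1.0 - w, 1e-300)
    if n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        arg = g - math.log(one_minus_w)
        if arg <= 0:
            return 0.0
        z = (-math.log(arg) - mu) / sigma
    else:
        ln_n = math.log(n)
        mu = -1.5861 - 0.31082 * ln_n - 0.083751 * ln_n**2 + 0.0038915 * ln_n**3
        sigma = math.exp(-0.4803 - 0.082676 * ln_n + 0.0030302 * ln_n**2)
        z = (math.log(one_minus_w) - mu) / sigma
    return float(special.ndtr(-z))


def shapiro_wilk(values, transform: str = "identity") -> FitTestResult:
    """Shapiro-Wilk normality test, AS R94 approximation (3 <= n <= 5000).

    W is the squared correlation between the ordered sample and the
    approximately optimal normal-scores weights; small W means poor fit.
    Pass ``transform="log"`` as a label when the caller supplies log
    values (the values themselves are tested as given).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if not 3 <= n <= 5000:
        raise FitError(f"Shapiro-Wilk approximation requires 3 <= n <= 5000, got {n}")
    ss = float(np.sum((x - x.mean()) ** 2))
    if ss == 0.0:
        raise FitError("degenerate sample: zero variance")
    a = _sw_coefficients(n)
    w = float((a @ x) ** 2 / ss)
    w = min(w, 1.0)
    return FitTestResult(
        test_name="shapiro_wilk",
        statistic=w,
        p_value=_sw_pvalue(w, n),
        df=None,
        transform=transform,
    )


# ---------------------------------------------------------------------------
# Pearson chi-square on equal-probability bins.

_N_FITTED = {"lognormal": 2, "normal": 2, "weibull": 2}


def _dist(label: str, params) -> stats.rv_continuous:
    if label == "lognormal":
        return stats.lognorm(s=params.sigma, scale=math.exp(params.mu))
    if label == "normal":
        return stats.norm(loc=params[0], scale=params[1])
    if label == "weibull":
        return stats.weibull_min(c=params.shape, scale=params.scale)
    raise FitError(f"unknown distribution label {label!r}")


def auto_bins(n: int) -> int:
    """Default equal-probability bin count: max(4, min(10, n // 5))."""
    return max(4, min(10, n // 5))


def pearson_chisq_gof(
    values, distribution: str, params, n_bins: int | str = "auto"
) -> FitTestResult:
    """Pearson chi-square goodness of fit on equal-probability bins.

    Bin edges are the fitted distribution's quantiles at j/k, so every
    expected count is exactly n/k; df = k - 1 - (number of fitted
    parameters).  Requires n >= 20 under automatic binning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n_bins == "auto":
        if n < 20:
            raise FitError("automatic binning requires n >= 20")
        k = auto_bins(n)
    else:
        k = int(n_bins)
        if k < 2:
            raise FitError("need at least 2 bins")
    expected = n / k
    if expected < 1.0:
        raise FitError(
            f"expected count {expected:.3g} < 1 per bin; use fewer bins"
        )
    dist = _dist(distribution, params)
    edges = dist.ppf(np.arange(1, k) / k)
    observed = np.bincount(np.searchsorted(edges, x, side="right"), minlength=k)
    statistic = float(np.sum((observed - expected) ** 2) / expected)
    df = k - 1 - _N_FITTED[distribution]
    if df < 1:
        raise FitError(f"non-positive degrees of freedom (k={k})")
    return FitTestResult(
        test_name="pearson_chisq",
        statistic=statistic,
        p_value=float(stats.chi2.sf(statistic, df)),
        df=df,
        transform="identity",
    )


def probability_plot_coords(
    values, distribution: str, params
) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical quantile, ordered value) pairs for a probability plot.

    Plotting positions are Blom's (i - 0.375)/(n + 0.25).  A straight-line
    plot indicates a good fit; rendering is left to the caller.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        raise FitError("need at least 3 values")
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theoretical = _dist(distribution, params).ppf(p)
    return theoretical, x


def shapiro_power_sim(
    alternative: Callable[[np.random.Generator, int], np.ndarray],
    n: int,
    alpha: float,
    n_sims: int,
    seed: int,
) -> tuple[float, float]:
    """Monte Carlo power of the Shapiro-Wilk test against an alternative.

    ``alternative(rng, n)`` draws one sample of size n; the returned pair is
    (rejection proportion at ``alpha``, binomial standard error).
    """
    if n < 3:
        raise FitError("n must be >= 3")
    if n_sims < 100:
        raise FitError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        sample = alternative(rng, n)
        if shapiro_wilk(sample).p_value < alpha:
            rejections += 1
    power = rejections / n_sims
    se = math.sqrt(power * (1.0 - power) / n_sims)
    return power, se


def compare_distributions(
    times,
    distributions: Sequence[str] = ("lognormal", "normal", "weibull"),
    n_bins: int | str = "auto",
) -> FitReport:
    """Fit each candidate distribution and score it.

    Log-normal: Shapiro-Wilk on log times + chi-square.  Normal:
    Shapiro-Wilk on raw times + chi-square.  Weibull: chi-square only
    (no Shapiro-Wilk analogue).  Winner = highest Shapiro-Wilk p on the
    matching transform, chi-square p as tiebreaker.
    """
    x = _positive(times)
    entries: dict = {}
    for label in distributions:
        if label == "lognormal":
            params = fit_lognormal(x)
            tests = (
                shapiro_wilk(np.log(x), transform="log"),
                pearson_chisq_gof(x, "lognormal", params, n_bins),
            )
        elif label == "normal":
            params = (float(np.mean(x)), float(np.std(x, ddof=1)))
            tests = (
                shapiro_wilk(x, transform="identity"),
                pearson_chisq_gof(x, "normal", params, n_bins),
            )
        elif label == "weibull":
            params = fit_weibull(x)
            tests = (pearson_chisq_gof(x, "weibull", params, n_bins),)
        else:
            raise FitError(f"unknown distribution label {label!r}")
        entries[label] = (params, tests)

    def sort_key(label: str) -> tuple[float, float]:
        _, tests = entries[label]
        sw = next((t.p_value for t in tests if t.test_name == "shapiro_wilk"), -1.0)
        chi = next((t.p_value for t in tests if t.test_name == "pearson_chisq"), -1.0)
        return (sw, chi)

    winner = max(entries, key=sort_key)
    return FitReport(n=int(x.size), entries=entries, winner=winner)
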