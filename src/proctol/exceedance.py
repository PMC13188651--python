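"""Confidence limits on tolerance-limit exceedance probabilities.

Under a log-normal time model with log-scale parameters (mu, sigma), the
probability that a procedure time exceeds a tolerance limit L minutes is

    p(L) = 1 - Phi((ln L - mu) / sigma).

This module provides three routes to an upper confidence limit on p(L):

* a generalized pivotal quantity (GPQ) Monte Carlo, the primary method:
  each replicate draws sigma_r = s * sqrt((n-1)/U_r) with U_r ~ chi2(n-1)
  and mu_r = xbar - Z_r * sigma_r / sqrt(n) with Z_r ~ N(0,1), evaluates
  p_r = 1 - Phi((ln L - mu_r)/sigma_r), and the upper limit is the
  empirical level-quantile of {p_r};
* the exact noncentral-t construction (the classical route to one-sided
  normal tolerance bounds), used as a deterministic validation oracle;
* the exact Clopper-Pearson binomial bound from the exceedance count,
  which uses only whether each time exceeded L, not the observed times.

All parametric inference runs on the log scale from the sufficient
statistics (xbar, s, n) of the log times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .fit import LogNormalParams
from .simulate import generate_time_sample

__all__ = [
    "ExceedanceError",
    "LogSampleSummary",
    "ExceedanceQuery",
    "ExceedanceEstimate",
    "log_summary",
    "plug_in_exceedance",
    "gpq_exceedance_upper",
    "exceedance_upper_noncentral_t",
    "clopper_pearson_upper",
    "coverage_simulation",
]

MIN_REPLICATIONS = 10_000
_BLOCK = 262_144


class ExceedanceError(ValueError):
    """Invalid exceedance query or summary."""


@dataclass(frozen=True)
class LogSampleSummary:
    """Sufficient statistics of the log times: mean, SD (n-1 denominator), n."""

    xbar: float
    s: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ExceedanceError(f"need n >= 2, got {self.n}")
        if not self.s > 0:
            raise ExceedanceError(f"need s > 0, got {self.s}")


@dataclass(frozen=True)
class ExceedanceQuery:
    """One exceedance question: tolerance L, confidence level, Monte Carlo sizing."""

    tolerance_L: float
    level: float = 0.95
    replications_R: int = 2_999_999
    seed: int = 0
    batches_B: int = 100

    def __post_init__(self) -> None:
        if not self.tolerance_L > 0:
            raise ExceedanceError("tolerance_L must be > 0")
        if not 0 < self.level < 1:
            raise ExceedanceError("level must lie in (0, 1)")
        if self.replications_R < MIN_REPLICATIONS:
            raise ExceedanceError(
                f"replications_R must be >= {MIN_REPLICATIONS} for a reported SE"
            )
        if self.batches_B < 2:
            raise ExceedanceError("batches_B must be >= 2")


@dataclass(frozen=True)
class ExceedanceEstimate:
    """Point estimate and upper confidence limit for P(time > L).

    ``point_estimate`` is the plug-in value; ``mc_se`` is the Monte Carlo
    standard error of the upper limit (None for exact methods).
    """

    point_estimate: float
    upper_limit: float
    mc_se: float | None
    method: str
    tolerance_L: float
    level: float


def log_summary(times) -> LogSampleSummary:
    """Compute the log-scale sufficient statistics from raw times."""
    x = np.asarray(times, dtype=float)
    if np.any(x <= 0):
        raise ExceedanceError("times must be positive")
    logs = np.log(x)
    return LogSampleSummary(
        xbar=float(np.mean(logs)), s=float(np.std(logs, ddof=1)), n=int(x.size)
    )


def _mu_sigma(params) -> tuple[float, float]:
    if isinstance(params, LogSampleSummary):
        return params.xbar, params.s
    if isinstance(params, LogNormalParams):
        return params.mu, params.sigma
    raise ExceedanceError(
        "params must be LogNormalParams or LogSampleSummary, got "
        f"{type(params).__name__}"
    )


def plug_in_exceedance(params, tolerance_L: float) -> float:
    """Plug-in exceedance probability 1 - Phi((ln L - mu)/sigma)."""
    if not tolerance_L > 0:
        raise ExceedanceError("tolerance_L must be > 0")
    mu, sigma = _mu_sigma(params)
    if not sigma > 0:
        raise ExceedanceError("sigma must be > 0")
    return float(special.ndtr((mu - math.log(tolerance_L)) / sigma))


def _order_stat_quantile(values: np.ndarray, level: float) -> float:
    """Nearest-order-statistic quantile: the ceil(level * R)-th smallest value."""
    r = values.size
    k = min(max(int(math.ceil(level * r)), 1), r)
    return float(np.partition(values, k - 1)[k - 1])


def gpq_exceedance_upper(
    summary: LogSampleSummary, query: ExceedanceQuery
) -> ExceedanceEstimate:
    """Generalized-pivotal Monte Carlo upper confidence limit on P(time > L).

    Replicates are computed in fixed-size blocks from two sequential
    sub-streams (one for the chi-square draws, one for the normal draws),
    so the result is identical for any block size given the seed.  The
    upper limit is the nearest-order-statistic ``level``-quantile of the
    replicate exceedance probabilities; its Monte Carlo standard error is
    the SD of ``batches_B`` contiguous batch quantiles divided by
    sqrt(batches_B).
    """
    ln_l = math.log(query.tolerance_L)
    n = summary.n
    df = n - 1
    sqrt_n = math.sqrt(n)
    r_total = query.replications_R

    ss = np.random.SeedSequence(query.seed)
    chi2_rng, z_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    p_all = np.empty(r_total)
    done = 0
    while done < r_total:
        k = min(_BLOCK, r_total - done)
        u = chi2_rng.chisquare(df, size=k)
        sigma_r = summary.s * np.sqrt(df / u)
        z = z_rng.standard_normal(k)
        mu_r = summary.xbar - z * sigma_r / sqrt_n
        p_all[done : done + k] = special.ndtr((mu_r - ln_l) / sigma_r)
        done += k

    upper = _order_stat_quantile(p_all, query.level)
    batches = np.array_split(p_all, query.batches_B)
    batch_q = np.array([_order_stat_quantile(b, query.level) for b in batches])
    mc_se = float(np.std(batch_q, ddof=1) / math.sqrt(query.batches_B))
    return ExceedanceEstimate(
        point_estimate=plug_in_exceedance(summary, query.tolerance_L),
        upper_limit=upper,
        mc_se=mc_se,
        method="gpq",
        tolerance_L=query.tolerance_L,
        level=query.level,
    )


def exceedance_upper_noncentral_t(
    summary: LogSampleSummary,
    tolerance_L: float,
    level: float = 0.95,
    tol: float = 1e-10,
    max_expand: int = 60,
) -> ExceedanceEstimate:
    """Exact upper confidence limit via the noncentral-t construction.

    With k_hat = (ln L - xbar)/s, the limit is 1 - Phi(k_L) where k_L
    solves  F_nct(sqrt(n) * k_hat; df = n-1, nc = sqrt(n) * k_L) = level,
    found by bracketed root-finding.  This is the classical one-sided
    normal tolerance bound; it carries no Monte Carlo error and serves as
    the deterministic oracle for the GPQ Monte Carlo.
    """
    if not tolerance_L > 0:
        raise ExceedanceError("tolerance_L must be > 0")
    if not 0 < level < 1:
        raise ExceedanceError("level must lie in (0, 1)")
    n = summary.n
    sqrt_n = math.sqrt(n)
    k_hat = (math.log(tolerance_L) - summary.xbar) / summary.s
    t_obs = sqrt_n * k_hat

    def objective(k_l: float) -> float:
        return float(stats.nct.cdf(t_obs, df=n - 1, nc=sqrt_n * k_l)) - level

    # F_nct is decreasing in the noncentrality, so the objective is
    # decreasing in k_l; expand a bracket around k_hat.
    half_width = 1.0
    lo, hi = k_hat - half_width, k_hat + half_width
    n_expand = 0
    while objective(lo) < 0:
        half_width *= 2.0
        lo = k_hat - half_width
        n_expand += 1
        if n_expand > max_expand:
            raise ExceedanceError("noncentral-t root not bracketed (low side)")
    while objective(hi) > 0:
        half_width *= 2.0
        hi = k_hat + half_width
        n_expand += 1
        if n_expand > max_expand:
            raise ExceedanceError("noncentral-t root not bracketed (high side)")
    k_l = float(optimize.brentq(objective, lo, hi, xtol=tol))
    return ExceedanceEstimate(
        point_estimate=plug_in_exceedance(summary, tolerance_L),
        upper_limit=float(special.ndtr(-k_l)),
        mc_se=None,
        method="noncentral_t",
        tolerance_L=tolerance_L,
        level=level,
    )


def clopper_pearson_upper(x: int, n: int, alpha: float = 0.05) -> float:
    """Exact one-sided upper (1 - alpha) Clopper-Pearson limit for a proportion.

    Beta-quantile formulation: Beta(x + 1, n - x) upper quantile; for
    x = 0 this is 1 - alpha**(1/n), and for x = n it is 1.
    """
    if not (0 <= x <= n and n >= 1):
        raise ExceedanceError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0 < alpha < 1:
        raise ExceedanceError("alpha must lie in (0, 1)")
    if x == n:
        return 1.0
    if x == 0:
        return 1.0 - alpha ** (1.0 / n)
    return float(stats.beta.ppf(1.0 - alpha, x + 1, n - x))


def coverage_simulation(
    true_params: LogNormalParams,
    n: int,
    tolerance_L: float,
    level: float,
    n_cohorts: int,
    replications_per_cohort: int,
    seed: int,
) -> tuple[float, float]:
    """Empirical coverage of the GPQ upper limit under a known log-normal truth.

    Simulates ``n_cohorts`` samples of size n from the true distribution,
    computes the GPQ upper limit for each, and returns the fraction whose
    limit is at or above the true exceedance probability, with its
    binomial standard error.
    """
    if n_cohorts < 200:
        raise ExceedanceError("n_cohorts must be >= 200")
    true_p = 1.0 - float(
        special.ndtr((math.log(tolerance_L) - true_params.mu) / true_params.sigma)
    )
    ss = np.random.SeedSequence(seed)
    sample_rng = np.random.default_rng(ss.spawn(1)[0])
    gpq_seeds = ss.generate_state(n_cohorts)
    covered = 0
    for i in range(n_cohorts):
        times = generate_time_sample(n, true_params.mu, true_params.sigma, sample_rng)
        summary = log_summary(times)
        estimate = gpq_exceedance_upper(
            summary,
            ExceedanceQuery(
                tolerance_L=tolerance_L,
                level=level,
                replications_R=replications_per_cohort,
                seed=int(gpq_seeds[i]),
                batches_B=10,
            ),
        )
        if estimate.upper_limit >= true_p:
            covered += 1
    coverage = covered / n_cohorts
    se = math.sqrt(coverage * (1.0 - coverage) / n_cohorts)
    return coverage, se
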