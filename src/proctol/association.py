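"""Rank association between prior experience and procedure time.

Kendall's tau_b (tie-corrected) and Spearman's rho (midranks), with
permutation p-values: exhaustive enumeration of all n! relabelings for
small samples, otherwise a seeded Monte Carlo with the add-one estimator
p_hat = (1 + #{|T*| >= |T_obs|}) / (M + 1), which can never return zero
and is valid by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "AssociationError",
    "AssociationResult",
    "kendall_tau_b",
    "spearman_rho",
    "permutation_pvalue",
]

#: Largest n for which the exhaustive permutation mode runs by default.
EXHAUSTIVE_MAX_N = 7
_TIE_SLACK = 1e-12


class AssociationError(ValueError):
    """Invalid association inputs (length mismatch, degenerate ranks, ...)."""


@dataclass(frozen=True)
class AssociationResult:
    statistic_name: str
    estimate: float
    p_value: float
    n_permutations_M: int | None = None
    seed: int | None = None
    method: str = "analytic"


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise AssociationError("x and y must be equal-length 1-D collections")
    if xa.size < min_n:
        raise AssociationError(f"need at least {min_n} pairs, got {xa.size}")
    return xa, ya


def kendall_tau_b(x, y) -> float:
    """Kendall's tau_b: (P - Q)/sqrt((n0 - n1)(n0 - n2)) with tie correction."""
    xa, ya = _paired(x, y, 2)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise AssociationError("tau_b undefined: one variable is all tied")
    tau = stats.kendalltau(xa, ya, variant="b").statistic
    return float(tau)


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of midranks (average ranks for ties)."""
    xa, ya = _paired(x, y, 3)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise AssociationError("rho undefined: zero rank variance")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)


def _extreme_count(t_perm: np.ndarray, t_obs: float, sidedness: str) -> int:
    if sidedness == "two-sided":
        return int(np.sum(np.abs(t_perm) >= abs(t_obs) - _TIE_SLACK))
    if sidedness == "greater":
        return int(np.sum(t_perm >= t_obs - _TIE_SLACK))
    if sidedness == "less":
        return int(np.sum(t_perm <= t_obs + _TIE_SLACK))
    raise AssociationError(f"unknown sidedness {sidedness!r}")


def _spearman_perm_stats(
    xa: np.ndarray, ya: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Spearman statistics over m random permutations of y."""
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    perm = rng.permuted(np.broadcast_to(ry_c, (m, ry_c.size)).copy(), axis=1)
    return (perm @ rx_c) / denom


def permutation_pvalue(
    x,
    y,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    M: int = 50_000,
    seed: int = 0,
    sidedness: str = "two-sided",
    exact: bool | None = None,
) -> AssociationResult:
    """Permutation p-value for an association statistic.

    ``exact=None`` (auto) enumerates all n! permutations when n <= 7 and
    the exact p is #{|T*| >= |T_obs|}/n! (the identity permutation is
    among them, so p >= 1/n!).  Otherwise a Monte Carlo over M seeded
    permutations of y with the add-one estimator (1 + count)/(M + 1).
    A vectorized path is used when ``statistic is spearman_rho``.
    """
    xa, ya = _paired(x, y, 2)
    n = xa.size
    t_obs = float(statistic(xa, ya))
    name = getattr(statistic, "__name__", "statistic")

    if exact is None:
        exact = n <= EXHAUSTIVE_MAX_N
    if exact:
        if n > 9:
            raise AssociationError(f"exhaustive enumeration infeasible at n = {n}")
        t_perm = np.empty(math.factorial(n))
        for i, perm in enumerate(permutations(range(n))):
            try:
                t_perm[i] = statistic(xa, ya[list(perm)])
            except Exception as exc:  # pragma: no cover - surfaced per spec
                raise AssociationError(
                    f"statistic failed on permutation {i}: {exc}"
                ) from exc
        p = _extreme_count(t_perm, t_obs, sidedness) / t_perm.size
        return AssociationResult(
            statistic_name=name,
            estimate=t_obs,
            p_value=p,
            n_permutations_M=int(t_perm.size),
            seed=None,
            method="exhaustive",
        )

    if M < 1000:
        raise AssociationError("M must be >= 1000 for a reported Monte Carlo p")
    rng = np.random.default_rng(seed)
    if statistic is spearman_rho:
        t_perm = _spearman_perm_stats(xa, ya, M, rng)
    else:
        t_perm = np.empty(M)
        for i in range(M):
            perm = rng.permutation(n)
            try:
                t_perm[i] = statistic(xa, ya[perm])
            except Exception as exc:
                raise AssociationError(
                    f"statistic failed on permutation {i}: {exc}"
                ) from exc
    count = _extreme_count(t_perm, t_obs, sidedness)
    p = (1.0 + count) / (M + 1.0)
    return AssociationResult(
        statistic_name=name,
        estimate=t_obs,
        p_value=p,
        n_permutations_M=M,
        seed=seed,
        method="monte_carlo",
    )
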