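"""Closed-form stationary occupancy results and analytical approximations.

At ``alpha = beta = gamma = 1`` no transition is rescaled and the two
kinetochores decouple into independent chains whose stationary law is
available in closed form: each of the ``n`` binding slots is independently
occupied by a left-pole kMT, a right-pole kMT or free, with per-slot odds
``p/(n q)`` for each pole.  The stationary per-kinetochore mean is then

    N_bar = n * rho / (n + rho),        rho = 2 p / q.

For the amphitelic class with ``alpha = 0`` an analytical approximation of
the mean kMT number is available,

    N5_bar = rho_bar (rho_bar/n + 2)^(n-1) / ((rho_bar/n + 2)^n - 2^n),

with ``rho_bar = 2 p / (beta q)``: tension (``beta``) stabilises kMTs by
effectively rescaling the detachment/attachment ratio.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "OccupancyStats",
    "steady_state_mean_kmt",
    "amphitelic_mean_kmt_approx",
    "occupancy_stats",
    "stationary_occupancy_pmf",
]


class FormulaDomainError(ValueError):
    """The closed form is undefined for these parameters."""


@dataclasses.dataclass(frozen=True)
class OccupancyStats:
    """Stationary occupancy summary for one parameter set."""

    rho: float              # 2p/q
    rho_bar: float          # 2p/(beta q)
    mean_all: float         # N_bar, unconditional per-kinetochore mean
    mean_amphitelic: float  # N5_bar, amphitelic-conditional approximation


def steady_state_mean_kmt(n: int, p: float, q: float) -> float:
    """Exact stationary per-kinetochore mean kMT count at unit scalings.

    Valid only for ``alpha = beta = gamma = 1``; returns
    ``n rho / (n + rho)`` with ``rho = 2p/q``.
    """
    if q <= 0:
        raise FormulaDomainError("q must be > 0 (rho = 2p/q undefined at q = 0)")
    rho = 2.0 * p / q
    return n * rho / (n + rho)


def amphitelic_mean_kmt_approx(n: int, p: float, q: float, beta: float) -> float:
    """Approximate amphitelic-conditional mean kMT count (``alpha = 0``).

    Evaluates ``rho_bar x^(n-1) / (x^n - 2^n)`` with ``x = rho_bar/n + 2``
    through the equivalent form ``(rho_bar/2) y^(n-1) / (y^n - 1)``,
    ``y = x/2``, using ``expm1`` in log space so large ``n`` or large
    ``rho_bar`` (small ``beta q``) neither overflow nor cancel.
    """
    if beta <= 0 or q <= 0:
        raise FormulaDomainError(
            "approximation requires beta > 0 and q > 0; for beta = 0 the "
            "amphitelic occupancy approaches n exactly"
        )
    if p <= 0:
        raise FormulaDomainError(
            "p must be > 0: the amphitelic class is unreachable without attachment"
        )
    rho_bar = 2.0 * p / (beta * q)
    log_y = math.log1p(rho_bar / (2.0 * n))  # y = rho_bar/(2n) + 1 > 1
    z = n * log_y
    if z > 700.0:  # y^n overflows; y^n - 1 == y^n to double precision
        return (rho_bar / 2.0) * math.exp(-log_y)
    return (rho_bar / 2.0) * math.exp((n - 1) * log_y) / math.expm1(z)


def occupancy_stats(n: int, p: float, q: float, beta: float) -> OccupancyStats:
    return OccupancyStats(
        rho=2.0 * p / q,
        rho_bar=2.0 * p / (beta * q),
        mean_all=steady_state_mean_kmt(n, p, q),
        mean_amphitelic=amphitelic_mean_kmt_approx(n, p, q, beta),
    )


def stationary_occupancy_pmf(n: int, p: float, q: float) -> np.ndarray:
    """Exact stationary per-kinetochore law at ``alpha = beta = gamma = 1``.

    Returns the (n+1, n+1) table ``P(i, j)`` of left/right kMT counts on a
    single kinetochore: a trinomial over the ``n`` binding slots where each
    slot is left-attached, right-attached or free with probabilities
    ``(s, s, 1 - 2s)`` and ``s = (p/(nq)) / (1 + 2 p/(nq))`` (the
    detailed-balance odds of one slot).
    """
    if q <= 0:
        raise FormulaDomainError("q must be > 0")
    odds = p / (n * q)
    s = odds / (1.0 + 2.0 * odds)
    pmf = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pmf[i, j] = stats.multinomial.pmf(
                [i, j, n - i - j], n=n, p=[s, s, 1.0 - 2.0 * s]
            )
    return pmf
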