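"""Analytic N-person assurance game and its replicator dynamics.

The model: each member of a randomly sampled group of ``N`` players either
stays home (asocial strategy, guaranteed payoff ``h``) or joins a collective
ritual (social strategy, payoff ``s > h`` if at least ``M`` of the group
attend, nothing otherwise).  With a proportion ``x`` of social players in an
infinite well-mixed population, the number of social co-players a focal agent
meets is binomial, and the replicator equation

    x' = x (1 - x) (f_S - f_H)

governs how the social strategy spreads.  For ``M >= 2`` the dynamics have
two stable boundary equilibria (nobody attends / everybody attends) separated
by a single unstable interior threshold: the game is an assurance game and
the social strategy cannot invade from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

__all__ = [
    "GameParams",
    "EquilibriumReport",
    "payoff_asocial",
    "payoff_social",
    "expected_fitness_social",
    "expected_fitness_asocial",
    "fitness_gap",
    "replicator_step",
    "find_equilibria",
    "equilibria_frame",
]

_GAP_TOL = 1e-10


@dataclass(frozen=True)
class GameParams:
    """Payoff and group-structure parameters of the assurance game.

    Parameters
    ----------
    h : float
        Asocial (stay-home) payoff; ``h > 0``.
    s : float
        Social payoff when the attendance threshold is cleared; ``s > h``.
    n : int
        Group size; at least 2.
    m : int
        Threshold count of social players required for the collective
        benefit, ``1 <= m <= n``.
    """

    h: float
    s: float
    n: int
    m: int

    def __post_init__(self) -> None:
        if not (self.h > 0):
            raise ValueError(f"asocial payoff h must be positive, got {self.h}")
        if not (self.s > self.h):
            raise ValueError(f"social payoff s={self.s} must exceed h={self.h}")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"group size n must be an integer >= 2, got {self.n}")
        if int(self.m) != self.m or not (1 <= self.m <= self.n):
            raise ValueError(f"threshold m must satisfy 1 <= m <= n, got {self.m}")


@dataclass(frozen=True)
class EquilibriumReport:
    """A fixed point of the replicator dynamics and its stability."""

    x: float
    stability: Literal["stable", "unstable"]


def _check_k(k: int, lo: int, hi: int) -> None:
    if int(k) != k or not (lo <= k <= hi):
        raise ValueError(f"pilgrim count k={k} outside [{lo}, {hi}]")


def _check_x(x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"proportion x={x} outside [0, 1]")


def payoff_asocial(k: int, params: GameParams) -> float:
    """Payoff to staying home given ``k`` pilgrims among the N-1 co-players.

    Frequency independent: always ``h``.
    """
    _check_k(k, 0, params.n - 1)
    return params.h


def payoff_social(k: int, params: GameParams) -> float:
    """Payoff to attending given ``k`` pilgrims in total (focal included).

    A step function: ``s`` when the threshold is cleared (``k >= m``),
    zero otherwise — the lone pilgrim leaves empty-handed.
    """
    _check_k(k, 1, params.n)
    return params.s if k >= params.m else 0.0


def expected_fitness_social(x: float, params: GameParams) -> float:
    """Expected payoff f_S of a social player when a fraction ``x`` is social.

    The focal pilgrim meets ``K ~ Binomial(N-1, x)`` social co-players, so

        f_S = sum_k C(N-1, k) x^k (1-x)^(N-1-k) * pi_S(k + 1)
            = s * P(K >= m - 1).
    """
    _check_x(x)
    # P(K >= m-1) with K ~ Binom(n-1, x); sf(m-2) handles m=1 (prob 1).
    return params.s * float(binom.sf(params.m - 2, params.n - 1, x))


def expected_fitness_asocial(x: float, params: GameParams) -> float:
    """Expected payoff f_H of an asocial player: the binomial-weighted sum.

    Evaluated as the explicit sum over co-player compositions; since the
    asocial payoff is constant this equals ``h`` (the weights normalize).
    """
    _check_x(x)
    k = np.arange(params.n)
    return float(np.sum(binom.pmf(k, params.n - 1, x)) * params.h)


def fitness_gap(x: float, params: GameParams) -> float:
    """f_S - f_H, the selection gradient of the social strategy.

    Uses the rewritten form  -h + s * P(K >= m-1),  K ~ Binomial(N-1, x).
    Negative at x=0 whenever m >= 2: a rare pilgrim cannot invade.
    """
    _check_x(x)
    return -params.h + params.s * float(binom.sf(params.m - 2, params.n - 1, x))


def replicator_step(x: float, params: GameParams) -> float:
    """Rate of change x' = x (1-x) (f_S - f_H); zero at both boundaries."""
    _check_x(x)
    if x == 0.0 or x == 1.0:
        return 0.0
    return x * (1.0 - x) * fitness_gap(x, params)


def find_equilibria(params: GameParams, grid_resolution: int = 1001) -> list[EquilibriumReport]:
    """Locate all fixed points of the replicator dynamics on [0, 1].

    The boundaries x=0 and x=1 are always fixed points; x=0 is stable when
    the gap at zero is negative (social cannot invade) and x=1 is stable
    when the gap at one is positive.  Interior roots of the fitness gap are
    found by sign-change scanning on a uniform grid followed by Brent
    refinement; a crossing from negative to positive is the unstable
    assurance threshold.

    Parameters
    ----------
    grid_resolution : int
        Number of grid points for sign-change detection (>= 100).
    """
    if grid_resolution < 100:
        raise ValueError("grid_resolution must be at least 100")
    gap0 = fitness_gap(0.0, params)
    gap1 = fitness_gap(1.0, params)
    reports = [
        EquilibriumReport(0.0, "stable" if gap0 < 0 else "unstable"),
        EquilibriumReport(1.0, "stable" if gap1 > 0 else "unstable"),
    ]

    xs = np.linspace(0.0, 1.0, grid_resolution)
    gaps = np.array([fitness_gap(float(x), params) for x in xs])

    flat = np.abs(gaps) < _GAP_TOL
    if np.count_nonzero(flat[1:-1]) > 1:
        warnings.warn(
            "fitness gap vanishes on an interval (degenerate payoffs); "
            "reporting a single representative interior point",
            stacklevel=2,
        )
        i = int(np.flatnonzero(flat[1:-1])[0]) + 1
        reports.append(EquilibriumReport(float(xs[i]), "unstable"))
        return reports

    sign = np.sign(gaps)
    for i in range(grid_resolution - 1):
        a, b = float(xs[i]), float(xs[i + 1])
        if sign[i] == 0.0 and 0 < i:  # exact grid-point root
            root, rising = a, gaps[i + 1] > gaps[i - 1]
        elif sign[i] * sign[i + 1] < 0:
            root = float(brentq(lambda x: fitness_gap(x, params), a, b, xtol=_GAP_TOL))
            rising = gaps[i + 1] > gaps[i]
        else:
            continue
        if 0.0 < root < 1.0:
            reports.append(EquilibriumReport(root, "unstable" if rising else "stable"))
    return reports


def equilibria_frame(reports: list[EquilibriumReport]):
    """Equilibrium reports as a DataFrame (columns: x, stability)."""
    import pandas as pd

    return pd.DataFrame({"x": [r.x for r in reports], "stability": [r.stability for r in reports]})
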