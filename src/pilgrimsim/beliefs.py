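"""Agents' Gaussian payoff beliefs: sampling, choice, and Bayesian updating.

Each agent carries one Gaussian belief per strategy, parameterized by a mean,
a spread (standard deviation) and a certainty expressed as a pseudo-sample
size.  Strategies are chosen by drawing once from each belief and playing
the strategy with the higher draw (Thompson-style sampling).  Updating is
moment-matched pseudo-sample updating: the prior is treated as ``n`` pseudo
observations with the belief's mean and variance, and each observed payoff
is pooled in as one additional observation, so the mean and spread both
move and certainty grows by exactly one per observation.  Individual and
social observations go through the same update and therefore carry equal
weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.stats import norm

__all__ = [
    "StrategyBelief",
    "AgentState",
    "DEFAULT_SD_MIN",
    "sample_value",
    "choose_strategy",
    "update_belief",
    "update_belief_arrays",
    "calibrate_prior_sd",
]

#: Floor on the belief spread after an update, preventing a belief from
#: collapsing to a point mass and ending exploration forever.
DEFAULT_SD_MIN = 1e-3

Strategy = Literal["social", "asocial"]


@dataclass(frozen=True)
class StrategyBelief:
    """Gaussian belief about one strategy's payoff.

    Parameters
    ----------
    mean : float
        Believed expected payoff (utility units).
    sd : float
        Believed payoff spread (standard deviation, >= 0).
    pseudo_n : float
        Certainty as an effective sample size (>= 1); grows by one with
        every observed payoff.
    """

    mean: float
    sd: float
    pseudo_n: float = 2.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"belief sd must be >= 0, got {self.sd}")
        if self.pseudo_n < 1:
            raise ValueError(f"pseudo_n must be >= 1, got {self.pseudo_n}")


@dataclass
class AgentState:
    """One agent: two strategy beliefs plus attendance-commitment bookkeeping."""

    id: int
    belief_social: StrategyBelief
    belief_asocial: StrategyBelief
    commitment_remaining: int = 0
    last_strategy: Optional[Strategy] = None
    last_payoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.commitment_remaining < 0:
            raise ValueError("commitment_remaining must be >= 0")
        if (self.last_strategy is None) != (self.last_payoff is None):
            raise ValueError("last_payoff is set iff last_strategy is set")


def sample_value(belief: StrategyBelief, rng: np.random.Generator) -> float:
    """One draw from the belief; a zero-spread belief returns its mean."""
    if belief.sd == 0.0:
        return belief.mean
    return belief.mean + belief.sd * rng.standard_normal()


def choose_strategy(agent: AgentState, rng: np.random.Generator) -> Strategy:
    """Draw once from each belief; play the strategy with the higher draw.

    The social draw is taken first.  An exact tie resolves to asocial (ties
    have probability zero whenever either spread is positive).
    """
    draw_social = sample_value(agent.belief_social, rng)
    draw_asocial = sample_value(agent.belief_asocial, rng)
    return "social" if draw_social > draw_asocial else "asocial"


def update_belief_arrays(
    mean: np.ndarray,
    sd: np.ndarray,
    pseudo_n: np.ndarray,
    observation: np.ndarray,
    sd_min: float = DEFAULT_SD_MIN,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized moment-matched update; returns (mean', sd', pseudo_n').

    Pools the prior — read as ``pseudo_n`` pseudo observations with sample
    mean ``mean`` and sample variance ``sd**2`` — with one new observation:

        n' = n + 1
        mu' = (n mu + y) / n'
        sd'^2 = max( (n (sd^2 + mu^2) + y^2) / n' - mu'^2 , sd_min^2 )

    The update is order-independent over a batch of observations because it
    only tracks the pooled sufficient statistics (n, sum y, sum y^2).
    """
    n1 = pseudo_n + 1.0
    mu1 = (pseudo_n * mean + observation) / n1
    var1 = (pseudo_n * (sd * sd + mean * mean) + observation * observation) / n1 - mu1 * mu1
    var1 = np.maximum(var1, sd_min * sd_min)
    return mu1, np.sqrt(var1), n1


def update_belief(
    belief: StrategyBelief, observation: float, sd_min: float = DEFAULT_SD_MIN
) -> StrategyBelief:
    """Update a belief with one observed payoff (individual or social)."""
    if not np.isfinite(observation):
        raise ValueError(f"observation must be finite, got {observation}")
    mu, sd, n = update_belief_arrays(
        np.float64(belief.mean),
        np.float64(belief.sd),
        np.float64(belief.pseudo_n),
        np.float64(observation),
        sd_min=sd_min,
    )
    return StrategyBelief(mean=float(mu), sd=float(sd), pseudo_n=float(n))


def calibrate_prior_sd(p0: float, mu_asocial: float, mu_social: float) -> float:
    """Common prior spread giving a target first-turn pilgrim proportion.

    Both beliefs get the same spread ``sigma``.  A first-turn agent plays
    social when its social draw beats its asocial draw, which happens with
    probability ``Phi((mu_S - mu_A) / (sigma sqrt(2)))``; inverting gives

        sigma = (mu_A - mu_S) / (sqrt(2) * z_{1 - p0}).

    With this spread the expected number of first-turn pilgrims in a group
    of N agents is ``N * p0``.

    Parameters
    ----------
    p0 : float
        Target initial pilgrim proportion, in (0, 0.5).
    mu_asocial, mu_social : float
        Shared prior means; requires ``mu_asocial > mu_social`` (the initial
        cultural expectation favors staying home).
    """
    if not (0.0 < p0 < 0.5):
        raise ValueError(f"target initial proportion must lie in (0, 0.5), got {p0}")
    if not (mu_asocial > mu_social):
        raise ValueError(
            f"calibration requires mu_asocial > mu_social, got {mu_asocial} <= {mu_social}"
        )
    z = norm.ppf(1.0 - p0)
    return (mu_asocial - mu_social) / (np.sqrt(2.0) * z)
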