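"""Agent-based simulator of pilgrimage emergence.

Each turn, every agent (i) samples its two payoff beliefs and plays the
strategy with the higher draw (agents under an attendance commitment play
social without sampling); (ii) receives the frequency-dependent assurance
game payoff — social players get ``SP`` if at least ``M`` of the ``N``
agents attended, nothing otherwise; stay-homes get ``AP``; (iii) receives
an independent zero-mean Gaussian frequency-independent payoff with spread
``PV`` from its everyday economic activity; (iv) updates the belief of the
strategy it played with its own *total* payoff — the model's central
conflation: agents cannot tell a lucky year from a miracle; (v) observes
one random demonstrator from the transmission-rule-eligible pool and
updates the belief of the demonstrator's strategy with the demonstrator's
total payoff.

A *round* is a fresh population run for ``TMax`` turns; an *experiment* is
``RMax`` independent rounds with sub-seeds derived deterministically from
the master seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .beliefs import (
    DEFAULT_SD_MIN,
    AgentState,
    StrategyBelief,
    calibrate_prior_sd,
    update_belief_arrays,
)
from .conventions import ATTENDANCE_RULES, TRANSMISSION_KINDS, TransmissionRule, eligible_mask

__all__ = ["SimConfig", "TurnRecord", "Population", "init_population", "play_turn", "run_round", "run_experiment", "trajectory_frame"]


@dataclass(frozen=True)
class SimConfig:
    """Full parameter set for one simulation condition.

    Parameters
    ----------
    t_max, r_max : int
        Turns per round and number of independent rounds.
    n_agents : int
        Group size N.
    m : int, optional
        Explicit attendance threshold M; if omitted, ``m_fraction`` applies.
    m_fraction : float
        Threshold as a fraction of N (default one third, floored, min 1).
    pv : float
        Spread of the frequency-independent environmental payoff (the scale
        of the zero-mean Gaussian).  If ``pv_is_variance`` is set, ``pv`` is
        read as a variance instead.
    ap, sp : float
        Asocial payoff h and social payoff s (s > h > 0).
    mu_asocial, mu_social : float
        Shared prior means; mu_asocial defaults to ``ap``.
    p0 : float, optional
        Target initial pilgrim proportion; when given, the common prior
        spread is calibrated so that the expected first-turn pilgrim
        fraction equals p0.  Mutually exclusive with ``sigma``.
    sigma : float, optional
        Explicit common prior spread (used when ``p0`` is None).
    nu : float
        Initial prior certainty (pseudo-sample size) for both strategies.
    sd_min : float
        Floor on belief spread after updates.
    attendance_rule : str
        ``off`` or ``three_visits``.
    transmission_rule : str
        ``baseline``, ``site_serving`` or ``general_positivity``.
    seed : int
        Master seed; rounds derive independent sub-streams from it.
    condition_id : str
        Label carried into output tables.
    """

    t_max: int = 300
    r_max: int = 50
    n_agents: int = 50
    m: Optional[int] = None
    m_fraction: float = 1.0 / 3.0
    pv: float = 0.6
    ap: float = 1.0
    sp: float = 2.0
    mu_asocial: Optional[float] = None
    mu_social: float = 0.0
    p0: Optional[float] = 0.10
    sigma: Optional[float] = None
    nu: float = 2.0
    sd_min: float = DEFAULT_SD_MIN
    attendance_rule: str = "off"
    transmission_rule: str = "baseline"
    positivity_strict: bool = False
    pv_is_variance: bool = False
    seed: int = 0
    condition_id: str = "run"

    def __post_init__(self) -> None:
        if self.t_max < 1 or self.r_max < 1 or self.n_agents < 1:
            raise ValueError("t_max, r_max and n_agents must be positive")
        if not (self.sp > self.ap > 0):
            raise ValueError(f"need sp > ap > 0, got sp={self.sp}, ap={self.ap}")
        if self.pv < 0:
            raise ValueError(f"pv must be >= 0, got {self.pv}")
        if not (1 <= self.m_resolved <= self.n_agents):
            raise ValueError(f"threshold M={self.m_resolved} outside [1, N={self.n_agents}]")
        if self.attendance_rule not in ATTENDANCE_RULES:
            raise ValueError(f"unknown attendance_rule {self.attendance_rule!r}")
        if self.transmission_rule not in TRANSMISSION_KINDS:
            raise ValueError(f"unknown transmission_rule {self.transmission_rule!r}")
        if (self.p0 is None) == (self.sigma is None):
            raise ValueError("specify exactly one of p0 (calibrated spread) or sigma")
        # Fail early on infeasible calibration.
        self.prior_sd

    @property
    def m_resolved(self) -> int:
        """The attendance threshold M (explicit, or floor(N * fraction), min 1)."""
        if self.m is not None:
            return int(self.m)
        return max(1, math.floor(self.n_agents * self.m_fraction))

    @property
    def pv_sd(self) -> float:
        """Standard deviation of the FI noise, whatever scale ``pv`` is on."""
        return math.sqrt(self.pv) if self.pv_is_variance else self.pv

    @property
    def mu_asocial_resolved(self) -> float:
        return self.ap if self.mu_asocial is None else self.mu_asocial

    @property
    def prior_sd(self) -> float:
        """Common prior spread: calibrated from p0, or the explicit sigma."""
        if self.p0 is not None:
            return calibrate_prior_sd(self.p0, self.mu_asocial_resolved, self.mu_social)
        return float(self.sigma)

    @property
    def transmission(self) -> TransmissionRule:
        return TransmissionRule(
            kind=self.transmission_rule,
            reference_payoff=self.ap,
            strict_at_cutoff=self.positivity_strict,
        )

    def resolved_dict(self) -> dict:
        """All fields plus derived quantities, for run logs."""
        d = asdict(self)
        d.update(
            m_resolved=self.m_resolved,
            pv_sd=self.pv_sd,
            prior_sd=self.prior_sd,
            mu_asocial_resolved=self.mu_asocial_resolved,
        )
        return d


@dataclass(frozen=True)
class TurnRecord:
    """Per-turn observables."""

    round: int
    turn: int
    k: int
    prop_social: float
    threshold_cleared: bool


_STRAT_NONE, _STRAT_ASOCIAL, _STRAT_SOCIAL = -1, 0, 1


class Population:
    """Struct-of-arrays population; indexable as a sequence of AgentState.

    The engine operates on the arrays directly so a turn is a handful of
    vectorized operations regardless of N; ``pop[i]`` materializes a view
    of one agent for inspection and tests.
    """

    def __init__(self, config: SimConfig):
        n = config.n_agents
        sd = config.prior_sd
        self.mu_social = np.full(n, config.mu_social, dtype=float)
        self.sd_social = np.full(n, sd, dtype=float)
        self.nu_social = np.full(n, config.nu, dtype=float)
        self.mu_asocial = np.full(n, config.mu_asocial_resolved, dtype=float)
        self.sd_asocial = np.full(n, sd, dtype=float)
        self.nu_asocial = np.full(n, config.nu, dtype=float)
        self.commitment = np.zeros(n, dtype=np.int64)
        self.last_strategy = np.full(n, _STRAT_NONE, dtype=np.int64)
        self.last_payoff = np.full(n, np.nan, dtype=float)

    def __len__(self) -> int:
        return self.mu_social.size

    def __getitem__(self, i: int) -> AgentState:
        strat = self.last_strategy[i]
        return AgentState(
            id=int(i),
            belief_social=StrategyBelief(
                float(self.mu_social[i]), float(self.sd_social[i]), float(self.nu_social[i])
            ),
            belief_asocial=StrategyBelief(
                float(self.mu_asocial[i]), float(self.sd_asocial[i]), float(self.nu_asocial[i])
            ),
            commitment_remaining=int(self.commitment[i]),
            last_strategy=(
                None if strat == _STRAT_NONE else ("social" if strat == _STRAT_SOCIAL else "asocial")
            ),
            last_payoff=None if strat == _STRAT_NONE else float(self.last_payoff[i]),
        )

    def __iter__(self) -> Iterator[AgentState]:
        return (self[i] for i in range(len(self)))


def init_population(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Population:
    """Fresh population of N agents sharing the configured priors.

    Priors are cultural expectations shared across the population, so
    initialization is deterministic; the ``rng`` argument is accepted for
    interface symmetry and future heterogeneous-prior extensions.
    """
    return Population(config)


def _sample_demonstrators(
    pool: np.ndarray, in_pool: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """For each focal agent, one uniform draw from pool minus itself.

    Returns (demonstrator index per agent, validity mask).  Agents whose
    pool (after removing themselves) is empty are marked invalid and skip
    social learning this turn.
    """
    m = pool.size
    m_eff = m - in_pool.astype(np.int64)
    valid = m_eff > 0
    # Uniform integer in [0, m_eff); the rng is consumed for every agent so
    # the stream layout does not depend on pool composition.
    r = np.floor(rng.random(n) * np.maximum(m_eff, 1)).astype(np.int64)
    # Rank of each agent inside the sorted pool; skipping self shifts draws
    # at or above the agent's own rank up by one slot.
    rank = np.searchsorted(pool, np.arange(n))
    idx = r + (in_pool & (r >= rank))
    return pool[np.minimum(idx, m - 1)], valid


def play_turn(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    round_index: int = 0,
    turn_index: int = 0,
) -> TurnRecord:
    """Advance the population by one turn; returns the turn's observables."""
    n = len(pop)
    if n == 0:
        raise ValueError("empty population")
    m_thresh = config.m_resolved

    # 1. Strategy choice: one draw per belief; committed agents play social
    # regardless (their draws are discarded).
    committed = pop.commitment > 0
    draw_social = pop.mu_social + pop.sd_social * rng.standard_normal(n)
    draw_asocial = pop.mu_asocial + pop.sd_asocial * rng.standard_normal(n)
    free_social = ~committed & (draw_social > draw_asocial)
    social = committed | free_social

    # 2-3. Frequency-dependent payoff: threshold public good.
    k = int(np.count_nonzero(social))
    cleared = k >= m_thresh
    fd = np.where(social, config.sp if cleared else 0.0, config.ap)

    # 4-5. Frequency-independent payoff: everyone's economic year.
    total = fd + config.pv_sd * rng.standard_normal(n)
    pop.last_strategy = np.where(social, _STRAT_SOCIAL, _STRAT_ASOCIAL)
    pop.last_payoff = total

    # Attendance bookkeeping: free pilgrims commit to two more visits;
    # committed pilgrims work one off.
    if config.attendance_rule == "three_visits":
        pop.commitment = np.where(committed, pop.commitment - 1, np.where(free_social, 2, 0))

    # 6. Individual learning on the strategy each agent actually played.
    _update_masked(pop, social, total, config.sd_min, social_belief=True)
    _update_masked(pop, ~social, total, config.sd_min, social_belief=False)

    # 7. Social learning from one demonstrator drawn from the eligible pool.
    keep = eligible_mask(social, total, config.transmission)
    pool = np.flatnonzero(keep)
    if pool.size:
        dem, valid = _sample_demonstrators(pool, keep, n, rng)
        obs_social = social[dem]
        obs_pay = total[dem]
        _update_masked(pop, valid & obs_social, obs_pay, config.sd_min, social_belief=True)
        _update_masked(pop, valid & ~obs_social, obs_pay, config.sd_min, social_belief=False)
    else:
        rng.random(n)  # keep the stream layout turn-invariant

    return TurnRecord(
        round=round_index,
        turn=turn_index,
        k=k,
        prop_social=k / n,
        threshold_cleared=cleared,
    )


def _update_masked(
    pop: Population,
    mask: np.ndarray,
    observations: np.ndarray,
    sd_min: float,
    social_belief: bool,
) -> None:
    if not mask.any():
        return
    if social_belief:
        mu, sd, nu = pop.mu_social, pop.sd_social, pop.nu_social
    else:
        mu, sd, nu = pop.mu_asocial, pop.sd_asocial, pop.nu_asocial
    mu1, sd1, nu1 = update_belief_arrays(
        mu[mask], sd[mask], nu[mask], observations[mask], sd_min=sd_min
    )
    mu[mask], sd[mask], nu[mask] = mu1, sd1, nu1


def run_round(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    round_index: int = 0,
) -> list[TurnRecord]:
    """One fresh population run for ``t_max`` turns; beliefs persist within."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pop = init_population(config, rng)
    return [
        play_turn(pop, config, rng, round_index=round_index, turn_index=t)
        for t in range(config.t_max)
    ]


def run_experiment(config: SimConfig) -> list[list[TurnRecord]]:
    """``r_max`` independent rounds with deterministic per-round sub-seeds.

    Round ``r`` uses the sub-stream spawned at key ``r`` from the master
    seed, so rounds are statistically independent, reproducible, and
    unaffected by how many of them run.
    """
    rounds = []
    for r in range(config.r_max):
        ss = np.random.SeedSequence(config.seed, spawn_key=(r,))
        rounds.append(run_round(config, np.random.default_rng(ss), round_index=r))
    return rounds


def trajectory_frame(rounds: list[list[TurnRecord]], condition_id: str = "run") -> pd.DataFrame:
    """Flatten round trajectories into the standard output table.

    Columns: condition_id, round, turn, k, prop_social, threshold_cleared.
    """
    recs = [
        (condition_id, t.round, t.turn, t.k, t.prop_social, t.threshold_cleared)
        for rnd in rounds
        for t in rnd
    ]
    return pd.DataFrame(
        recs, columns=["condition_id", "round", "turn", "k", "prop_social", "threshold_cleared"]
    )
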