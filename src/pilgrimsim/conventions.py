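"""Site-side conventions: attendance commitments and biased transmission.

Two families of belief-system rules that a shrine's community can impose:

* the **three-visit attendance rule** — an agent who freely chooses to go on
  pilgrimage commits to attending the next two turns as well, without
  consulting its beliefs;
* **positivity-biased transmission** — restrictions on who may serve as a
  demonstrator during social learning.  Under the *site-serving* ("lucky
  pilgrim") bias only pilgrims whose payoff beat the expected stay-home
  payoff are observable (unlucky pilgrims keep quiet; everyone who stayed
  home may be observed).  Under the *general positivity* bias any player —
  either strategy — whose payoff fell below the stay-home expectation drops
  out of the demonstrator pool.

The luck cutoff is the environment's asocial payoff ``h`` (an objective
property of the world), not any agent's subjective belief about it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .beliefs import AgentState

__all__ = [
    "TransmissionRule",
    "TRANSMISSION_KINDS",
    "ATTENDANCE_RULES",
    "apply_attendance_rule",
    "demonstrator_pool",
    "eligible_mask",
]

TRANSMISSION_KINDS = ("baseline", "site_serving", "general_positivity")
ATTENDANCE_RULES = ("off", "three_visits")


@dataclass(frozen=True)
class TransmissionRule:
    """Which players are observable as demonstrators this turn.

    Parameters
    ----------
    kind : str
        One of ``baseline``, ``site_serving``, ``general_positivity``.
    reference_payoff : float
        The luck cutoff — the expected asocial payoff ``h`` of the active
        configuration.
    strict_at_cutoff : bool
        For ``general_positivity`` only: whether a payoff exactly equal to
        the cutoff excludes the player.  Default False (payoff >= h keeps a
        player in the pool); the boundary case has probability zero once
        environmental noise is present.
    """

    kind: Literal["baseline", "site_serving", "general_positivity"]
    reference_payoff: float
    strict_at_cutoff: bool = False

    def __post_init__(self) -> None:
        if self.kind not in TRANSMISSION_KINDS:
            raise ValueError(f"unknown transmission rule {self.kind!r}")


def apply_attendance_rule(agent: AgentState, chosen: str) -> AgentState:
    """Advance the three-visit commitment counter after a strategy choice.

    A free social choice (commitment counter at zero) commits the agent to
    two further visits; a committed agent works one visit off.  Commitments
    never stack: a committed agent cannot freely choose while committed.
    Committed agents skip belief sampling when choosing but keep learning
    from payoffs and social observation as usual.
    """
    if agent.commitment_remaining > 0:
        return replace(agent, commitment_remaining=agent.commitment_remaining - 1)
    if chosen == "social":
        return replace(agent, commitment_remaining=2)
    return agent


def eligible_mask(
    is_social: np.ndarray,
    payoffs: np.ndarray,
    rule: TransmissionRule,
) -> np.ndarray:
    """Boolean mask of demonstrator-eligible players (focal not yet removed)."""
    h = rule.reference_payoff
    if rule.kind == "baseline":
        return np.ones_like(is_social, dtype=bool)
    if rule.kind == "site_serving":
        # All stay-homes, plus only the lucky pilgrims (payoff strictly > h).
        return ~is_social | (payoffs > h)
    if rule.strict_at_cutoff:
        return payoffs > h
    return payoffs >= h


def demonstrator_pool(
    agents: Sequence[AgentState],
    focal: AgentState,
    rule: TransmissionRule,
) -> list[AgentState]:
    """The agents a focal learner may observe this turn, rule applied.

    Every agent must carry this turn's ``last_strategy`` and ``last_payoff``.
    The focal agent is never its own demonstrator.  An empty pool is legal;
    the engine then skips social learning for that focal agent.
    """
    is_social = np.array([a.last_strategy == "social" for a in agents])
    payoffs = np.array(
        [a.last_payoff if a.last_payoff is not None else np.nan for a in agents], dtype=float
    )
    if np.isnan(payoffs).any():
        raise ValueError("all agents need last_strategy/last_payoff before transmission")
    keep = eligible_mask(is_social, payoffs, rule)
    return [a for a, ok in zip(agents, keep) if ok and a.id != focal.id]
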