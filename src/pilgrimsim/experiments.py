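"""Parameter sweeps and trajectory summaries.

The headline experiment crosses three factors — initial pilgrim proportion
(prior strength), environmental payoff variance, and group size — into a
3 x 8 x 3 = 72-condition grid, runs every condition for ``r_max`` rounds,
and summarizes the round trajectories (mean adoption per turn, fraction of
rounds reaching fixation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import SimConfig, run_experiment, trajectory_frame

__all__ = [
    "SweepSpec",
    "DEFAULT_FIXATION_CUTOFF",
    "build_sweep_grid",
    "run_conditions",
    "summarize",
    "variant_configs",
]

DEFAULT_FIXATION_CUTOFF = 0.9

DEFAULT_P0_LEVELS = (0.01, 0.05, 0.10)
DEFAULT_PV_GRID = tuple(round(0.2 * i, 1) for i in range(1, 9))  # 0.2 .. 1.6
DEFAULT_GROUP_SIZES = (10, 50, 100)


@dataclass(frozen=True)
class SweepSpec:
    """Factor grids plus the shared settings for every cell.

    ``shared`` supplies all SimConfig fields not governed by the grid; each
    cell overrides n_agents, p0 and pv and receives a deterministic
    condition id and sub-seed derived from the shared master seed.
    """

    initial_proportions: Sequence[float] = DEFAULT_P0_LEVELS
    pv_grid: Sequence[float] = DEFAULT_PV_GRID
    group_sizes: Sequence[int] = DEFAULT_GROUP_SIZES
    shared: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not (self.initial_proportions and self.pv_grid and self.group_sizes):
            raise ValueError("all three factor lists must be non-empty")
        if any(not (0 < p < 0.5) for p in self.initial_proportions):
            raise ValueError("every initial proportion must lie in (0, 0.5)")


def _condition_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def build_sweep_grid(spec: SweepSpec) -> list[SimConfig]:
    """Cartesian product of the three factor lists over the shared settings.

    Cell order: initial proportion (slowest) x variance x group size; the
    default spec yields 72 conditions.
    """
    configs = []
    index = 0
    for p0 in spec.initial_proportions:
        for pv in spec.pv_grid:
            for n in spec.group_sizes:
                configs.append(
                    replace(
                        spec.shared,
                        p0=p0,
                        sigma=None,
                        pv=pv,
                        n_agents=n,
                        seed=_condition_seed(spec.shared.seed, index),
                        condition_id=f"p{p0:g}_pv{pv:g}_N{n}",
                    )
                )
                index += 1
    return configs


def run_conditions(configs: Iterable[SimConfig], progress: bool = False) -> pd.DataFrame:
    """Run every condition; returns the concatenated trajectory table."""
    configs = list(configs)
    if progress:
        try:
            from tqdm import tqdm

            configs = tqdm(configs, desc="conditions")
        except ImportError:  # pragma: no cover - cosmetic only
            pass
    frames = [trajectory_frame(run_experiment(c), condition_id=c.condition_id) for c in configs]
    return pd.concat(frames, ignore_index=True)


def summarize(
    trajectories: pd.DataFrame,
    fixation_cutoff: float = DEFAULT_FIXATION_CUTOFF,
    configs: Optional[Sequence[SimConfig]] = None,
) -> pd.DataFrame:
    """Per-(condition, turn) mean adoption plus per-condition fixation share.

    ``mean_prop_social`` averages prop_social over rounds at each turn;
    ``fixation_fraction`` is the share of rounds whose final-turn
    prop_social reaches the cutoff.  When ``configs`` is given, the factor
    columns p0, pv and n_agents are joined in by condition id.
    """
    required = {"condition_id", "round", "turn", "prop_social"}
    if not required.issubset(trajectories.columns):
        raise ValueError(f"trajectory table must have columns {sorted(required)}")
    lengths = trajectories.groupby(["condition_id", "round"])["turn"].count()
    for cond, counts in lengths.groupby(level=0):
        if counts.nunique() > 1:
            raise ValueError(f"mismatched trajectory lengths within condition {cond!r}")

    mean = (
        trajectories.groupby(["condition_id", "turn"], sort=True)["prop_social"]
        .mean()
        .rename("mean_prop_social")
        .reset_index()
    )
    final_turn = trajectories.groupby("condition_id")["turn"].transform("max")
    finals = trajectories[trajectories["turn"] == final_turn]
    fix = (
        finals.groupby("condition_id")["prop_social"]
        .apply(lambda p: float(np.mean(p >= fixation_cutoff)))
        .rename("fixation_fraction")
        .reset_index()
    )
    out = mean.merge(fix, on="condition_id")
    if configs is not None:
        meta = pd.DataFrame(
            {
                "condition_id": [c.condition_id for c in configs],
                "p0": [c.p0 for c in configs],
                "pv": [c.pv for c in configs],
                "n_agents": [c.n_agents for c in configs],
            }
        )
        out = meta.merge(out, on="condition_id")
    return out


def variant_configs(base: SimConfig) -> list[SimConfig]:
    """The convention-rule comparison at one condition.

    Four variants of the base condition: the plain model, the three-visit
    attendance rule, and the two positivity-biased transmission rules.
    """
    variants = [
        ("baseline", "off", "baseline"),
        ("three_visits", "three_visits", "baseline"),
        ("site_serving", "off", "site_serving"),
        ("general_positivity", "off", "general_positivity"),
    ]
    return [
        replace(base, attendance_rule=att, transmission_rule=trans, condition_id=label)
        for label, att, trans in variants
    ]
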