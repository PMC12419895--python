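# Methods

## The assurance game

The analytic layer treats ritual attendance as an N-person stag hunt.
A group of `N` players is sampled from an infinite well-mixed population
in which a fraction `x` plays the social strategy. Staying home pays `h`
regardless of others; attending pays `s > h` if at least `M` players
attend, else nothing. A focal attendee therefore faces a binomial number
`K ~ Bin(N−1, x)` of co-attendees, giving expected payoffs
`f_H = h` and `f_S = s·P(K ≥ M−1)`, and replicator dynamics
`x' = x(1−x)(f_S − f_H)`.

`x'` is read as a continuous-time rate: the package analyzes signs, zeros
and basins, not discrete trajectories of the analytic model. Because
`f_S − f_H` is monotone increasing in `x` for `M ≥ 2`, the dynamics have
exactly two stable boundary equilibria and one interior unstable
threshold whenever `s > h > 0` and `2 ≤ M ≤ N`; with `M = 1` the social
strategy is dominant and `x = 0` is unstable. Interior roots are located
by sign-change scanning on a 1001-point grid followed by Brent refinement
to `|gap| < 1e−10`; a degenerate parameter set whose gap vanishes on an
interval is reported as a single representative point with a warning.

## The agent-based model

Each turn proceeds synchronously:

1. every agent draws once from each of its two Gaussian payoff beliefs
   and plays the strategy with the higher draw (ties, probability zero
   for positive spreads, resolve to staying home); agents under an
   attendance commitment attend without consulting their beliefs;
2. the assurance game is scored: `k` attendees, attendees get `SP` if
   `k ≥ M` else 0, stay-homes get `AP`;
3. every agent independently adds a zero-mean Gaussian environmental
   payoff with standard deviation `PV` — identical in distribution for
   both strategies and symmetric, modelling the variance of everyday
   economic activity;
4. each agent updates the belief of the strategy it played with its own
   **total** payoff. The agent cannot decompose the sum: a lucky year
   after a pilgrimage is indistinguishable from a miracle;
5. each agent observes one demonstrator drawn uniformly from the
   transmission-eligible pool (excluding itself) and updates the belief
   of the demonstrator's strategy with the demonstrator's total payoff.

All individual updates complete before social learning, and social
learning observes the current turn's strategies and payoffs, so results
do not depend on agent ordering within a turn.

### Beliefs and updating

A belief is `(μ, σ, ν)`: mean, spread and a certainty expressed as a
pseudo-sample size. Updating is moment-matched pseudo-sample pooling —
the prior counts as `ν` pseudo-observations with mean `μ` and variance
`σ²`, and each payoff joins the pool as one observation:

```
ν' = ν + 1
μ' = (νμ + y) / ν'
σ'² = max( (ν(σ² + μ²) + y²)/ν' − μ'², σ_min² )
```

This makes "prior certainty interpreted as a prior sample" literal,
weighs individual and social observations exactly equally, and is
order-independent over any batch of observations. Strategy draws come
from `N(μ, σ²)` itself (not from a posterior over the mean), so the
spread tracks the *perceived payoff variability*: in noisy environments
beliefs stay wide and agents keep occasionally re-testing the minority
strategy even after the ritual is established. That persistent churn is a
substantive model feature, and the reason adoption saturates below 1.0
at high `PV`. The update rule is a deliberate design choice where a
Normal–Inverse–Gamma posterior would be the conjugate alternative; the
update function is a single isolated routine, so swapping families is a
one-function change.

`σ_min = 1e−3` (configurable) keeps a belief from collapsing to a point
mass after repeated identical observations, which would end exploration
irreversibly.

### Priors and calibration

Priors are shared across the population and favor staying home:
`μ_A = AP` and `μ_S = 0 < μ_A` by default, both configurable, with
`ν_A = ν_S = 2`, the smallest pseudo-sample with a well-defined variance.
Prior *strength* is parameterized by its observable consequence: given a
target initial attendance proportion `p0`, both beliefs receive the
common spread

```
σ = (μ_A − μ_S) / (√2 · z_{1−p0})
```

so that a first-turn agent attends with probability exactly `p0`. The
standard scenarios are `p0 ∈ {1%, 5%, 10%}`.

### Conventions

* **Three-visit attendance rule** — a free choice to attend commits the
  agent to the next two turns as well. Commitments do not stack, and
  committed agents keep learning individually and socially (the rule
  constrains behavior, not perception).
* **Site-serving bias** — only attendees whose total payoff *strictly
  exceeded* `AP` may be observed; stay-homes are always observable.
* **General positivity bias** — any player whose payoff fell below `AP`
  drops out of the demonstrator pool (a payoff exactly equal to `AP`
  keeps the player in by default; a strict-cutoff toggle exists, the
  boundary being probability-zero once `PV > 0`).

The luck cutoff is the configured `AP` — an environmental quantity — not
any agent's subjective mean. If the eligible pool (minus the focal agent)
is empty, that agent simply skips social learning for the turn.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `AP` (h) | 1.0 | stay-home payoff (utility units) |
| `SP` (s) | 2.0 | ritual payoff when threshold cleared |
| `N` | 50 | group size; sweep uses 10 / 50 / 100 |
| `M` | ⌊N/3⌋, min 1 | attendance threshold (10→3, 50→16, 100→33) |
| `PV` | 0.6 | sd of environmental payoff; sweep grid 0.2–1.6 step 0.2 |
| `p0` | 0.10 | target initial attendance; sweep uses 1% / 5% / 10% |
| `ν` | 2 | initial prior certainty |
| `σ_min` | 1e−3 | belief-spread floor |
| `TMax` | 300 | turns per round |
| `RMax` | 50 | independent rounds per condition |

The payoff scale (`AP = 1`, `SP = 2`) and prior means are package
configuration: the model's substance pins only their ordering
(`SP > AP > μ_S`), and the chosen values put the variance grid 0.2–1.6 in
a regime spanning near-certain to highly unpredictable payoffs relative
to the `SP − AP = 1` coordination premium. `PV` is interpreted as a
standard deviation (the noise is `N(0, PV²)`); a `pv_is_variance` switch
reinterprets it as a variance for sensitivity checks.

## Randomness and reproducibility

All randomness flows through `numpy` Generators. Round `r` of an
experiment uses the stream spawned from `SeedSequence(seed, spawn_key=(r,))`,
so rounds are independent, reproducible in isolation, and invariant to
how many rounds run. Sweep cells likewise derive per-condition seeds from
the master seed by cell index. Identical configurations produce
byte-identical output tables.

The engine is vectorized over agents (a struct-of-arrays population).
Committed agents' belief draws are generated and discarded rather than
skipped so the draw layout per turn is fixed; this changes no behavior,
only how the stream is consumed. Demonstrators are drawn uniformly from
the eligible pool minus the focal agent via rank arithmetic on the sorted
pool, which is exact (no rejection resampling).

## What the simulations show — and what they do not

The simulator's experiments are self-generated; there is no empirical
data path. Runs reproduce the qualitative regularities of the model:
adoption of the ritual is impossible without environmental noise, rises
steeply with `PV` before saturating (exploration churn), is harder in
larger groups at fixed relative threshold, is accelerated by the
three-visit rule, is helped by the site-serving bias and hindered by the
general positivity bias. Statistical checks of these trends run at the
standard 300-turn rounds with 50–60 rounds per condition, sizes at which
each comparison is decisively powered.

None of this speaks to real pilgrimage data: the model has no population
structure, no birth–death dynamics, no cost asymmetries, non-fungible
payoff channels, or strategic anticipation of commitment rules, and the
Gaussian payoff model is a convenience. The analytic and agent-based
layers also answer different questions — infinite-population selection
gradients versus finite-population learning dynamics — and agree only in
their broad equilibrium structure.
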