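"""Stochastic projection of adult-female numbers and realized growth rate.

The deterministic skeleton is the Hatter–Bergerud female-only model:
survivors O_t = S·N_t, recruited females J_t = O_t·R/2 (50 % calf sex
ratio), so N_{t+1} = N_t·S(1+R/2) = N_t·λ̄ below the ceiling.  Three
stochastic layers can be switched on:

* interannual variation — annual S_t, R_t are beta draws around the
  population means, with their own precisions;
* demographic stochasticity — survivors and recruits are binomial
  counts rather than expectations;
* density dependence — a hard ceiling K = c·N₀ on adult females.

Realized growth over a horizon of T years is the geometric mean
(N_T/N₀)^(1/T); populations with realized λ below 0.99 are classed as not
self-sustaining.  An ensemble holds each population's national-quantile
draw fixed across scenarios (quantile persistence), so scenario contrasts
are paired at the population level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .demography import (
    DemographicModel,
    DisturbanceCovariates,
    PopulationQuantile,
    beta_draw,
    rates_at_quantile,
    sample_population_quantiles,
)

SELF_SUSTAINING_LAMBDA = 0.99


@dataclass(frozen=True)
class SimulationOptions:
    years: int = 20
    initial_females: int = 100
    interannual_precision_S: float = 500.0
    interannual_precision_R: float = 100.0
    interannual_variation: bool = True
    demographic_stochasticity: bool = True
    carrying_capacity_multiplier: float = 5.0
    self_sustaining_threshold: float = SELF_SUSTAINING_LAMBDA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.initial_females < 1:
            raise ValueError("initial_females must be >= 1")
        if self.carrying_capacity_multiplier < 1:
            raise ValueError("carrying_capacity_multiplier must be >= 1")
        if not 0.0 < self.self_sustaining_threshold < 2.0:
            raise ValueError("self_sustaining_threshold must be in (0, 2)")
        if self.interannual_precision_S <= 0 or self.interannual_precision_R <= 0:
            raise ValueError("interannual precisions must be > 0")

    @property
    def carrying_capacity(self) -> float:
        return self.carrying_capacity_multiplier * self.initial_females


@dataclass(frozen=True)
class Trajectory:
    N_t: np.ndarray           # adult females per year, length years+1
    S_t: np.ndarray           # realized annual survival, length years
    R_t: np.ndarray           # realized annual recruitment (calves/cow)
    extinct: bool

    @property
    def realized_lambda(self) -> float:
        return realized_lambda(self)


def realized_lambda(traj: Trajectory) -> float:
    """Geometric-mean annual growth (N_T/N₀)^(1/T); 0 for extinct runs."""
    N = np.asarray(traj.N_t, dtype=float)
    if N.size < 2:
        raise ValueError("trajectory must span at least two time points")
    if N[0] <= 0:
        raise ValueError("initial population must be positive")
    T = N.size - 1
    if N[-1] == 0:
        return 0.0
    return float((N[-1] / N[0]) ** (1.0 / T))


def simulate_population(
    population_means: tuple[float, float],
    options: SimulationOptions,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Project one population forward under the configured stochastic layers.

    ``population_means`` is (S_pop, R_pop) with survival in (0,1) and
    recruitment in calves per cow.  Extinction (N = 0) is absorbing; the
    ceiling K caps adult females every year.
    """
    S_pop, R_pop = population_means
    if not 0.0 < S_pop < 1.0:
        raise ValueError(f"population survival must be in (0,1), got {S_pop}")
    if R_pop < 0:
        raise ValueError(f"population recruitment must be >= 0, got {R_pop}")
    if rng is None:
        rng = np.random.default_rng(options.seed)

    K = options.carrying_capacity
    N = np.empty(options.years + 1, dtype=float)
    S_real = np.empty(options.years)
    R_real = np.empty(options.years)
    N[0] = float(options.initial_females)
    for t in range(options.years):
        if options.interannual_variation:
            S_t = beta_draw(S_pop, options.interannual_precision_S, rng)
            # recruitment mean may be >= 1 calves/cow in principle; beta
            # layer applies only when it is a valid proportion
            if 0.0 < R_pop < 1.0:
                R_t = beta_draw(R_pop, options.interannual_precision_R, rng)
            else:
                R_t = R_pop
        else:
            S_t, R_t = S_pop, R_pop
        S_real[t], R_real[t] = S_t, R_t
        n = N[t]
        if n == 0:
            N[t + 1] = 0.0
            continue
        if options.demographic_stochasticity:
            survivors = rng.binomial(int(n), S_t)
            recruits = rng.binomial(survivors, min(R_t / 2.0, 1.0))
        else:
            survivors = n * S_t
            recruits = survivors * min(R_t / 2.0, 1.0)
        N[t + 1] = min(survivors + recruits, K)
    if options.demographic_stochasticity:
        N = np.round(N)
    return Trajectory(N_t=N, S_t=S_real, R_t=R_real, extinct=bool(N[-1] == 0))


@dataclass(frozen=True)
class EnsembleSummary:
    scenario: str
    n_pops: int
    lambda_quantiles: dict[str, float]   # keys "2.5", "25", "50", "75", "97.5"
    prop_not_self_sustaining: float
    mean_lambda: float

    def __post_init__(self) -> None:
        q = [self.lambda_quantiles[k] for k in ("2.5", "25", "50", "75", "97.5")]
        if any(b < a - 1e-12 for a, b in zip(q, q[1:])):
            raise ValueError("lambda quantiles must be monotone")
        if not 0.0 <= self.prop_not_self_sustaining <= 1.0:
            raise ValueError("proportion must be in [0, 1]")


def run_ensemble(
    model: DemographicModel,
    scenarios: Sequence[tuple[str, DisturbanceCovariates]],
    options: SimulationOptions,
    n_pops: int = 500,
    stratified: bool = True,
    return_lambdas: bool = False,
):
    """Simulate n_pops populations under each scenario with persistent quantiles.

    Quantiles are sampled once and reused for every scenario, so a
    population keeps its rank in the national distribution as disturbance
    changes.  Each population runs on its own RNG stream derived from the
    ensemble seed and the population index, making results independent of
    execution order.  Returns one :class:`EnsembleSummary` per scenario
    (plus the raw per-population realized λ arrays if requested).
    """
    if not scenarios:
        raise ValueError("at least one scenario required")
    if n_pops <= 0:
        raise ValueError("n_pops must be >= 1")
    labels = [s[0] for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate scenario labels: {labels}")

    quantiles = sample_population_quantiles(n_pops, seed=options.seed, stratified=stratified)
    summaries: list[EnsembleSummary] = []
    all_lambdas: dict[str, np.ndarray] = {}
    for label, cov in scenarios:
        lams = np.empty(n_pops)
        for i, pq in enumerate(quantiles):
            S_pop, R_pop = rates_at_quantile(model, cov, pq)
            # stream depends on (seed, population) only: scenarios are paired
            rng = np.random.default_rng(
                np.random.SeedSequence([int(options.seed), i])
            )
            traj = simulate_population((S_pop, R_pop), options, rng=rng)
            lams[i] = realized_lambda(traj)
        qs = np.quantile(lams, [0.025, 0.25, 0.50, 0.75, 0.975])
        summaries.append(
            EnsembleSummary(
                scenario=label,
                n_pops=n_pops,
                lambda_quantiles={
                    "2.5": float(qs[0]),
                    "25": float(qs[1]),
                    "50": float(qs[2]),
                    "75": float(qs[3]),
                    "97.5": float(qs[4]),
                },
                prop_not_self_sustaining=float(
                    np.mean(lams < options.self_sustaining_threshold)
                ),
                mean_lambda=float(lams.mean()),
            )
        )
        all_lambdas[label] = lams
    if return_lambdas:
        return summaries, all_lambdas
    return summaries
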