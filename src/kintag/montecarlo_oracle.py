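"""Finite-population agent-based realization of the identical lifecycle.

Explicit individuals, stochastic encounter loops, Bernoulli infection,
and fitness-proportional multinomial reproduction with free
recombination.  Used as an independent validation oracle for the
deterministic recursion: as N grows the per-generation discrepancy
between the two shrinks proportionally to 1/sqrt(N).

Clone encounters instantiate an exact genotype copy of the focal
individual.  The benefit a helper donates to its clone is credited back
to the focal itself, which reproduces the mean-field per-capita
accounting exactly (clone donations by genotype g equal clone receipts
by genotype g) and conserves the help budget at finite N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .genotype_core import (
    AX_RESIST,
    HELP,
    USE_RESIST,
    GenotypeSpace,
    InitSpec,
    ModelParams,
    PopulationState,
    ResistHistory,
    build_space,
)
from .observables import ObservableRecord, snapshot
from .parasite_dynamics import lagged_frequencies

__all__ = ["AgentPopulation", "FiniteTrajectory", "simulate_finite",
           "sample_population", "finite_step", "population_state"]

_MAX_RETRIES = 10_000


@dataclass
class AgentPopulation:
    """N haploid individuals as per-locus integer arrays."""

    resist: np.ndarray
    neutral: np.ndarray
    choice: np.ndarray
    trait: np.ndarray
    generation: int = 0

    @property
    def size(self) -> int:
        return self.resist.size

    def copy(self) -> "AgentPopulation":
        return AgentPopulation(self.resist.copy(), self.neutral.copy(),
                               self.choice.copy(), self.trait.copy(),
                               self.generation)


def sample_population(space: GenotypeSpace, init: InitSpec, N: int,
                      rng: np.random.Generator) -> AgentPopulation:
    """Multinomial draw of N individuals from the product measure of the
    initial-frequency specification (the perturbation epsilon is not
    applied: sampling noise already breaks the symmetry)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    xr = (np.full(space.L_resist, 1.0 / space.L_resist)
          if init.resist_freqs is None else np.asarray(init.resist_freqs, float))
    xn = (np.full(space.L_neutral, 1.0 / space.L_neutral)
          if init.neutral_freqs is None else np.asarray(init.neutral_freqs, float))
    return AgentPopulation(
        resist=rng.choice(space.L_resist, N, p=xr / xr.sum()),
        neutral=rng.choice(space.L_neutral, N, p=xn / xn.sum()),
        choice=(rng.random(N) >= init.q0).astype(np.int64),  # 0=USE_RESIST w.p. q0
        trait=(rng.random(N) < init.p0).astype(np.int64),
    )


def population_state(pop: AgentPopulation, space: GenotypeSpace) -> PopulationState:
    """Empirical genotype-frequency vector of an agent population."""
    idx = space.encode(pop.resist, pop.neutral, pop.choice, pop.trait)
    counts = np.bincount(idx, minlength=space.size)
    return PopulationState(counts / pop.size, pop.generation)


def _run_encounters(pop: AgentPopulation, params: ModelParams,
                    rng: np.random.Generator):
    """Realize every individual's social search for one generation.

    Returns (helped_out: bool array -- focal found a match and helps;
    received: int array -- number of help units landing on each agent).
    """
    N = pop.size
    helped_out = np.zeros(N, dtype=bool)
    received = np.zeros(N, dtype=np.int64)
    active = np.arange(N)
    for _ in range(_MAX_RETRIES):
        if active.size == 0:
            return helped_out, received
        clone = rng.random(active.size) < params.theta
        # uniform draw among the N-1 *other* individuals
        partner = rng.integers(0, N - 1, active.size)
        partner += partner >= active
        use_resist = pop.choice[active] == USE_RESIST
        own_tag = np.where(use_resist, pop.resist[active], pop.neutral[active])
        partner_tag = np.where(use_resist, pop.resist[partner], pop.neutral[partner])
        match = clone | (own_tag == partner_tag)
        helper = pop.trait[active] == HELP
        donates = match & helper
        helped_out[active[donates]] = True
        # clone receipts credit the focal; nonrelative receipts credit the partner
        received[active[donates & clone]] += 1
        np.add.at(received, partner[donates & ~clone], 1)
        unmatched = ~match
        retry = unmatched & (rng.random(active.size) < params.alpha)
        active = active[retry]
    raise RuntimeError(
        f"encounter loop exceeded {_MAX_RETRIES} retries "
        "(alpha=1 with no matching tag reachable)"
    )


def finite_step(pop: AgentPopulation, history: ResistHistory,
                params: ModelParams, space: GenotypeSpace,
                rng: np.random.Generator) -> AgentPopulation:
    """One full stochastic generation; appends the new census to history."""
    N = pop.size
    helped_out, received = _run_encounters(pop, params, rng)
    Z = np.asarray(lagged_frequencies(history, params.lag), dtype=float)
    infected = rng.random(N) < Z[pop.resist]
    fec = (1.0 - params.c * helped_out + params.b * received) * (1.0 - params.d * infected)
    if np.any(fec < 0):
        raise ValueError("negative fecundity: parameters outside the model's assumptions")
    total = fec.sum()
    if total <= 0:
        raise ValueError("population fecundity collapsed to zero")
    w = fec / total

    p1 = rng.choice(N, N, p=w)
    p2 = rng.choice(N, N, p=w)
    mask = rng.random((N, 4)) < 0.5  # locus from parent 1 where True
    resist = np.where(mask[:, 0], pop.resist[p1], pop.resist[p2])
    neutral = np.where(mask[:, 1], pop.neutral[p1], pop.neutral[p2])
    choice = np.where(mask[:, 2], pop.choice[p1], pop.choice[p2])
    trait = np.where(mask[:, 3], pop.trait[p1], pop.trait[p2])
    choice ^= rng.random(N) < params.mu_choice
    trait ^= rng.random(N) < params.mu_trait

    new = AgentPopulation(resist, neutral, choice.astype(np.int64),
                          trait.astype(np.int64), pop.generation + 1)
    history.append(np.bincount(new.resist, minlength=space.L_resist) / N)
    return new


@dataclass
class FiniteTrajectory:
    records: List[ObservableRecord]
    final_population: AgentPopulation
    history: ResistHistory


def simulate_finite(
    params: ModelParams,
    N: int,
    generations: int,
    seed: int,
    init: Optional[InitSpec] = None,
    initial: Optional[AgentPopulation] = None,
    record_every: int = 1,
) -> FiniteTrajectory:
    """Run the agent-based lifecycle for a fixed number of generations.

    Deterministic given ``seed``.  ``initial`` overrides the multinomial
    draw from ``init`` (useful for paired oracle comparisons).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not isinstance(seed, (int, np.integer)):
        raise ValueError("seed must be an integer")
    rng = np.random.default_rng(seed)
    space = build_space(params.L_resist, params.L_neutral)
    if initial is not None:
        pop = initial.copy()
        if pop.size != N:
            raise ValueError("initial population size differs from N")
    else:
        pop = sample_population(space, init or InitSpec(), N, rng)
    history = ResistHistory(np.bincount(pop.resist, minlength=space.L_resist) / N,
                            params.lag)
    records = [snapshot(population_state(pop, space), history, params, space, per_tag=False)]
    for gen in range(1, generations + 1):
        pop = finite_step(pop, history, params, space, rng)
        if gen % record_every == 0 or gen == generations:
            records.append(snapshot(population_state(pop, space), history,
                                    params, space, per_tag=False))
    return FiniteTrajectory(records=records, final_population=pop, history=history)
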