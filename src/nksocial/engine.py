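"""Synchronous simulation engine.

Each repetition places ``n`` agents with independent uniform-random starting
solutions on a fixed network over a freshly drawn NK landscape, then iterates
``t`` synchronous steps: every agent first applies its social-learning
strategy to a sample of its contacts' *start-of-step* solutions, adopts the
socially identified solution if it strictly beats its own payoff, and
otherwise (or when the strategy yields no decision) takes one hill-climbing
step.  All updates commit simultaneously; the population mean payoff and the
number of distinct solutions are recorded after each step.

The production path encodes genotypes as integers and steps whole
populations with numpy array operations against the landscape's payoff
cache; :func:`step_reference` is a naive per-agent implementation of the same
rules, kept for cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .landscape import NKLandscape, index_to_bits
from .strategies import (
    NO_DECISION,
    AgentState,
    StrategySpec,
    critical_social_update,
    decide_best_member,
    decide_conformity,
    individual_learning_step,
    random_copy_update,
    sample_contacts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TimeSeriesResult",
    "init_population",
    "neighbor_matrix",
    "step_codes",
    "step_reference",
    "run",
]


@dataclass
class SimulationConfig:
    """Full description of one simulation cell."""

    strategy: StrategySpec
    network: nx.Graph
    N: int = 15
    K: int = 7
    n_agents: int = 100
    t_steps: int = 200
    repetitions: int = 1000
    master_seed: int = 0
    update: str = "synchronous"
    landscape_seeds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.t_steps < 1 or self.repetitions < 1:
            raise ValueError("t_steps and repetitions must be >= 1")
        if self.network.number_of_nodes() != self.n_agents:
            raise ValueError(
                f"network has {self.network.number_of_nodes()} nodes, "
                f"config expects n_agents={self.n_agents}"
            )
        if self.update not in ("synchronous", "asynchronous"):
            raise ValueError("update must be 'synchronous' or 'asynchronous'")
        degrees = [deg for _, deg in self.network.degree()]
        min_deg = min(degrees)
        s = self.strategy.sample_size
        if self.strategy.rule in ("best_member", "conformity") and s > min_deg:
            raise ValueError(
                f"sample size s={s} exceeds the minimum network degree {min_deg}"
            )
        if self.strategy.rule == "random_copy" and min_deg < 1:
            raise ValueError("random_copy requires every agent to have a neighbour")


@dataclass
class TimeSeriesResult:
    """Per-step population statistics, averaged over repetitions."""

    mean_payoff: np.ndarray
    unique_solutions: np.ndarray
    per_repetition_final: np.ndarray
    metadata: dict = field(default_factory=dict)


def init_population(landscape: NKLandscape, n: int, rng: np.random.Generator):
    """``n`` agents at independent uniform-random genotypes with cached payoffs."""
    codes = init_codes(landscape, n, rng)
    return [
        AgentState(
            id=i,
            genotype=index_to_bits(int(c), landscape.N),
            payoff=float(landscape.payoff_cache[c]),
        )
        for i, c in enumerate(codes)
    ]


def init_codes(landscape: NKLandscape, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2**landscape.N, size=n, dtype=np.int64)


def neighbor_matrix(net: nx.Graph) -> np.ndarray:
    """(n, d) array of neighbour ids; requires a regular graph on nodes 0..n-1."""
    n = net.number_of_nodes()
    if sorted(net.nodes()) != list(range(n)):
        raise ValueError("engine networks must be labelled 0..n-1")
    degrees = {deg for _, deg in net.degree()}
    if len(degrees) != 1:
        raise ValueError("engine requires a regular network (uniform degree)")
    d = degrees.pop()
    mat = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        mat[i] = sorted(net.neighbors(i))
    return mat


# ----------------------------------------------------------- vectorised step

def _sample_columns(n: int, d: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """For each of n agents, s distinct column indices into its neighbour row,
    uniformly without replacement and in uniformly random order."""
    keys = rng.random((n, d))
    return np.argpartition(keys, s - 1, axis=1)[:, :s]


def step_codes(
    codes: np.ndarray,
    nbrs: np.ndarray,
    landscape: NKLandscape,
    strategy: StrategySpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous step on integer-encoded genotypes; returns new codes."""
    n = codes.size
    d = nbrs.shape[1]
    cache = landscape.payoff_cache
    pay = cache[codes]
    rows = np.arange(n)
    rule = strategy.rule

    if rule == "random_copy":
        cols = rng.integers(0, d, size=n)
        cand = codes[nbrs[rows, cols]]
        adopt = cache[cand] > pay
        return np.where(adopt, cand, codes)

    if rule == "individual":
        adopt = np.zeros(n, dtype=bool)
        cand = codes
        needs_il = ~adopt
    else:
        s = strategy.sample_size
        cols = _sample_columns(n, d, s, rng)
        obs = codes[nbrs[rows[:, None], cols]]  # (n, s) observed codes
        if rule == "best_member":
            obs_pay = cache[obs]
            # sample order is uniformly random, so first-argmax breaks payoff
            # ties uniformly among the tied contacts
            j = np.argmax(obs_pay, axis=1)
            cand = obs[rows, j]
            decided = np.ones(n, dtype=bool)
        else:  # conformity
            cnt = (obs[:, :, None] == obs[:, None, :]).sum(axis=2)
            top = cnt.max(axis=1)
            j = np.argmax(cnt, axis=1)
            cand = obs[rows, j]
            tie = ((cnt == top[:, None]) & (obs != cand[:, None])).any(axis=1)
            decided = ~tie
        adopt = decided & (cache[cand] > pay)
        needs_il = ~adopt

    # hill-climbing step for everyone who did not adopt socially
    bits = rng.integers(0, landscape.N, size=n)
    flipped = codes ^ (np.int64(1) << bits)
    improve = cache[flipped] > pay
    new = np.where(adopt, cand, np.where(needs_il & improve, flipped, codes))
    return new


# ------------------------------------------------------------ reference step

def step_reference(population, net, landscape, strategy, rng):
    """Naive synchronous step built from the per-agent strategy functions.

    Reads every observation from the start-of-step population and commits all
    updates at the end; exists as the semantic reference for the vectorised
    kernel and for the asynchronous mode.
    """
    new_population = []
    for agent in population:
        new_population.append(
            _update_one(agent, population, net, landscape, strategy, rng)
        )
    return new_population


def _update_one(agent, population, net, landscape, strategy, rng):
    rule = strategy.rule
    if rule == "individual":
        return individual_learning_step(agent, landscape, rng)
    if rule == "random_copy":
        return random_copy_update(agent, population, net, landscape, rng)
    contacts = sample_contacts(agent.id, net, strategy.sample_size, rng)
    samples = [(population[c].genotype, population[c].payoff) for c in contacts]
    if rule == "best_member":
        candidate = decide_best_member(samples, rng)
    else:
        candidate = decide_conformity(samples)
    return critical_social_update(agent, candidate, landscape, rng)


# --------------------------------------------------------------------- run

def _landscape_seeds(master_seed: int, repetitions: int) -> np.ndarray:
    """Deterministic per-repetition landscape seeds derived from a master seed."""
    return np.random.default_rng([master_seed, 0x1A5D]).integers(
        0, 2**31 - 1, size=repetitions
    )


def run(config: SimulationConfig) -> TimeSeriesResult:
    """Execute all repetitions of a cell and average the recorded series.

    Every repetition draws a fresh landscape (seed from
    ``config.landscape_seeds`` or derived from the master seed) and a fresh
    starting population; the network topology is fixed.  Bit-reproducible for
    a given config and master seed.
    """
    reps = config.repetitions
    t_steps = config.t_steps
    ls_seeds = config.landscape_seeds
    if ls_seeds is None:
        ls_seeds = _landscape_seeds(config.master_seed, reps)
    if len(ls_seeds) < reps:
        raise ValueError("need one landscape seed per repetition")
    nbrs = neighbor_matrix(config.network)

    mean_payoff = np.zeros(t_steps)
    unique_solutions = np.zeros(t_steps)
    finals = np.zeros(reps)
    sim_rngs = np.random.default_rng([config.master_seed, 0x51E9]).spawn(reps)

    for r in range(reps):
        landscape = NKLandscape.generate(config.N, config.K, seed=int(ls_seeds[r]))
        rng = sim_rngs[r]
        codes = init_codes(landscape, config.n_agents, rng)
        if config.update == "synchronous":
            for t in range(t_steps):
                codes = step_codes(codes, nbrs, landscape, config.strategy, rng)
                mean_payoff[t] += landscape.payoff_cache[codes].mean()
                unique_solutions[t] += np.unique(codes).size
        else:
            population = [
                AgentState(
                    id=i,
                    genotype=index_to_bits(int(c), landscape.N),
                    payoff=float(landscape.payoff_cache[c]),
                )
                for i, c in enumerate(codes)
            ]
            for t in range(t_steps):
                order = rng.permutation(config.n_agents)
                for i in order:
                    population[i] = _update_one(
                        population[i], population, config.network, landscape,
                        config.strategy, rng,
                    )
                mean_payoff[t] += np.mean([a.payoff for a in population])
                unique_solutions[t] += len(
                    {tuple(a.genotype.tolist()) for a in population}
                )
                codes = None
        if config.update == "synchronous":
            finals[r] = landscape.payoff_cache[codes].mean()
        else:
            finals[r] = np.mean([a.payoff for a in population])
        logger.info(
            "repetition %d/%d (%s on %s): final mean payoff %.4f",
            r + 1, reps, config.strategy.label,
            config.network.graph.get("name", "unnamed"), finals[r],
        )

    mean_payoff /= reps
    unique_solutions /= reps
    metadata = {
        "strategy": config.strategy.label,
        "network": config.network.graph.get("name", "unnamed"),
        "N": config.N,
        "K": config.K,
        "n_agents": config.n_agents,
        "t_steps": t_steps,
        "repetitions": reps,
        "master_seed": config.master_seed,
        "update": config.update,
    }
    return TimeSeriesResult(
        mean_payoff=mean_payoff,
        unique_solutions=unique_solutions,
        per_repetition_final=finals,
        metadata=metadata,
    )
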