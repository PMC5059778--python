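"""Social-learning strategy building blocks.

A strategy is composed of a search rule (sample random network contacts),
a stopping rule (stop after ``s`` contacts) and a decision rule:

* ``best_member`` — copy the highest-payoff solution in the sample
  (payoff-biased transmission);
* ``conformity`` — copy the most frequent solution in the sample
  (frequency-dependent transmission); any tie for the top frequency yields
  no decision and routes the agent to individual learning;
* ``random_copy`` — pure social baseline: observe one random contact and
  adopt its solution only if strictly better, never innovate;
* ``individual`` — pure individual baseline: hill climbing only.

All social strategies other than random copying are "critical": a socially
identified solution is adopted only if it strictly beats the agent's current
payoff, and otherwise the agent takes one hill-climbing step (flip one random
bit, keep it only on strict improvement).

These per-agent functions define the model semantics; the vectorised engine
in :mod:`nksocial.engine` implements the same rules over whole populations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landscape import NKLandscape

__all__ = [
    "NO_DECISION",
    "StrategySpec",
    "AgentState",
    "RULES",
    "sample_contacts",
    "decide_best_member",
    "decide_conformity",
    "individual_learning_step",
    "critical_social_update",
    "random_copy_update",
]

RULES = ("best_member", "conformity", "random_copy", "individual")

#: sentinel returned by a decision rule that could not single out a solution
NO_DECISION = None


@dataclass(frozen=True)
class StrategySpec:
    """Decision rule plus sample size ``s`` (ignored for the pure baselines)."""

    rule: str
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {RULES}")
        if self.rule in ("best_member", "conformity"):
            if self.sample_size is None or self.sample_size < 1:
                raise ValueError(f"{self.rule} needs a sample size >= 1")

    @property
    def label(self) -> str:
        if self.rule in ("best_member", "conformity"):
            return f"{self.rule}_s{self.sample_size}"
        return self.rule


@dataclass(frozen=True)
class AgentState:
    """One agent: node id, current solution, and its cached transformed payoff."""

    id: int
    genotype: np.ndarray
    payoff: float


def sample_contacts(agent_id: int, net, s: int, rng: np.random.Generator) -> list[int]:
    """``s`` distinct neighbours of ``agent_id``, uniformly without replacement."""
    neighbors = sorted(net.neighbors(agent_id))
    if s > len(neighbors):
        raise ValueError(
            f"sample size s={s} exceeds degree {len(neighbors)} of agent {agent_id}"
        )
    picks = rng.choice(len(neighbors), size=s, replace=False)
    return [neighbors[i] for i in picks]


def decide_best_member(samples, rng: np.random.Generator):
    """Genotype with the maximal payoff in the sample; ties broken uniformly."""
    if not samples:
        raise ValueError("empty sample")
    payoffs = np.array([p for _, p in samples])
    top = np.flatnonzero(payoffs == payoffs.max())
    choice = top[rng.integers(len(top))]
    return samples[choice][0]


def decide_conformity(samples):
    """Unique modal genotype, or :data:`NO_DECISION` on any tie for the top count."""
    if not samples:
        raise ValueError("empty sample")
    counts: dict[tuple, list] = {}
    for genotype, _ in samples:
        key = tuple(np.asarray(genotype).tolist())
        if key in counts:
            counts[key][0] += 1
        else:
            counts[key] = [1, genotype]
    best = max(c for c, _ in counts.values())
    modal = [g for c, g in counts.values() if c == best]
    if len(modal) != 1:
        return NO_DECISION
    return modal[0]


def individual_learning_step(
    agent: AgentState, landscape: NKLandscape, rng: np.random.Generator
) -> AgentState:
    """Flip one uniformly chosen bit; keep the change only on strict improvement."""
    bit = int(rng.integers(landscape.N))
    candidate = agent.genotype.copy()
    candidate[bit] ^= 1
    payoff = landscape.transformed_payoff(candidate)
    if payoff > agent.payoff:
        return replace(agent, genotype=candidate, payoff=payoff)
    return agent


def critical_social_update(
    agent: AgentState,
    candidate,
    landscape: NKLandscape,
    rng: np.random.Generator,
) -> AgentState:
    """Adopt the socially identified solution iff strictly better; else hill climb."""
    if candidate is not NO_DECISION:
        payoff = landscape.transformed_payoff(candidate)
        if payoff > agent.payoff:
            return replace(agent, genotype=np.asarray(candidate).copy(), payoff=payoff)
    return individual_learning_step(agent, landscape, rng)


def random_copy_update(
    agent: AgentState,
    population,
    net,
    landscape: NKLandscape,
    rng: np.random.Generator,
) -> AgentState:
    """Observe one random contact; adopt iff strictly better.  Never innovates."""
    contact = sample_contacts(agent.id, net, 1, rng)[0]
    other = population[contact]
    if other.payoff > agent.payoff:
        return replace(agent, genotype=other.genotype.copy(), payoff=other.payoff)
    return agent
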