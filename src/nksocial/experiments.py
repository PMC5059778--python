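"""Experiment grids and headline analyses.

Two grids reproduce the study design:

* the *strategy grid*: six strategies (best member and conformity at sample
  sizes 3 and 9, random copying, pure individual learning) on the fully
  connected network, in a smooth (K=0) and a rugged (K=7) environment;
* the *network grid*: the two best complex-task strategies (best member s=3,
  conformity s=3) on the ten-network ensemble, plus the efficiency-class
  contrast and the Pearson correlation between network diameter and final
  mean payoff.

Within a grid every cell uses the same per-repetition landscape seeds
(a paired design), so between-cell contrasts are not inflated by
landscape-to-landscape variance; sampling and initialisation streams remain
independent per cell.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimulationConfig, TimeSeriesResult, run
from .networks import classify_efficiency, diameter, generate_ensemble, make_fully_connected
from .strategies import StrategySpec

__all__ = [
    "SIX_STRATEGIES",
    "strategy_grid",
    "network_grid",
    "build_ensemble",
    "class_means",
    "diameter_correlation",
    "summarize_variability",
    "time_to_single_solution",
]

SIX_STRATEGIES = (
    StrategySpec("best_member", 3),
    StrategySpec("best_member", 9),
    StrategySpec("conformity", 3),
    StrategySpec("conformity", 9),
    StrategySpec("random_copy"),
    StrategySpec("individual"),
)

SMALL_SAMPLE_PAIR = (StrategySpec("best_member", 3), StrategySpec("conformity", 3))


def _cell_seed(master_seed: int, *tags: str) -> int:
    """Deterministic per-cell seed below 2^31 derived from a master seed."""
    digest = hashlib.sha256("|".join(tags).encode()).digest()
    tag_int = int.from_bytes(digest[:4], "little")
    h = np.random.default_rng([master_seed, tag_int])
    return int(h.integers(0, 2**31 - 1))


def _landscape_seeds(master_seed: int, repetitions: int) -> np.ndarray:
    return np.random.default_rng([master_seed, 0x7A9]).integers(
        0, 2**31 - 1, size=repetitions
    )


def strategy_grid(
    seed: int,
    K_values=(0, 7),
    strategies=SIX_STRATEGIES,
    N: int = 15,
    n_agents: int = 100,
    t_steps: int = 200,
    repetitions: int = 100,
) -> dict[tuple[str, int], TimeSeriesResult]:
    """All strategies on the fully connected network, one cell per (strategy, K)."""
    net = make_fully_connected(n_agents)
    ls_seeds = _landscape_seeds(seed, repetitions)
    out: dict[tuple[str, int], TimeSeriesResult] = {}
    for K in K_values:
        for strat in strategies:
            config = SimulationConfig(
                strategy=strat,
                network=net,
                N=N,
                K=K,
                n_agents=n_agents,
                t_steps=t_steps,
                repetitions=repetitions,
                master_seed=_cell_seed(seed, strat.label, f"K{K}"),
                landscape_seeds=ls_seeds,
            )
            out[(strat.label, K)] = run(config)
    return out


def build_ensemble(seed: int, n: int = 100, d: int = 19,
                   rewire_iters: dict | int | None = None, restarts: int = 1,
                   budget_scale: float = 1.0):
    """Ten-network ensemble plus diameters and efficiency classes."""
    nets = generate_ensemble(seed, n=n, d=d, rewire_iters=rewire_iters,
                             restarts=restarts, budget_scale=budget_scale)
    classes = classify_efficiency(nets)
    records = {
        name: {"graph": g, "diameter": diameter(g), "efficiency": classes[name]}
        for name, g in nets.items()
    }
    return records


def network_grid(
    seed: int,
    ensemble,
    strategies=SMALL_SAMPLE_PAIR,
    N: int = 15,
    K: int = 7,
    t_steps: int = 200,
    repetitions: int = 100,
) -> pd.DataFrame:
    """Run each strategy on each ensemble network; one row per cell.

    Columns: strategy, network, diameter, efficiency, final_mean_payoff, sem.
    """
    ls_seeds = _landscape_seeds(seed, repetitions)
    rows = []
    for strat in strategies:
        for name, rec in ensemble.items():
            g = rec["graph"]
            config = SimulationConfig(
                strategy=strat,
                network=g,
                N=N,
                K=K,
                n_agents=g.number_of_nodes(),
                t_steps=t_steps,
                repetitions=repetitions,
                master_seed=_cell_seed(seed, strat.label, name),
                landscape_seeds=ls_seeds,
            )
            result = run(config)
            rows.append(
                {
                    "strategy": strat.label,
                    "network": name,
                    "diameter": rec["diameter"],
                    "efficiency": rec["efficiency"],
                    "final_mean_payoff": float(result.mean_payoff[-1]),
                    "sem": summarize_variability(result.per_repetition_final),
                }
            )
    return pd.DataFrame(rows)


def class_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean final payoff per (strategy, efficiency class)."""
    return (
        records.groupby(["strategy", "efficiency"])["final_mean_payoff"]
        .mean()
        .reset_index()
    )


def diameter_correlation(records: pd.DataFrame | list) -> float:
    """Pearson r between network diameter and final mean payoff."""
    if isinstance(records, pd.DataFrame):
        diams = records["diameter"].to_numpy(dtype=float)
        payoffs = records["final_mean_payoff"].to_numpy(dtype=float)
    else:
        diams = np.array([r[0] for r in records], dtype=float)
        payoffs = np.array([r[1] for r in records], dtype=float)
    if len(diams) < 3:
        raise ValueError("need at least 3 networks for a correlation")
    if np.ptp(diams) == 0:
        raise ValueError("correlation undefined for constant diameters")
    return float(stats.pearsonr(diams, payoffs).statistic)


def summarize_variability(per_repetition_final: np.ndarray) -> float:
    """Standard error of the mean across repetitions (ddof=1)."""
    x = np.asarray(per_repetition_final, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 repetitions for a standard error")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def time_to_single_solution(result: TimeSeriesResult, tol: float = 0.05) -> int | None:
    """First step at which the mean unique-solution count is within ``tol`` of 1."""
    hit = np.flatnonzero(result.unique_solutions <= 1.0 + tol)
    return int(hit[0]) + 1 if hit.size else None
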