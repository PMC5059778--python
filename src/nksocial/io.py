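"""Configuration files and result serialisation.

Configs are YAML.  A minimal config only names the landscape and strategy;
group size (n=100), degree (d=19) and run length (t=200) default to the
study's values::

    landscape: {N: 15, K: 7}
    strategy: {rule: conformity, sample_size: 3}
    network: {kind: complete}          # or ring_lattice / edgelist {path: ...}
    simulation: {repetitions: 100, master_seed: 1}

Results go to a tidy CSV (one row per time step) with a JSON metadata
sidecar; ``read_results(write_results(x))`` reproduces the series to full
float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationConfig, TimeSeriesResult
from .networks import make_fully_connected, make_ring_lattice, read_edgelist
from .strategies import StrategySpec

__all__ = ["load_config", "write_config", "write_results", "read_results"]

DEFAULTS = {"n_agents": 100, "degree": 19, "t_steps": 200, "repetitions": 1000}


class ConfigError(ValueError):
    """Invalid configuration; message carries the offending field path."""


def _require(mapping, key, path):
    if key not in mapping:
        raise ConfigError(f"{path}.{key}: missing required field")
    return mapping[key]


def _build_network(spec: dict, n_agents: int, degree: int):
    kind = spec.get("kind", "complete")
    if kind == "complete":
        return make_fully_connected(n_agents)
    if kind == "ring_lattice":
        return make_ring_lattice(n_agents, spec.get("d", degree))
    if kind == "edgelist":
        path = _require(spec, "path", "network")
        return read_edgelist(path, n=n_agents)
    raise ConfigError(f"network.kind: unknown kind {kind!r}")


def load_config(path) -> SimulationConfig:
    """Parse and validate a simulation config, filling study defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    land = _require(raw, "landscape", "config")
    N = _require(land, "N", "landscape")
    K = _require(land, "K", "landscape")
    strat_raw = _require(raw, "strategy", "config")
    try:
        strategy = StrategySpec(
            _require(strat_raw, "rule", "strategy"), strat_raw.get("sample_size")
        )
    except ValueError as err:
        raise ConfigError(f"strategy: {err}") from err
    sim = raw.get("simulation", {})
    n_agents = sim.get("n_agents", DEFAULTS["n_agents"])
    network = _build_network(raw.get("network", {}), n_agents, DEFAULTS["degree"])
    try:
        return SimulationConfig(
            strategy=strategy,
            network=network,
            N=N,
            K=K,
            n_agents=n_agents,
            t_steps=sim.get("t_steps", DEFAULTS["t_steps"]),
            repetitions=sim.get("repetitions", DEFAULTS["repetitions"]),
            master_seed=sim.get("master_seed", 0),
            update=sim.get("update", "synchronous"),
        )
    except ValueError as err:
        raise ConfigError(str(err)) from err


def write_config(config: SimulationConfig, path) -> None:
    """Serialise a config back to YAML (complete / ring_lattice networks only)."""
    kind = config.network.graph.get("name")
    if kind not in ("complete", "ring_lattice"):
        raise ValueError(
            "only complete/ring_lattice networks round-trip through YAML; "
            "save other networks as edge lists and reference them by path"
        )
    net: dict = {"kind": kind}
    if kind == "ring_lattice":
        net["d"] = next(iter(dict(config.network.degree()).values()))
    payload = {
        "landscape": {"N": config.N, "K": config.K},
        "strategy": {"rule": config.strategy.rule},
        "network": net,
        "simulation": {
            "n_agents": config.n_agents,
            "t_steps": config.t_steps,
            "repetitions": config.repetitions,
            "master_seed": config.master_seed,
            "update": config.update,
        },
    }
    if config.strategy.sample_size is not None:
        payload["strategy"]["sample_size"] = config.strategy.sample_size
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def write_results(result: TimeSeriesResult, path) -> None:
    """Tidy CSV (strategy, network, N, K, s, t, mean_payoff, unique_solutions)
    plus ``<path>.meta.json`` carrying the config echo and per-rep finals."""
    path = Path(path)
    meta = result.metadata
    strategy = meta.get("strategy", "")
    s = strategy.rsplit("_s", 1)[1] if "_s" in strategy else ""
    t = np.arange(1, len(result.mean_payoff) + 1)
    frame = pd.DataFrame(
        {
            "strategy": strategy,
            "network": meta.get("network", ""),
            "N": meta.get("N", ""),
            "K": meta.get("K", ""),
            "s": s,
            "t": t,
            "mean_payoff": result.mean_payoff,
            "unique_solutions": result.unique_solutions,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "metadata": meta,
        "per_repetition_final": result.per_repetition_final.tolist(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar))


def read_results(path) -> TimeSeriesResult:
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed results file {path}: {err}") from err
    sidecar = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return TimeSeriesResult(
        mean_payoff=frame["mean_payoff"].to_numpy(),
        unique_solutions=frame["unique_solutions"].to_numpy(),
        per_repetition_final=np.array(sidecar["per_repetition_final"]),
        metadata=sidecar["metadata"],
    )
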