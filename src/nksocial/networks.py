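"""Communication-network construction, graph measures and rewiring optimisation.

The simulated groups sit on one of ten undirected networks of n=100 nodes:
a complete graph (every degree n-1), a locally connected ring lattice with
degree d=19, and eight networks obtained by degree-preserving double-edge-swap
hill climbing that maximises or minimises the population mean of one of four
per-node measures: closeness centrality, betweenness centrality, clustering
coefficient, or Burt's structural constraint.

Graphs are ``networkx.Graph`` objects throughout; measure evaluation inside
the hill climb goes through igraph's C routines (numerically identical to the
networkx implementations for these graphs) because a climb evaluates the
measure once per candidate swap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np

__all__ = [
    "MeasureSpec",
    "MEASURES",
    "MEASURE_SPECS",
    "make_fully_connected",
    "make_ring_lattice",
    "graph_measure",
    "diameter",
    "rewire_optimize",
    "random_regular_connected",
    "generate_ensemble",
    "classify_efficiency",
    "write_edgelist",
    "read_edgelist",
]

MEASURES = ("closeness", "betweenness", "clustering", "constraint")
DIRECTIONS = ("maximize", "minimize")


@dataclass(frozen=True)
class MeasureSpec:
    """A per-node graph statistic (averaged over nodes) and an optimisation direction."""

    measure: str
    direction: str

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; choose from {MEASURES}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "maximize" else -1

    @property
    def name(self) -> str:
        return f"{'max' if self.direction == 'maximize' else 'min'}_{self.measure}"


#: the eight extremised-network specifications
MEASURE_SPECS = tuple(
    MeasureSpec(m, d) for m in MEASURES for d in DIRECTIONS
)


# ------------------------------------------------------------- construction

def make_fully_connected(n: int) -> nx.Graph:
    """Complete graph on ``n`` nodes (every node adjacent to all others)."""
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got n={n}")
    g = nx.complete_graph(n)
    g.graph["name"] = "complete"
    return g


def make_ring_lattice(n: int, d: int) -> nx.Graph:
    """Ring lattice of degree exactly ``d``: each node tied to its nearest nodes.

    For even ``d`` this is the circulant graph with offsets 1..d/2 on both
    sides.  Odd ``d`` is not realisable as a circulant; each node gets the
    (d-1)/2 nearest nodes on both sides plus one edge at offset h=(d+1)/2,
    arranged as a perfect matching between alternating blocks of h consecutive
    nodes (requires ``n % 2h == 0``), so every node is tied to d of its 2h
    circularly nearest nodes.
    """
    if not (2 <= d < n):
        raise ValueError(f"need 2 <= d < n, got n={n}, d={d}")
    if (n * d) % 2 != 0:
        raise ValueError(f"no {d}-regular graph on {n} nodes exists (n*d odd)")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    half = d // 2
    for i in range(n):
        for k in range(1, half + 1):
            g.add_edge(i, (i + k) % n)
    if d % 2 == 1:
        h = half + 1
        if n % (2 * h) != 0:
            raise ValueError(
                f"odd-degree ring lattice needs n divisible by {2 * h} (n={n}, d={d})"
            )
        for i in range(n):
            if (i // h) % 2 == 0:
                g.add_edge(i, i + h)
    assert all(deg == d for _, deg in g.degree())
    g.graph["name"] = "ring_lattice"
    return g


def random_regular_connected(n: int, d: int, seed) -> nx.Graph:
    """Connected random d-regular graph (resamples the rare disconnected draws)."""
    rng = np.random.default_rng(seed)
    for _ in range(100):
        g = nx.random_regular_graph(d, n, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g
    raise RuntimeError(f"could not draw a connected {d}-regular graph on {n} nodes")


# ----------------------------------------------------------------- measures

def _to_igraph(net: nx.Graph) -> ig.Graph:
    idx = {v: i for i, v in enumerate(net.nodes())}
    return ig.Graph(n=net.number_of_nodes(), edges=[(idx[u], idx[v]) for u, v in net.edges()])


def _ig_measure(g: ig.Graph, measure: str) -> float:
    n = g.vcount()
    if measure == "closeness":
        return float(np.mean(g.closeness(normalized=True)))
    if measure == "betweenness":
        # normalised as in networkx: divide by (n-1)(n-2)/2 pair count
        return float(np.mean(g.betweenness()) * 2.0 / ((n - 1) * (n - 2)))
    if measure == "clustering":
        return float(np.mean(g.transitivity_local_undirected(mode="zero")))
    if measure == "constraint":
        return float(np.mean(g.constraint()))
    raise ValueError(f"unknown measure {measure!r}")


def graph_measure(net: nx.Graph, measure: str | MeasureSpec) -> float:
    """Mean over nodes of a per-node statistic (direction of a spec is ignored)."""
    if isinstance(measure, MeasureSpec):
        measure = measure.measure
    if not nx.is_connected(net):
        raise ValueError("graph measures require a connected graph")
    return _ig_measure(_to_igraph(net), measure)


def diameter(net: nx.Graph) -> int:
    """Longest shortest-path length between any pair of nodes."""
    if not nx.is_connected(net):
        raise ValueError("diameter is undefined for a disconnected graph")
    return int(nx.diameter(net))


# ------------------------------------------------------------------ rewiring

def _swap_candidates(edges, i, j, orient):
    """The two degree-preserving rewirings of edge pair (a,b),(c,d)."""
    a, b = edges[i]
    c, d = edges[j]
    if orient:
        return (a, c), (b, d)
    return (a, d), (b, c)


def _valid_new_edges(e1, e2, edge_set):
    for u, v in (e1, e2):
        if u == v:
            return False
        if (min(u, v), max(u, v)) in edge_set:
            return False
    # the two new edges must also differ from each other
    return frozenset(e1) != frozenset(e2)


def _climb_stochastic(edges, n, spec, max_iters, rng):
    """First-improvement hill climb over random double-edge swaps.

    Evaluates the measure on every candidate through igraph; the clustering
    measure instead uses an exact incremental triangle-count update, which is
    ~100x cheaper per candidate.
    """
    if spec.measure == "clustering":
        return _climb_clustering(edges, n, spec.sign, max_iters, rng)
    edges = [tuple(sorted(e)) for e in edges]
    edge_set = set(edges)
    cur = _ig_measure(ig.Graph(n=n, edges=edges), spec.measure)
    m = len(edges)
    for _ in range(max_iters):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        e1, e2 = _swap_candidates(edges, i, j, bool(rng.integers(2)))
        if not _valid_new_edges(e1, e2, edge_set):
            continue
        new_edges = list(edges)
        new_edges[i] = tuple(sorted(e1))
        new_edges[j] = tuple(sorted(e2))
        g = ig.Graph(n=n, edges=new_edges)
        if not g.is_connected():
            continue
        val = _ig_measure(g, spec.measure)
        if spec.sign * (val - cur) > 0:
            edge_set.discard(edges[i])
            edge_set.discard(edges[j])
            edges = new_edges
            edge_set.add(edges[i])
            edge_set.add(edges[j])
            cur = val
    return edges, cur


def _climb_clustering(edges, n, sign, max_iters, rng):
    """Clustering hill climb with exact incremental mean-clustering deltas.

    A double-edge swap only creates or destroys triangles through the four
    touched edges; each triangle (u, v, w) on an edge (u, v) contributes to
    the local clustering of u, v and w with weight 1/(deg(deg-1)) each, and
    degrees are swap-invariant, so the change in the population mean follows
    from the common-neighbour sets of the removed and added edges alone.
    Connectivity is verified (and the move rejected if broken) only for
    improving candidates.
    """
    edges = [tuple(sorted(e)) for e in edges]
    m = len(edges)
    A = np.zeros((n, n), dtype=bool)
    deg = np.zeros(n, dtype=np.int64)
    for u, v in edges:
        A[u, v] = A[v, u] = True
        deg[u] += 1
        deg[v] += 1
    with np.errstate(divide="ignore"):
        inv_b = np.where(deg >= 2, 1.0 / (deg * (deg - 1.0)), 0.0)

    def edge_delta(u, v, present_sign):
        # contribution of all triangles through edge (u, v) to the mean
        common = A[u] & A[v]
        c = int(common.sum())
        return present_sign * (c * (inv_b[u] + inv_b[v]) + inv_b[common].sum())

    for _ in range(max_iters):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        e1, e2 = _swap_candidates(edges, i, j, bool(rng.integers(2)))
        a, b = edges[i]
        c, d = edges[j]
        ok = True
        for u, v in (e1, e2):
            if u == v or A[u, v]:
                ok = False
                break
        if not ok or frozenset(e1) == frozenset(e2):
            continue
        delta = edge_delta(a, b, -1)
        A[a, b] = A[b, a] = False
        delta += edge_delta(c, d, -1)
        A[c, d] = A[d, c] = False
        delta += edge_delta(*e1, +1)
        A[e1[0], e1[1]] = A[e1[1], e1[0]] = True
        delta += edge_delta(*e2, +1)
        A[e2[0], e2[1]] = A[e2[1], e2[0]] = True
        if sign * delta > 0:
            new_edges = list(edges)
            new_edges[i] = tuple(sorted(e1))
            new_edges[j] = tuple(sorted(e2))
            if ig.Graph(n=n, edges=new_edges).is_connected():
                edges = new_edges
                continue
        # revert the adjacency updates
        A[e2[0], e2[1]] = A[e2[1], e2[0]] = False
        A[e1[0], e1[1]] = A[e1[1], e1[0]] = False
        A[a, b] = A[b, a] = True
        A[c, d] = A[d, c] = True
    cur = _ig_measure(ig.Graph(n=n, edges=edges), "clustering")
    return edges, cur


def _climb_best_improvement(edges, n, spec, max_iters):
    """Exhaustive best-improvement climb (tiny graphs only; used for validation)."""
    edges = [tuple(sorted(e)) for e in edges]
    cur = _ig_measure(ig.Graph(n=n, edges=edges), spec.measure)
    for _ in range(max_iters):
        edge_set = set(edges)
        best = None
        for i, j in itertools.combinations(range(len(edges)), 2):
            for orient in (True, False):
                e1, e2 = _swap_candidates(edges, i, j, orient)
                if not _valid_new_edges(e1, e2, edge_set):
                    continue
                new_edges = list(edges)
                new_edges[i] = tuple(sorted(e1))
                new_edges[j] = tuple(sorted(e2))
                g = ig.Graph(n=n, edges=new_edges)
                if not g.is_connected():
                    continue
                val = _ig_measure(g, spec.measure)
                if spec.sign * (val - cur) > 0 and (
                    best is None or spec.sign * (val - best[0]) > 0
                ):
                    best = (val, new_edges)
        if best is None:
            break
        cur, edges = best
    return edges, cur


def rewire_optimize(
    start: nx.Graph,
    spec: MeasureSpec,
    max_iters: int = 20_000,
    restarts: int = 20,
    seed=None,
    method: str = "stochastic",
) -> nx.Graph:
    """Extremise the mean of a node measure by degree-preserving rewiring.

    Each restart hill-climbs with double-edge swaps (pick two edges (a,b) and
    (c,d), rewire to (a,c),(b,d) or (a,d),(b,c)); a move is accepted only when
    it keeps the graph simple and connected and *strictly* improves the target
    measure in the requested direction.  Restart 0 begins from ``start``;
    subsequent restarts begin from fresh connected random regular graphs with
    the same n and degree.  Returns the best network found.

    ``method='best_improvement'`` scans every swap per step instead of
    sampling; only feasible for tiny graphs.
    """
    degrees = {deg for _, deg in start.degree()}
    if len(degrees) != 1:
        raise ValueError("rewire_optimize requires a regular start graph")
    if not nx.is_connected(start):
        raise ValueError("start graph must be connected")
    d = degrees.pop()
    n = start.number_of_nodes()
    mapping = {v: i for i, v in enumerate(start.nodes())}
    rng = np.random.default_rng(seed)

    best_edges, best_val = None, None
    for r in range(restarts):
        if r == 0:
            edges = [(mapping[u], mapping[v]) for u, v in start.edges()]
        else:
            g0 = random_regular_connected(n, d, rng)
            edges = list(g0.edges())
        if method == "stochastic":
            edges, val = _climb_stochastic(edges, n, spec, max_iters, rng)
        elif method == "best_improvement":
            edges, val = _climb_best_improvement(edges, n, spec, max_iters)
        else:
            raise ValueError(f"unknown method {method!r}")
        if best_val is None or spec.sign * (val - best_val) > 0:
            best_edges, best_val = edges, val

    out = nx.Graph()
    out.add_nodes_from(range(n))
    out.add_edges_from(best_edges)
    out.graph["name"] = spec.name
    out.graph["measure_value"] = best_val
    return out


# ------------------------------------------------------------------ ensemble

#: default rewiring iterations per measure, weighted by per-candidate
#: evaluation cost so each objective gets comparable wall time
DEFAULT_REWIRE_ITERS = {
    "clustering": 800_000,
    "constraint": 80_000,
    "closeness": 50_000,
    "betweenness": 20_000,
}


def generate_ensemble(
    seed: int,
    n: int = 100,
    d: int = 19,
    rewire_iters: dict | int | None = None,
    restarts: int = 1,
    budget_scale: float = 1.0,
) -> dict[str, nx.Graph]:
    """The ten-network ensemble: complete, ring lattice, and eight extremised graphs.

    ``rewire_iters`` may be a single int for all measures or a per-measure
    mapping; ``budget_scale`` multiplies the budgets (use < 1 for quick
    exploratory ensembles, > 1 to push further toward the extremes).
    """
    if rewire_iters is None:
        rewire_iters = DEFAULT_REWIRE_ITERS
    if isinstance(rewire_iters, int):
        rewire_iters = {m: rewire_iters for m in MEASURES}
    nets = {
        "complete": make_fully_connected(n),
        "ring_lattice": make_ring_lattice(n, d),
    }
    rng = np.random.default_rng(seed)
    for spec in MEASURE_SPECS:
        start = random_regular_connected(n, d, rng)
        iters = max(1, int(rewire_iters[spec.measure] * budget_scale))
        nets[spec.name] = rewire_optimize(
            start, spec, max_iters=iters, restarts=restarts, seed=rng
        )
    return nets


def classify_efficiency(networks: dict[str, nx.Graph]) -> dict[str, str]:
    """Split networks at the median diameter: low-diameter graphs spread
    information fast (efficient), high-diameter graphs slowly (inefficient).
    Ties at the split resolve by name for determinism."""
    diams = {name: diameter(g) for name, g in networks.items()}
    order = sorted(diams, key=lambda name: (diams[name], name))
    half = len(order) // 2
    return {name: ("efficient" if i < half else "inefficient") for i, name in enumerate(order)}


# ----------------------------------------------------------------------- I/O

def write_edgelist(net: nx.Graph, path) -> None:
    """One 'u v' pair per line, 0-based ids, u < v, sorted; deterministic."""
    edges = sorted((min(u, v), max(u, v)) for u, v in net.edges())
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u} {v}\n")


def read_edgelist(path, n: int | None = None) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'u v', got {line!r}")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}")
            g.add_edge(u, v)
    if n is not None:
        g.add_nodes_from(range(n))
    return g
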