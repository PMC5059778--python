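"""Network construction, graph measures and degree-preserving rewiring."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from nksocial.networks import (
    MeasureSpec,
    classify_efficiency,
    diameter,
    generate_ensemble,
    graph_measure,
    make_fully_connected,
    make_ring_lattice,
    random_regular_connected,
    read_edgelist,
    rewire_optimize,
    write_edgelist,
)


def bfs_eccentricity(g, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    assert len(dist) == g.number_of_nodes()
    return max(dist.values())


def bfs_diameter(g):
    return max(bfs_eccentricity(g, v) for v in g.nodes())


# ------------------------------------------------------------- construction

def test_complete_graph_contract():
    g = make_fully_connected(100)
    assert g.number_of_edges() == 4950
    assert diameter(g) == 1
    assert all(deg == 99 for _, deg in g.degree())


def test_complete_graph_clustering_is_one():
    assert graph_measure(make_fully_connected(4), "clustering") == pytest.approx(1.0)


def test_complete_graph_too_small():
    with pytest.raises(ValueError):
        make_fully_connected(1)


def test_ring_lattice_is_regular_and_connected():
    g = make_ring_lattice(100, 19)
    assert all(deg == 19 for _, deg in g.degree())
    assert nx.is_connected(g)
    # every neighbour is one of the 20 circularly nearest nodes
    for i in range(100):
        for j in g.neighbors(i):
            circ = min((i - j) % 100, (j - i) % 100)
            assert 1 <= circ <= 10


def test_ring_lattice_diameter_matches_bfs_oracle():
    g = make_ring_lattice(100, 19)
    assert diameter(g) == bfs_diameter(g)


def test_small_ring_lattice_is_a_cycle():
    g = make_ring_lattice(6, 2)
    assert sorted(map(sorted, g.edges())) == [[0, 1], [0, 5], [1, 2], [2, 3], [3, 4], [4, 5]]
    assert diameter(g) == 3


def test_ring_lattice_parity_error():
    with pytest.raises(ValueError):
        make_ring_lattice(5, 3)  # n*d odd


def test_path_graph_diameter():
    assert diameter(nx.path_graph(5)) == 4


def test_diameter_requires_connected():
    g = nx.Graph([(0, 1), (2, 3)])
    with pytest.raises(ValueError):
        diameter(g)


# ----------------------------------------------------------------- measures

def test_star_betweenness_hand_value():
    # K_{1,3}: centre lies on all 3 leaf pairs -> normalised 1.0; leaves 0
    star = nx.star_graph(3)
    assert graph_measure(star, "betweenness") == pytest.approx(0.25)


def test_cycle_constraint_hand_value():
    # 6-cycle: p_ij = 1/2, no shared neighbours -> c_i = 2*(1/2)^2 = 0.5
    assert graph_measure(nx.cycle_graph(6), "constraint") == pytest.approx(0.5)


def test_path_closeness_hand_value():
    # P_3 closeness: ends 2/3, middle 1
    assert graph_measure(nx.path_graph(3), "closeness") == pytest.approx(7 / 9)


@pytest.mark.parametrize("measure", ["closeness", "betweenness", "clustering", "constraint"])
def test_measures_match_networkx(measure):
    """igraph-backed measures agree with the networkx implementations."""
    g = random_regular_connected(40, 7, seed=3)
    nx_value = {
        "closeness": np.mean(list(nx.closeness_centrality(g).values())),
        "betweenness": np.mean(list(nx.betweenness_centrality(g).values())),
        "clustering": nx.average_clustering(g),
        "constraint": np.mean(list(nx.constraint(g).values())),
    }[measure]
    assert graph_measure(g, measure) == pytest.approx(nx_value, abs=1e-10)


def test_measure_requires_connected():
    with pytest.raises(ValueError):
        graph_measure(nx.Graph([(0, 1), (2, 3)]), "closeness")


def test_unknown_measure_rejected():
    with pytest.raises(ValueError):
        MeasureSpec("eigenvector", "maximize")


# ------------------------------------------------------------------ rewiring

@pytest.mark.parametrize(
    "measure,direction",
    [("clustering", "minimize"), ("clustering", "maximize"),
     ("constraint", "maximize"), ("closeness", "minimize"),
     ("betweenness", "maximize")],
)
def test_rewiring_moves_measure_in_requested_direction(measure, direction):
    start = random_regular_connected(30, 4, seed=1)
    before = graph_measure(start, measure)
    spec = MeasureSpec(measure, direction)
    result = rewire_optimize(start, spec, max_iters=600, restarts=1, seed=2)
    after = graph_measure(result, measure)
    if direction == "maximize":
        assert after >= before
    else:
        assert after <= before
    assert result.graph["measure_value"] == pytest.approx(after)


def test_rewiring_preserves_degrees_and_connectivity():
    start = random_regular_connected(40, 5, seed=4)
    result = rewire_optimize(
        start, MeasureSpec("clustering", "maximize"), max_iters=10_000, restarts=1, seed=5
    )
    assert sorted(d for _, d in result.degree()) == sorted(d for _, d in start.degree())
    assert nx.is_connected(result)
    assert not any(u == v for u, v in result.edges())  # simple graph


def test_rewiring_requires_regular_start():
    with pytest.raises(ValueError):
        rewire_optimize(nx.star_graph(4), MeasureSpec("clustering", "maximize"))


def test_single_best_improvement_step_matches_brute_force():
    """One accepted best-improvement move equals the best swap found by an
    independent exhaustive scan with networkx evaluation."""
    start = random_regular_connected(12, 3, seed=6)
    spec = MeasureSpec("clustering", "maximize")
    result = rewire_optimize(start, spec, max_iters=1, restarts=1, method="best_improvement")

    edges = [tuple(sorted(e)) for e in start.edges()]
    edge_set = set(edges)
    best = graph_measure(start, "clustering")
    for i, j in itertools.combinations(range(len(edges)), 2):
        (a, b), (c, d) = edges[i], edges[j]
        for e1, e2 in (((a, c), (b, d)), ((a, d), (b, c))):
            if any(u == v for u, v in (e1, e2)):
                continue
            if any(tuple(sorted(e)) in edge_set for e in (e1, e2)):
                continue
            if frozenset(e1) == frozenset(e2):
                continue
            candidate = nx.Graph(
                [e for k, e in enumerate(edges) if k not in (i, j)] + [e1, e2]
            )
            candidate.add_nodes_from(range(12))
            if not nx.is_connected(candidate):
                continue
            best = max(best, nx.average_clustering(candidate))
    assert graph_measure(result, "clustering") == pytest.approx(best)


def test_incremental_clustering_value_is_exact():
    """The fast clustering climb reports the true mean clustering of its result."""
    start = random_regular_connected(24, 5, seed=8)
    result = rewire_optimize(
        start, MeasureSpec("clustering", "maximize"), max_iters=5_000, restarts=1, seed=9
    )
    assert result.graph["measure_value"] == pytest.approx(nx.average_clustering(result))


# ------------------------------------------------- ensemble and efficiency

def test_ensemble_contract():
    nets = generate_ensemble(seed=3, n=20, d=4, rewire_iters=200, restarts=1)
    assert len(nets) == 10
    assert nets["complete"].number_of_edges() == 190
    for name, g in nets.items():
        assert nx.is_connected(g)
        if name != "complete":
            assert all(deg == 4 for _, deg in g.degree())


def test_classify_efficiency_split():
    nets = {
        "complete": make_fully_connected(10),   # diameter 1
        "dense": make_ring_lattice(10, 6),      # small diameter
        "cycle": nx.cycle_graph(10),            # diameter 5
        "path_like": make_ring_lattice(12, 2),  # diameter 6
    }
    classes = classify_efficiency(nets)
    assert classes["complete"] == "efficient"
    assert classes["dense"] == "efficient"
    assert classes["cycle"] == "inefficient"
    assert classes["path_like"] == "inefficient"


# ----------------------------------------------------------------------- I/O

def test_edgelist_round_trip(tmp_path):
    g = random_regular_connected(20, 3, seed=1)
    path = tmp_path / "g.edges"
    write_edgelist(g, path)
    loaded = read_edgelist(path, n=20)
    assert set(map(frozenset, loaded.edges())) == set(map(frozenset, g.edges()))
    # deterministic ordering on write
    assert path.read_text() == "\n".join(
        f"{u} {v}" for u, v in sorted((min(u, v), max(u, v)) for u, v in g.edges())
    ) + "\n"


def test_edgelist_rejects_malformed_line(tmp_path):
    path = tmp_path / "bad.edges"
    path.write_text("0 1\n2 3 4\n")
    with pytest.raises(ValueError, match="2"):
        read_edgelist(path)
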