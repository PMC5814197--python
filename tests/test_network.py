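import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stagetraj.enrichment import AnnotationError, GeneAnnotation
from stagetraj.io import FormatError
from stagetraj.network import (
    SizeGuardError,
    annotate_stage,
    hub_subnetwork,
    induce,
    key_chain,
    mcode_modules,
    mcode_weights,
    read_graphml,
    read_interactions,
    remove_term_nodes,
    write_graphml,
)
from stagetraj.synthetic import simulate_expression, simulate_interactions
from stagetraj.trajectory import build_trajectory


def _edges(rows, channels=("experimental",)):
    recs = []
    for r in rows:
        rec = {"protein1": r[0], "protein2": r[1]}
        for i, ch in enumerate(channels):
            rec[ch] = r[2 + i]
        rec.setdefault("combined_score", rec[channels[0]])
        recs.append(rec)
    return pd.DataFrame(recs)


# ----------------------------------------------------------- construction

def test_zero_score_edge_dropped():
    g = read_interactions(_edges([("a", "b", 0)]))
    assert g.number_of_edges() == 0


def test_symmetric_duplicates_collapse():
    g = read_interactions(_edges([("a", "b", 500), ("b", "a", 700)]))
    assert g.number_of_edges() == 1
    assert g["a"]["b"]["experimental"] == 700


def test_self_loops_dropped():
    g = read_interactions(_edges([("a", "a", 900), ("a", "b", 900)]))
    assert g.number_of_edges() == 1 and not list(nx.selfloop_edges(g))


def test_missing_column_is_format_error():
    with pytest.raises(FormatError):
        read_interactions(pd.DataFrame({"protein1": ["a"], "protein2": ["b"]}))


def test_counts_match_generator_truth(tiny_design):
    ds = simulate_expression(design=tiny_design, n_genes=150, seed=15)
    edges = simulate_interactions(ds.truth, n_modules=2, module_size=5,
                                  intra_density=1.0, background_density=0.0, seed=15)
    g = read_interactions(edges)
    assert g.number_of_edges() == len(edges) == 20
    assert set(g.nodes) == set(edges.protein1) | set(edges.protein2)


def test_induce_matches_pair_scan(rng):
    g = nx.gnp_random_graph(60, 0.1, seed=5)
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    subset = {f"g{i}" for i in rng.choice(60, size=25, replace=False)}
    sub = induce(g, subset)
    brute = sum(1 for u, v in itertools.combinations(sorted(subset), 2) if g.has_edge(u, v))
    assert sub.number_of_edges() == brute
    assert induce(g, set(g.nodes)).number_of_edges() == g.number_of_edges()
    assert induce(g, {"zzz"}).number_of_nodes() == 0


def test_remove_term_nodes():
    pairs = pd.DataFrame([("b", "RESP")], columns=["gene", "term"])
    meta = pd.DataFrame([("RESP", "respiratory chain", "CC")],
                        columns=["term", "name", "namespace"])
    ann = GeneAnnotation.from_tables(pairs, meta)
    g = read_interactions(_edges([("a", "b", 500), ("b", "c", 500), ("a", "c", 500)]))
    pruned = remove_term_nodes(g, ann, "RESP")
    assert set(pruned.nodes) == {"a", "c"}
    assert dict(pruned.degree()) == {"a": 1, "c": 1}
    with pytest.raises(AnnotationError):
        remove_term_nodes(g, ann, "nope")


# --------------------------------------------------------------- weights

def brute_force_weight(g, v):
    """Independent oracle: explicit iterative-peeling core decomposition of
    the closed neighborhood of v."""
    nodes = set(g[v]) | {v}
    best = 0.0
    k = 1
    while True:
        sub = g.subgraph(nodes).copy()
        # peel to the k-core
        while True:
            weak = [u for u in sub if sub.degree(u) < k]
            if not weak:
                break
            sub.remove_nodes_from(weak)
        if sub.number_of_nodes() == 0:
            break
        V, E = sub.number_of_nodes(), sub.number_of_edges()
        dens = 2 * E / (V * (V - 1)) if V > 1 else 0.0
        best = k * dens  # highest k seen so far wins
        k += 1
    return best


def test_clique_weights_closed_form():
    for size in (3, 5, 8):
        g = nx.complete_graph(size)
        w = mcode_weights(g)
        assert all(val == pytest.approx(size - 1) for val in w.values())


def test_star_weights_match_brute_force():
    g = nx.star_graph(6)  # center 0, six leaves
    w = mcode_weights(g)
    for v in g.nodes:
        assert w[v] == pytest.approx(brute_force_weight(g, v))


def test_isolated_node_weight_zero():
    g = nx.Graph()
    g.add_node("lonely")
    assert mcode_weights(g)["lonely"] == 0.0


def test_weights_match_oracle_on_random_graphs():
    """Implementation equals the peeling oracle on random graphs."""
    rng = np.random.default_rng(31)
    for rep in range(30):
        n = int(rng.integers(5, 60))
        p = float(rng.uniform(0.02, 0.25))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        w = mcode_weights(g)
        for v in g.nodes:
            assert w[v] == pytest.approx(brute_force_weight(g, v)), (rep, v)


# --------------------------------------------------------------- modules

def test_two_disjoint_cliques_two_modules():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    mods = mcode_modules(g)
    assert len(mods) == 2
    for m in mods:
        assert m.size == 5 and m.score == pytest.approx(5.0)
        assert m.density == pytest.approx(1.0)
    assert mods[0].members.isdisjoint(mods[1].members)


def test_tree_has_no_modules():
    g = nx.balanced_tree(2, 4)
    assert mcode_modules(g) == []


def test_invalid_vwp():
    with pytest.raises(ValueError):
        mcode_modules(nx.complete_graph(4), vwp=1.0)


def test_module_score_bounded_by_size(rng):
    g = nx.gnp_random_graph(80, 0.1, seed=9)
    mods = mcode_modules(g)
    seen = set()
    for m in mods:
        assert m.score <= m.size + 1e-9
        assert 0.0 <= m.density <= 1.0
        assert nx.is_connected(g.subgraph(m.members))
        assert not (m.members & seen)
        seen |= m.members


def test_planted_clique_recovered(tiny_design):
    """Top-ranked module overlaps the planted 6-clique (Jaccard >= 0.8)
    across seeds."""
    ok = 0
    for seed in range(6):
        ds = simulate_expression(design=tiny_design, n_genes=500, seed=seed)
        edges = simulate_interactions(ds.truth, n_modules=1, module_size=6,
                                      intra_density=1.0, background_density=0.01,
                                      seed=seed)
        planted = set(ds.truth.loc[ds.truth["module_id"].notna(), "gene"])
        g = read_interactions(edges)
        mods = mcode_modules(g)
        if not mods:
            continue
        top = set(mods[0].members)
        jac = len(top & planted) / len(top | planted)
        ok += jac >= 0.8
    assert ok >= 5


# ------------------------------------------------------------------ hubs

def test_hub_membership_matches_degree_scan(rng):
    g = nx.gnp_random_graph(100, 0.08, seed=12)
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    hub = hub_subnetwork(g, 5, 9)
    brute = {v for v in g.nodes if 5 <= g.degree(v) <= 9}
    assert set(hub.graph.nodes) == brute
    assert all(hub.parent_degree[v] == g.degree(v) for v in brute)


def test_hub_full_range_keeps_all():
    g = nx.complete_graph(5)
    assert set(hub_subnetwork(g, 0, 10**6).graph.nodes) == set(g.nodes)
    assert set(hub_subnetwork(g, 4, 4).graph.nodes) == set(g.nodes)


def test_hub_monotone_in_range():
    g = nx.gnp_random_graph(60, 0.1, seed=3)
    wide = set(hub_subnetwork(g, 2, 10).graph.nodes)
    narrow = set(hub_subnetwork(g, 3, 8).graph.nodes)
    assert narrow <= wide


def test_hub_invalid_range():
    with pytest.raises(ValueError):
        hub_subnetwork(nx.complete_graph(3), 5, 2)


# ----------------------------------------------------------------- chain

def _hub_of(g):
    return hub_subnetwork(g, 0, 10**6)


def test_chain_on_path_graph():
    g = nx.Graph([("a", "b"), ("b", "c")])
    assert key_chain(_hub_of(g)) == ["a", "b", "c"]


def test_chain_single_node():
    g = nx.Graph()
    g.add_node("x")
    assert key_chain(_hub_of(g)) == ["x"]


def test_chain_empty_hub_errors():
    with pytest.raises(ValueError):
        key_chain(_hub_of(nx.Graph()))


def test_chain_size_guard():
    g = nx.path_graph(30)
    with pytest.raises(SizeGuardError):
        key_chain(_hub_of(g))


def brute_best_path(g, w):
    """Exhaustive simple-path oracle: best (total weight, length) pair."""
    best = None
    for r in range(1, g.number_of_nodes() + 1):
        for perm in itertools.permutations(g.nodes, r):
            if all(g.has_edge(a, b) for a, b in zip(perm, perm[1:])):
                key = (sum(w[v] for v in perm), len(perm))
                if best is None or key > best[0]:
                    best = (key, list(perm))
    return best[1]


def test_chain_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    for rep in range(10):
        g = nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(0, 2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        if g.number_of_nodes() == 0:
            continue
        hub = _hub_of(g)
        chain = key_chain(hub)
        w = hub.parent_degree
        brute = brute_best_path(g, w)
        assert sum(w[v] for v in chain) == sum(w[v] for v in brute)
        assert len(chain) == len(brute)


def test_chain_covers_best_edge():
    """Whenever an edge exists, the chain's total degree is at least both
    endpoints' degrees summed."""
    g = nx.gnp_random_graph(10, 0.3, seed=77)
    if g.number_of_edges():
        hub = _hub_of(g)
        chain = key_chain(hub)
        total = sum(hub.parent_degree[v] for v in chain)
        best_edge = max(hub.parent_degree[u] + hub.parent_degree[v] for u, v in g.edges)
        assert total >= best_edge


# ------------------------------------------------------------ annotation

def test_annotate_stage_lookup():
    traj = build_trajectory(
        [{"a", "b", "c"}, {"b", "c"}, {"c"}], ["I", "II", "III"], "up"
    )
    g = nx.Graph([("a", "b"), ("b", "c"), ("c", "x")])
    annotated = annotate_stage(g, traj)
    assert annotated.nodes["a"]["stage"] == "I"  # deviates at I -> II
    assert annotated.nodes["b"]["stage"] == "II"
    assert annotated.nodes["c"]["stage"] == "persistent"
    assert annotated.nodes["x"]["stage"] == "unclassified"
    assert annotated.nodes["a"]["direction"] == "up"


def test_graphml_roundtrip(tmp_path):
    traj = build_trajectory([{"a", "b"}, {"b"}], ["I", "II"], "up")
    g = annotate_stage(nx.Graph([("a", "b", {"experimental": 900,
                                             "combined_score": 900})]), traj)
    write_graphml(g, tmp_path / "net.graphml")
    g2 = read_graphml(tmp_path / "net.graphml")
    assert set(g2.nodes) == set(g.nodes)
    assert {tuple(sorted(e)) for e in g2.edges} == {tuple(sorted(e)) for e in g.edges}
    assert g2.nodes["a"]["stage"] == "I"
    assert int(g2["a"]["b"]["experimental"]) == 900
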