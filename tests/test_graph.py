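"""Minimizer-graph construction and weight-based filtering."""

from __future__ import annotations

from collections import Counter

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mxscaff.graph import (
    InputSpec,
    break_cycles,
    build_graph,
    filter_global,
    resolve_branches,
    select_anchor_minimizers,
    validate_inputs,
)
from mxscaff.sketch import MinimizerRecord
from _oracles import oracle_filtered_edges


def _records(name, seq_id, hashes):
    return [MinimizerRecord(h, seq_id, 10 * i, "+") for i, h in enumerate(hashes)]


def test_input_contract_enforced():
    t = InputSpec("target", "t.fa", 1.0, "target")
    r = InputSpec("ref1", "r.fa", 2.0, "reference")
    validate_inputs([t, r])
    with pytest.raises(ValueError):
        validate_inputs([t])
    with pytest.raises(ValueError):
        validate_inputs([t, t, r])
    with pytest.raises(ValueError):
        InputSpec("x", "x.fa", 1.0, "query")


def test_low_reference_weight_warns(caplog):
    t = InputSpec("target", "t.fa", 3.0, "target")
    r = InputSpec("ref1", "r.fa", 2.0, "reference")
    with caplog.at_level("WARNING"):
        validate_inputs([t, r])
    assert any("does not exceed" in m for m in caplog.messages)


def test_anchor_requires_uniqueness_and_presence_everywhere():
    counts = {
        "target": Counter({1: 1, 2: 2, 3: 1, 4: 1}),
        "ref1": Counter({1: 1, 2: 1, 3: 1}),
    }
    anchors = select_anchor_minimizers(counts)
    assert anchors == {1, 3}  # 2 duplicated in target, 4 absent from ref


def test_anchor_selection_matches_set_algebra_oracle(rng):
    names = ["target", "ref1", "ref2"]
    counts = {
        n: Counter(
            {int(h): int(c) for h, c in zip(rng.integers(0, 60, 80), rng.integers(1, 4, 80))}
        )
        for n in names
    }
    unique_sets = [{h for h, c in counts[n].items() if c == 1} for n in names]
    expected = set.intersection(*unique_sets)
    if not expected:
        with pytest.raises(RuntimeError):
            select_anchor_minimizers(counts)
    else:
        assert select_anchor_minimizers(counts) == expected


def test_empty_anchor_set_is_fatal_with_advice():
    counts = {"target": Counter({1: 2}), "ref1": Counter({2: 1})}
    with pytest.raises(RuntimeError, match="smaller window"):
        select_anchor_minimizers(counts)


def test_full_agreement_edge_weights():
    hashes = [11, 22, 33, 44, 55]
    filtered = {
        "target": {"c1": _records("target", "c1", hashes)},
        "ref1": {"r1": _records("ref1", "r1", hashes)},
    }
    G = build_graph(filtered, {"target": 1.0, "ref1": 2.0})
    assert G.number_of_edges() == 4
    for _, _, d in G.edges(data=True):
        assert d["weight"] == 3.0 and d["support"] == {"target", "ref1"}


def test_reference_only_adjacency():
    filtered = {
        "target": {"c1": _records("target", "c1", [1, 2]), "c2": _records("target", "c2", [3])},
        "ref1": {"r1": _records("ref1", "r1", [1, 2, 3])},
    }
    G = build_graph(filtered, {"target": 1.0, "ref1": 2.0})
    assert G.edges[2, 3]["weight"] == 2.0
    assert G.edges[2, 3]["support"] == {"ref1"}
    assert G.edges[1, 2]["weight"] == 3.0


def test_edge_multiset_matches_bruteforce_adjacency_scan(rng):
    names = ["target", "ref1"]
    weights = {"target": 1.0, "ref1": 2.0}
    filtered = {}
    expected = {}
    for n in names:
        per_seq = {}
        for s in range(3):
            hashes = list(rng.permutation(30)[: rng.integers(2, 12)])
            per_seq[f"{n}_s{s}"] = _records(n, f"{n}_s{s}", [int(h) for h in hashes])
            for a, b in zip(hashes, hashes[1:]):
                key = frozenset((int(a), int(b)))
                expected.setdefault(key, set()).add(n)
        filtered[n] = per_seq
    G = build_graph(filtered, weights)
    got = {
        frozenset((u, v)): d["support"] for u, v, d in G.edges(data=True)
    }
    assert got == expected
    for pair, support in got.items():
        u, v = tuple(pair)
        assert G.edges[u, v]["weight"] == sum(weights[s] for s in support)


def _random_weighted_graph(rng, n_nodes=30, n_edges=50):
    G = nx.Graph()
    G.add_nodes_from(range(n_nodes))
    for _ in range(n_edges):
        u, v = rng.integers(0, n_nodes, 2)
        if u == v:
            continue
        G.add_edge(int(u), int(v), weight=float(rng.integers(1, 6)), support={"x"})
    return G


def test_global_filter_edge_cases(rng):
    G = _random_weighted_graph(rng)
    assert filter_global(G, 0).number_of_edges() == G.number_of_edges()
    assert filter_global(G, 100.0).number_of_edges() == 0
    assert filter_global(G, 100.0).number_of_nodes() == G.number_of_nodes()
    med = float(np.median([w for _, _, w in G.edges(data="weight")]))
    H = filter_global(G, med)
    assert set(H.edges) == {
        (u, v) for u, v, w in G.edges(data="weight") if w >= med
    }


def test_branch_node_drops_lightest_then_stops():
    G = nx.Graph()
    G.add_edge(0, 1, weight=1.0, support={"a"})
    G.add_edge(0, 2, weight=2.0, support={"a"})
    G.add_edge(0, 3, weight=3.0, support={"a"})
    H = resolve_branches(G)
    assert set(H.edges) == {(0, 2), (0, 3)}


def test_branch_node_all_ties_removes_everything():
    G = nx.Graph()
    for nb in (1, 2, 3):
        G.add_edge(0, nb, weight=2.0, support={"a"})
    H = resolve_branches(G)
    assert H.degree(0) == 0
    assert set(H.nodes) == {0, 1, 2, 3}


@pytest.mark.parametrize("seed", range(8))
def test_branch_resolution_matches_independent_rule(seed):
    rng = np.random.default_rng(seed)
    G = _random_weighted_graph(rng, n_nodes=40, n_edges=90)
    threshold = 2.0
    H = resolve_branches(filter_global(G, threshold))
    assert max((d for _, d in H.degree), default=0) <= 2
    expected = oracle_filtered_edges(
        list(G.nodes),
        {frozenset((u, v)): w for u, v, w in G.edges(data="weight")},
        threshold,
    )
    assert {frozenset((u, v)) for u, v in H.edges} == expected


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_branch_resolution_always_ends_linear(seed):
    rng = np.random.default_rng(seed)
    G = _random_weighted_graph(rng, n_nodes=25, n_edges=60)
    H = resolve_branches(G)
    assert max((d for _, d in H.degree), default=0) <= 2


def test_weight_and_support_survive_filtering(rng):
    G = _random_weighted_graph(rng)
    H = break_cycles(resolve_branches(filter_global(G, 2.0)))
    for u, v, d in H.edges(data=True):
        assert d["weight"] == G.edges[u, v]["weight"]
        assert d["support"] == G.edges[u, v]["support"]


def test_break_cycles_removes_weakest_edge():
    G = nx.Graph()
    cycle = [(0, 1, 3.0), (1, 2, 3.0), (2, 3, 1.0), (3, 0, 3.0)]
    for u, v, w in cycle:
        G.add_edge(u, v, weight=w, support={"a"})
    H = break_cycles(G)
    assert not H.has_edge(2, 3)
    assert H.number_of_edges() == 3
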