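"""The minimizer graph: construction from ordered sketches and filtering.

All input assemblies (one *target*, one or more *references*) are reduced to
a shared vocabulary of *anchor* minimizers — hashes that occur exactly once
in every input — so that each node of the graph corresponds to exactly one
locus in every assembly.  Edges join minimizers that are adjacent in at
least one input's (anchor-filtered) ordered sketch, and an edge's weight is
the sum of the user-supplied weights of the inputs supporting it.  Because
the reference weight is normally higher than the target weight, filtering by
weight fits the target's contigs to the reference structure.

Filtering proceeds in three stages: a global weight threshold, per-node
resolution of branching (degree > 2) nodes by an ascending incident-weight
threshold, and breaking of any surviving cycles at their weakest edge.  The
result has maximum degree 2 and no cycles, i.e. every connected component is
a simple path of minimizers.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .sketch import MinimizerRecord, OrderedSketch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InputSpec:
    """One input assembly: name, FASTA path, mapping weight, and role."""

    name: str
    path: str
    weight: float
    role: str  # "target" or "reference"

    def __post_init__(self):
        if self.role not in ("target", "reference"):
            raise ValueError(f"role must be 'target' or 'reference', got {self.role!r}")
        if self.weight < 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")


def validate_inputs(inputs: list[InputSpec]) -> tuple[InputSpec, list[InputSpec]]:
    """Check the one-target / >=1-reference contract; warn on odd weights."""
    targets = [i for i in inputs if i.role == "target"]
    refs = [i for i in inputs if i.role == "reference"]
    if len(targets) != 1:
        raise ValueError(f"exactly one target input required, got {len(targets)}")
    if not refs:
        raise ValueError("at least one reference input required")
    names = [i.name for i in inputs]
    if len(set(names)) != len(names):
        raise ValueError("input names must be unique")
    for ref in refs:
        if ref.weight <= targets[0].weight:
            logger.warning(
                "reference %s weight (%g) does not exceed target weight (%g); "
                "the target will not be fitted to the reference structure",
                ref.name,
                ref.weight,
                targets[0].weight,
            )
    return targets[0], refs


def select_anchor_minimizers(counts_by_input: dict[str, Counter]) -> set[int]:
    """Hashes occurring exactly once in every input (target and all refs).

    These anchors give an unambiguous node <-> position correspondence in
    every assembly; everything else is discarded before graph construction.
    """
    names = list(counts_by_input)
    if not names:
        raise ValueError("no inputs")
    smallest = min(names, key=lambda n: len(counts_by_input[n]))
    anchors = {
        h
        for h, c in counts_by_input[smallest].items()
        if c == 1
        and all(counts_by_input[n].get(h, 0) == 1 for n in names if n != smallest)
    }
    if not anchors:
        raise RuntimeError(
            "no anchor minimizers shared by all inputs; try a smaller window "
            "size (w), a smaller k, or a more closely related reference"
        )
    logger.info("selected %d anchor minimizers", len(anchors))
    return anchors


def filter_sketches_to_anchors(
    sketches_by_input: dict[str, dict[str, OrderedSketch]], anchors: set[int]
) -> dict[str, dict[str, list[MinimizerRecord]]]:
    """Restrict every sketch to anchor records, preserving position order."""
    out: dict[str, dict[str, list[MinimizerRecord]]] = {}
    for name, sketches in sketches_by_input.items():
        out[name] = {
            seq_id: [rec for rec in sk.records if rec.hash in anchors]
            for seq_id, sk in sketches.items()
        }
    return out


def build_graph(
    filtered: dict[str, dict[str, list[MinimizerRecord]]],
    weight_by_input: dict[str, float],
) -> nx.Graph:
    """Build the undirected minimizer graph from anchor-filtered sketches.

    Consecutive anchors in any input sketch create (or augment) an edge; the
    edge records its supporting inputs and carries weight equal to the sum
    of their weights.
    """
    G = nx.Graph()
    for name, per_seq in filtered.items():
        for records in per_seq.values():
            for rec in records:
                G.add_node(rec.hash)
            for a, b in zip(records, records[1:]):
                if a.hash == b.hash:
                    continue
                if G.has_edge(a.hash, b.hash):
                    G.edges[a.hash, b.hash]["support"].add(name)
                else:
                    G.add_edge(a.hash, b.hash, support={name})
    for _, _, data in G.edges(data=True):
        data["weight"] = sum(weight_by_input[s] for s in data["support"])
    logger.info(
        "minimizer graph: %d nodes, %d edges", G.number_of_nodes(), G.number_of_edges()
    )
    return G


def filter_global(G: nx.Graph, n: float) -> nx.Graph:
    """Remove every edge with weight below the global threshold ``n``."""
    if n < 0:
        raise ValueError(f"edge weight threshold must be >= 0, got {n}")
    H = G.copy()
    drop = [(u, v) for u, v, wt in H.edges(data="weight") if wt < n]
    H.remove_edges_from(drop)
    logger.info("global weight filter (n=%g): removed %d edges", n, len(drop))
    return H


def resolve_branches(G: nx.Graph) -> nx.Graph:
    """Resolve every branching node (degree > 2) by ascending weight.

    For each such node the distinct incident edge weights are tried as
    thresholds in ascending order, removing incident edges lighter than the
    threshold, until the degree drops below 3.  If every remaining incident
    edge ties at the maximum weight and the degree is still >= 3, all
    incident edges of the node are removed.  Nodes are processed in sorted
    hash order; removals immediately affect neighbours.
    """
    H = G.copy()
    removed = 0
    for node in sorted(H.nodes):
        if H.degree(node) <= 2:
            continue
        thresholds = sorted({H.edges[node, nb]["weight"] for nb in H[node]})
        for t in thresholds:
            light = [nb for nb in H[node] if H.edges[node, nb]["weight"] < t]
            H.remove_edges_from((node, nb) for nb in light)
            removed += len(light)
            if H.degree(node) < 3:
                break
        if H.degree(node) >= 3:  # all survivors tie at the maximum weight
            removed += H.degree(node)
            H.remove_edges_from((node, nb) for nb in list(H[node]))
    logger.info("branch resolution: removed %d edges", removed)
    return H


def break_cycles(G: nx.Graph) -> nx.Graph:
    """Break each simple-cycle component at its minimum-weight edge.

    Requires maximum degree <= 2 (i.e. run after :func:`resolve_branches`).
    Ties are broken on the sorted hash pair, so the result is deterministic.
    """
    H = G.copy()
    broken = 0
    for comp in nx.connected_components(H):
        if len(comp) < 3:
            continue
        if all(H.degree(v) == 2 for v in comp):
            u, v, _ = min(
                H.edges(comp, data="weight"),
                key=lambda e: (e[2], min(e[0], e[1]), max(e[0], e[1])),
            )
            H.remove_edge(u, v)
            broken += 1
    if broken:
        logger.info("broke %d cycle(s) at their weakest edge", broken)
    return H
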