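"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results with naive algorithms and
different data structures from the library code they check.
"""

from __future__ import annotations

from collections import defaultdict

from mxscaff.sketch import EMPTY_HASH, canonical_hash


def naive_sketch_positions(seq: str, k: int, w: int) -> list[int]:
    """O(len*w) sliding-window-minimum minimizer selection.

    For every window of w consecutive k-mers take the leftmost k-mer of
    minimum canonical hash; windows whose k-mers are all ambiguous
    contribute nothing; consecutive duplicate selections collapse.
    """
    seq = seq.upper()
    n = len(seq)
    if n < k + w - 1:
        return []
    hashes = []
    for p in range(n - k + 1):
        kmer = seq[p : p + k]
        try:
            h, _ = canonical_hash(kmer)
        except ValueError:
            h = EMPTY_HASH
        hashes.append(h)
    selected: list[int] = []
    for j in range(len(hashes) - w + 1):
        window = hashes[j : j + w]
        mn = min(window)
        if mn == EMPTY_HASH:
            continue
        p = j + window.index(mn)  # leftmost tie-break
        if not selected or selected[-1] != p:
            selected.append(p)
    return selected


def oracle_filtered_edges(
    nodes, weighted_edges: dict[frozenset, float], threshold: float
) -> set[frozenset]:
    """Global weight threshold + ascending-threshold branch resolution.

    ``weighted_edges`` maps frozenset({u, v}) -> weight.  Returns the
    surviving edge set after removing edges below ``threshold`` and then
    resolving every node of degree > 2 exactly as specified: try the
    distinct incident weights ascending, dropping lighter incident edges,
    until degree < 3; if all survivors tie at the maximum weight and degree
    is still >= 3, drop them all.  Nodes processed in sorted order.
    """
    adj: dict[object, dict[object, float]] = defaultdict(dict)
    for pair, wt in weighted_edges.items():
        if wt < threshold:
            continue
        u, v = sorted(pair)
        adj[u][v] = wt
        adj[v][u] = wt
    for node in sorted(nodes):
        if len(adj[node]) <= 2:
            continue
        resolved = False
        for t in sorted(set(adj[node].values())):
            for nb in [nb for nb, wt in adj[node].items() if wt < t]:
                del adj[node][nb]
                del adj[nb][node]
            if len(adj[node]) < 3:
                resolved = True
                break
        if not resolved and len(adj[node]) >= 3:
            for nb in list(adj[node]):
                del adj[node][nb]
                del adj[nb][node]
    return {frozenset((u, v)) for u in adj for v in adj[u]}


def oracle_ng50(lengths, genome_size: int) -> int:
    """Sort-and-accumulate NG50, written independently of the library."""
    acc = 0
    for ln in sorted(lengths)[::-1]:
        acc += ln
        if acc * 2 >= genome_size:
            return ln
    return 0
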