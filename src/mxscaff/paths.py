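"""From linear minimizer paths to ordered, oriented contig paths.

Each connected component of the filtered minimizer graph is a simple path of
anchors.  Walking a path and looking every anchor up in the target assembly
yields blocks of consecutive anchors from one contig; the direction in which
the target positions move gives the contig's orientation in the scaffold.
A contig whose anchors land in more than one path (or in non-contiguous
blocks) is a putative misassembly: in the default mode it is cut in the
unanchored region between the conflicting blocks, while with ``no_cut`` it
is kept whole and assigned to the block holding the majority of its anchors.
Gap sizes between neighbouring contig runs are estimated from the distance
separating their boundary anchors on the reference.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class ContigRun:
    """A maximal block of one target contig used by one scaffold path.

    ``anchors``/``hashes`` are in path (scaffold) order: target positions
    strictly increase along the path for orientation ``+`` and strictly
    decrease for ``-``.  ``start``/``end`` (0-based half-open, assigned
    during cutting) delimit the contig interval the run consumes.
    """

    contig: str
    orientation: str
    anchors: list[int]
    hashes: list[int]
    start: int | None = None
    end: int | None = None

    def anchor_span(self, k: int) -> tuple[int, int]:
        return min(self.anchors), max(self.anchors) + k


@dataclass
class Cut:
    """One contig cut: position plus the anchored bounds of the junction."""

    contig: str
    pos: int
    left_anchor_end: int
    right_anchor_start: int


@dataclass
class ScaffoldPath:
    scaffold_id: str
    runs: list[ContigRun]
    gaps: list[int] = field(default_factory=list)  # len(runs) - 1 entries


def extract_paths(G: nx.Graph) -> list[list[int]]:
    """Walk every component of a max-degree-2 acyclic graph into a node list.

    Singleton components are discarded.  Each path is emitted in canonical
    direction (first hash < last hash) and the list is sorted by endpoints,
    so output is deterministic.  A component that is still a cycle is an
    internal error: cycles must have been broken upstream.
    """
    paths: list[list[int]] = []
    for comp in nx.connected_components(G):
        if len(comp) < 2:
            continue
        ends = sorted(v for v in comp if G.degree(v) <= 1)
        if not ends:
            raise RuntimeError("cycle component survived filtering (internal error)")
        prev, cur = None, ends[0]
        order = [cur]
        while True:
            nxt = [x for x in G[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            order.append(cur)
        if order[0] > order[-1]:
            order.reverse()
        paths.append(order)
    paths.sort(key=lambda p: (p[0], p[-1]))
    logger.info("extracted %d linear minimizer paths", len(paths))
    return paths


def translate_to_contig_runs(
    path: list[int],
    target_index: dict[int, tuple[str, int]],
    k: int,
) -> tuple[list[ContigRun], int]:
    """Translate a minimizer path into ordered, oriented contig runs.

    Maximal blocks of consecutive path nodes mapping to one contig become
    runs; blocks are additionally split wherever the target positions break
    monotonicity.  Blocks with a single anchor have unknowable orientation
    and are dropped (their count is returned for reporting).  Finally the
    whole path is flipped if that makes the majority of its bases
    forward-oriented, so unambiguous reconstructions come out on the plus
    strand.
    """
    blocks: list[list[tuple[int, int]]] = []  # [(hash, target_pos)...]
    contig_of_block: list[str] = []
    for h in path:
        contig, pos = target_index[h]
        if contig_of_block and contig_of_block[-1] == contig:
            blocks[-1].append((h, pos))
        else:
            blocks.append([(h, pos)])
            contig_of_block.append(contig)

    runs: list[ContigRun] = []
    dropped = 0
    for contig, block in zip(contig_of_block, blocks):
        # split at monotonicity breaks; each fragment is its own block
        segs: list[list[tuple[int, int]]] = [[block[0]]]
        direction = 0
        for item in block[1:]:
            d = 1 if item[1] > segs[-1][-1][1] else -1
            if direction == 0 or d == direction:
                direction = d
                segs[-1].append(item)
            else:
                segs.append([item])
                direction = 0
        for seg in segs:
            if len(seg) < 2:
                dropped += 1
                logger.debug(
                    "dropping single-anchor block of %s (unknown orientation)", contig
                )
                continue
            orient = "+" if seg[1][1] > seg[0][1] else "-"
            runs.append(
                ContigRun(
                    contig,
                    orient,
                    [pos for _, pos in seg],
                    [h for h, _ in seg],
                )
            )

    fwd = sum(max(r.anchors) - min(r.anchors) + k for r in runs if r.orientation == "+")
    rev = sum(max(r.anchors) - min(r.anchors) + k for r in runs if r.orientation == "-")
    if rev > fwd:
        runs.reverse()
        for r in runs:
            r.orientation = "+" if r.orientation == "-" else "-"
            r.anchors.reverse()
            r.hashes.reverse()
    return runs, dropped


def cut_contigs(
    paths_runs: list[list[ContigRun]],
    contig_lengths: dict[str, int],
    k: int,
    no_cut: bool = False,
) -> tuple[list[Cut], int]:
    """Assign contig intervals to runs, cutting putative misassemblies.

    Default mode: a contig claimed by >= 2 runs is cut between adjacent
    anchored intervals at the midpoint of the unanchored region separating
    them; the outermost pieces extend to the contig ends.  ``no_cut`` mode:
    a contested contig goes whole to the run holding most of its anchors
    (ties: larger anchored span, then the earliest path), and is removed
    from the others.  Mutates the runs in place (``start``/``end``; run
    removal under ``no_cut``).  Returns the cuts made and the number of
    runs removed by ``no_cut`` reassignment.
    """
    by_contig: dict[str, list[tuple[int, int, ContigRun]]] = defaultdict(list)
    for pi, runs in enumerate(paths_runs):
        for ri, run in enumerate(runs):
            by_contig[run.contig].append((pi, ri, run))

    cuts: list[Cut] = []
    removed = 0
    to_remove: list[tuple[int, ContigRun]] = []
    for contig in sorted(by_contig):
        entries = by_contig[contig]
        length = contig_lengths[contig]
        if len(entries) == 1:
            run = entries[0][2]
            run.start, run.end = 0, length
            continue
        if no_cut:
            best = max(
                entries,
                key=lambda e: (
                    len(e[2].anchors),
                    max(e[2].anchors) - min(e[2].anchors),
                    -e[0],
                    -e[1],
                ),
            )
            best[2].start, best[2].end = 0, length
            for pi, _, run in entries:
                if run is not best[2]:
                    to_remove.append((pi, run))
                    removed += 1
            continue
        entries.sort(key=lambda e: min(e[2].anchors))
        spans = [e[2].anchor_span(k) for e in entries]
        prev_cut = 0
        for i, (_, _, run) in enumerate(entries):
            if i < len(entries) - 1:
                boundary = (spans[i][1] + spans[i + 1][0]) // 2
                boundary = min(max(boundary, prev_cut + 1), length - 1)
                cuts.append(Cut(contig, boundary, spans[i][1], spans[i + 1][0]))
                run.start, run.end = prev_cut, boundary
                prev_cut = boundary
            else:
                run.start, run.end = prev_cut, length

    for pi, run in to_remove:
        paths_runs[pi].remove(run)
    if cuts:
        logger.info("cut %d putative misassembly junction(s)", len(cuts))
    if removed:
        logger.info("no_cut: reassigned %d contested run(s)", removed)
    return cuts, removed


def _trailing_flank(run: ContigRun, k: int) -> int:
    """Unanchored contig bases after the run's last anchor, in scaffold order."""
    if run.orientation == "+":
        return run.end - (run.anchors[-1] + k)
    return run.anchors[-1] - run.start


def _leading_flank(run: ContigRun, k: int) -> int:
    """Unanchored contig bases before the run's first anchor, in scaffold order."""
    if run.orientation == "+":
        return run.anchors[0] - run.start
    return run.end - (run.anchors[0] + k)


def estimate_gaps(
    runs: list[ContigRun],
    ref_indexes: list[tuple[str, dict[int, tuple[str, int]]]],
    k: int,
    min_gap: int,
) -> list[int]:
    """Reference-based gap estimates between consecutive runs of one path.

    The gap is the reference distance between the boundary anchors of the
    two runs, minus the unanchored contig flanks already accounted for by
    the runs themselves, clamped below at ``min_gap``.  If the boundary
    anchors never share a reference sequence the gap falls back to
    ``min_gap``.
    """
    gaps: list[int] = []
    for r1, r2 in zip(runs, runs[1:]):
        h1, h2 = r1.hashes[-1], r2.hashes[0]
        gap = min_gap
        for _, index in ref_indexes:
            e1, e2 = index.get(h1), index.get(h2)
            if e1 is None or e2 is None or e1[0] != e2[0]:
                continue
            ref_dist = abs(e2[1] - e1[1]) - k
            est = ref_dist - _trailing_flank(r1, k) - _leading_flank(r2, k)
            gap = max(min_gap, est)
            break
        gaps.append(gap)
    return gaps
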