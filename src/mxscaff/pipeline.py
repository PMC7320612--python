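"""End-to-end orchestration: sketch -> graph -> paths -> scaffolds.

:func:`scaffold_assemblies` is the library entry point; the command-line
interface is a thin wrapper around it.  The whole pipeline is deterministic:
identical inputs and parameters produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from . import graph as graph_mod
from . import io_formats, paths as paths_mod, scaffold as scaffold_mod
from .graph import InputSpec
from .sketch import SketchParams, sketch_assembly

logger = logging.getLogger(__name__)


@dataclass
class ScaffoldingResult:
    """Everything the pipeline produced, ready for writing or inspection."""

    paths: list[paths_mod.ScaffoldPath]
    placed: list[scaffold_mod.ScaffoldRecord]
    unplaced: list[scaffold_mod.ScaffoldRecord]
    report: dict
    graph: nx.Graph  # after all filtering
    raw_graph: nx.Graph  # before filtering
    cuts: list[paths_mod.Cut]
    n_dropped_single_anchor: int = 0
    n_reassigned_no_cut: int = 0
    params: dict = field(default_factory=dict)
    target_seqs: dict[str, str] = field(default_factory=dict)

    @property
    def records(self) -> list[scaffold_mod.ScaffoldRecord]:
        return self.placed + self.unplaced

    def scaffold_entries(self) -> list[io_formats.ScaffoldEntry]:
        """Neutral entry form of all output records (for path/AGP writers)."""
        entries: list[io_formats.ScaffoldEntry] = []
        for sp in self.paths:
            items: list[tuple] = []
            for i, run in enumerate(sp.runs):
                items.append(("run", run.contig, run.start, run.end, run.orientation))
                if i < len(sp.gaps):
                    items.append(("gap", sp.gaps[i]))
            entries.append((sp.scaffold_id, items))
        for rec in self.unplaced:
            contig, start, end = rec.source
            entries.append((rec.scaffold_id, [("run", contig, start, end, "+")]))
        return entries


def scaffold_assemblies(
    target_path,
    reference_paths,
    weights: list[float] | None = None,
    k: int = 32,
    w: int = 1000,
    n: float | None = None,
    min_gap: int = 20,
    no_cut: bool = False,
) -> ScaffoldingResult:
    """Scaffold (and optionally correct) a target assembly against references.

    Parameters
    ----------
    target_path, reference_paths
        FASTA (optionally gzipped) files: the draft assembly to improve and
        one or more guiding assemblies.
    weights
        Per-input weights, ordered target first then references.  Defaults
        to 1 for the target and 2 for every reference, so reference-backed
        adjacencies dominate.
    k, w
        Minimizer sketch parameters (k-mer size; window size in k-mers).
    n
        Global edge weight threshold.  Defaults to the minimum reference
        weight, which keeps every reference-supported adjacency.
    min_gap
        Floor for estimated gap sizes, in bases (>= 1).
    no_cut
        Keep target contigs whole instead of cutting putative misassemblies.
    """
    reference_paths = list(reference_paths)
    if weights is None:
        weights = [1.0] + [2.0] * len(reference_paths)
    if len(weights) != 1 + len(reference_paths):
        raise ValueError(
            f"expected {1 + len(reference_paths)} weights "
            f"(target + {len(reference_paths)} references), got {len(weights)}"
        )
    if min_gap < 1:
        raise ValueError(f"min_gap must be >= 1, got {min_gap}")
    params = SketchParams(k=k, w=w)

    inputs = [InputSpec("target", str(target_path), float(weights[0]), "target")]
    for i, (path, wt) in enumerate(zip(reference_paths, weights[1:])):
        inputs.append(InputSpec(f"ref{i + 1}", str(path), float(wt), "reference"))
    target_spec, refs = graph_mod.validate_inputs(inputs)
    if n is None:
        n = min(r.weight for r in refs)

    sketches_by_input = {}
    counts_by_input = {}
    for spec in inputs:
        sketches_by_input[spec.name], counts_by_input[spec.name] = sketch_assembly(
            spec.path, params
        )

    anchors = graph_mod.select_anchor_minimizers(counts_by_input)
    filtered = graph_mod.filter_sketches_to_anchors(sketches_by_input, anchors)
    weight_by_input = {spec.name: spec.weight for spec in inputs}

    raw_graph = graph_mod.build_graph(filtered, weight_by_input)
    G = graph_mod.filter_global(raw_graph, n)
    G = graph_mod.resolve_branches(G)
    G = graph_mod.break_cycles(G)

    target_index = {
        rec.hash: (rec.seq_id, rec.pos)
        for per_seq in [filtered["target"]]
        for records in per_seq.values()
        for rec in records
    }
    ref_indexes = []
    for spec in refs:
        index = {
            rec.hash: (rec.seq_id, rec.pos)
            for records in filtered[spec.name].values()
            for rec in records
        }
        ref_indexes.append((spec.name, index))

    minimizer_paths = paths_mod.extract_paths(G)
    paths_runs = []
    dropped = 0
    for mp in minimizer_paths:
        runs, d = paths_mod.translate_to_contig_runs(mp, target_index, k)
        dropped += d
        paths_runs.append(runs)

    target_seqs = io_formats.read_fasta(target_path)
    contig_lengths = {cid: len(seq) for cid, seq in target_seqs.items()}
    cuts, reassigned = paths_mod.cut_contigs(paths_runs, contig_lengths, k, no_cut)

    scaffold_paths = []
    for runs in paths_runs:
        if not runs:
            continue
        gaps = paths_mod.estimate_gaps(runs, ref_indexes, k, min_gap)
        scaffold_paths.append(paths_mod.ScaffoldPath("", runs, gaps))
    scaffold_paths.sort(key=lambda sp: (sp.runs[0].contig, sp.runs[0].start))
    for i, sp in enumerate(scaffold_paths, start=1):
        sp.scaffold_id = f"mxs_{i:06d}"

    placed = scaffold_mod.emit_scaffolds(scaffold_paths, target_seqs)
    intervals = scaffold_mod.placed_intervals(scaffold_paths)
    unplaced = scaffold_mod.emit_unplaced(target_seqs, intervals)
    report = scaffold_mod.placement_report(target_seqs, scaffold_paths, unplaced)
    report["dropped_single_anchor_blocks"] = dropped
    report["cuts"] = len(cuts)

    return ScaffoldingResult(
        paths=scaffold_paths,
        placed=placed,
        unplaced=unplaced,
        report=report,
        graph=G,
        raw_graph=raw_graph,
        cuts=cuts,
        n_dropped_single_anchor=dropped,
        n_reassigned_no_cut=reassigned,
        params={
            "k": k,
            "w": w,
            "n": n,
            "min_gap": min_gap,
            "no_cut": no_cut,
            "weights": list(weights),
        },
        target_seqs=target_seqs,
    )


def write_outputs(
    result: ScaffoldingResult,
    prefix: str,
    agp: bool = False,
    dot_prefilter: bool = False,
) -> dict[str, str]:
    """Write FASTA, path, dot (and optionally AGP, report) files.

    Returns a map from output kind to the file path written.
    """
    out = {}
    records = [(r.scaffold_id, r.sequence) for r in result.records]
    out["fasta"] = f"{prefix}.fa"
    io_formats.write_fasta(records, out["fasta"])

    entries = result.scaffold_entries()
    out["path"] = f"{prefix}.path"
    io_formats.write_path_file(entries, out["path"])

    out["dot"] = f"{prefix}.dot"
    io_formats.write_dot(
        result.raw_graph if dot_prefilter else result.graph, out["dot"]
    )

    if agp:
        out["agp"] = f"{prefix}.agp"
        io_formats.write_agp(entries, out["agp"])

    out["report"] = f"{prefix}.report.tsv"
    with open(out["report"], "w") as fh:
        fh.write(scaffold_mod.report_tsv_text(result.report))
    return out
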