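"""Readers and writers for the on-disk formats used by the scaffolder.

Covers FASTA (plain or gzip-compressed) input, 60-column FASTA output, the
``path`` sidecar dialect describing scaffold composition, AGP v2.1, and
Graphviz dot export of the minimizer graph.

The ``path`` dialect is normative for this package: one line per output
sequence, ``scaffold_id`` TAB space-separated tokens, where a token is either
``contigID[start-end]S`` (0-based half-open interval of the target contig,
``S`` the orientation ``+``/``-``) or ``gapN`` (``N`` the gap size in bases).
AGP output follows the NCBI v2.1 column conventions (1-based inclusive
coordinates, alternating ``W`` sequence and ``N`` gap components).

Both sidecar formats are lossless: :func:`materialize_entries` rebuilds the
output FASTA from either of them plus the target assembly.
"""

from __future__ import annotations

import gzip
import logging
import re
from typing import Iterable

logger = logging.getLogger(__name__)

# A "scaffold entry" is the neutral in-memory form shared by the path and AGP
# writers: (scaffold_id, [item...]) with item = ("run", contig, start, end,
# orient) or ("gap", size).  Coordinates are 0-based half-open; conversion to
# AGP's 1-based inclusive happens only at the AGP boundary.
ScaffoldEntry = tuple[str, list[tuple]]


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def open_text(path):
    """Open a possibly gzip-compressed file for text reading."""
    if _is_gzip(path):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered id -> sequence map.

    The sequence identifier is the header token before the first whitespace.
    Duplicate identifiers and unreadable files are fatal.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    try:
        with open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in seqs:
                    raise ValueError(
                        f"duplicate sequence identifier {rec.id!r} in {path}"
                    )
                seqs[rec.id] = str(rec.seq)
    except OSError as exc:
        raise RuntimeError(f"cannot read FASTA file {path}: {exc}") from exc
    if not seqs:
        logger.warning("no sequences found in %s", path)
    return seqs


def fasta_text(records: Iterable[tuple[str, str]], width: int = 60) -> str:
    """Render ``(id, sequence)`` pairs as wrapped FASTA text."""
    out = []
    for name, seq in records:
        out.append(f">{name}\n")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width] + "\n")
    return "".join(out)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(fasta_text(records, width=width))


# ---------------------------------------------------------------------------
# path dialect

_RUN_RE = re.compile(r"^(?P<contig>.+)\[(?P<start>\d+)-(?P<end>\d+)\](?P<orient>[+-])$")


def path_file_text(entries: Iterable[ScaffoldEntry]) -> str:
    lines = []
    for sid, items in entries:
        tokens = []
        for item in items:
            if item[0] == "run":
                _, contig, start, end, orient = item
                tokens.append(f"{contig}[{start}-{end}]{orient}")
            else:
                tokens.append(f"gap{item[1]}")
        lines.append(f"{sid}\t{' '.join(tokens)}\n")
    return "".join(lines)


def write_path_file(entries: Iterable[ScaffoldEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write(path_file_text(entries))


def parse_path_file(path) -> list[ScaffoldEntry]:
    entries: list[ScaffoldEntry] = []
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sid, _, rest = line.partition("\t")
            items: list[tuple] = []
            for token in rest.split(" "):
                if token.startswith("gap") and token[3:].isdigit():
                    items.append(("gap", int(token[3:])))
                    continue
                m = _RUN_RE.match(token)
                if m is None:
                    raise ValueError(f"malformed path token {token!r} in {path}")
                items.append(
                    (
                        "run",
                        m["contig"],
                        int(m["start"]),
                        int(m["end"]),
                        m["orient"],
                    )
                )
            entries.append((sid, items))
    return entries


def materialize_entries(
    entries: Iterable[ScaffoldEntry], target_seqs: dict[str, str]
) -> list[tuple[str, str]]:
    """Rebuild scaffold sequences from path/AGP entries and the target FASTA."""
    from .sketch import revcomp

    out = []
    for sid, items in entries:
        parts = []
        for item in items:
            if item[0] == "run":
                _, contig, start, end, orient = item
                sub = target_seqs[contig][start:end]
                parts.append(revcomp(sub) if orient == "-" else sub)
            else:
                parts.append("N" * item[1])
        out.append((sid, "".join(parts)))
    return out


# ---------------------------------------------------------------------------
# AGP v2.1

AGP_GAP_TYPE = "scaffold"
AGP_LINKAGE = "yes"
AGP_EVIDENCE = "align_genus"


def agp_text(entries: Iterable[ScaffoldEntry]) -> str:
    lines = ["##agp-version\t2.1\n"]
    for sid, items in entries:
        obj_pos = 1  # 1-based next coordinate on the object
        for part_number, item in enumerate(items, start=1):
            if item[0] == "run":
                _, contig, start, end, orient = item
                span = end - start
                lines.append(
                    "\t".join(
                        (
                            sid,
                            str(obj_pos),
                            str(obj_pos + span - 1),
                            str(part_number),
                            "W",
                            contig,
                            str(start + 1),
                            str(end),
                            orient,
                        )
                    )
                    + "\n"
                )
            else:
                span = item[1]
                lines.append(
                    "\t".join(
                        (
                            sid,
                            str(obj_pos),
                            str(obj_pos + span - 1),
                            str(part_number),
                            "N",
                            str(span),
                            AGP_GAP_TYPE,
                            AGP_LINKAGE,
                            AGP_EVIDENCE,
                        )
                    )
                    + "\n"
                )
            obj_pos += span
    return "".join(lines)


def write_agp(entries: Iterable[ScaffoldEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write(agp_text(entries))


def parse_agp(path) -> list[ScaffoldEntry]:
    """Parse an AGP v2.1 file back into scaffold entries (0-based half-open)."""
    entries: list[ScaffoldEntry] = []
    current_id = None
    items: list[tuple] = []
    with open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"AGP line does not have 9 columns: {line!r}")
            sid = cols[0]
            if sid != current_id:
                if current_id is not None:
                    entries.append((current_id, items))
                current_id, items = sid, []
            obj_beg, obj_end = int(cols[1]), int(cols[2])
            if cols[4] == "W":
                comp_beg, comp_end = int(cols[6]), int(cols[7])
                if comp_end - comp_beg != obj_end - obj_beg:
                    raise ValueError(f"inconsistent AGP spans: {line!r}")
                items.append(("run", cols[5], comp_beg - 1, comp_end, cols[8]))
            elif cols[4] == "N":
                items.append(("gap", int(cols[5])))
            else:
                raise ValueError(f"unsupported AGP component type {cols[4]!r}")
    if current_id is not None:
        entries.append((current_id, items))
    return entries


# ---------------------------------------------------------------------------
# Graphviz dot

def dot_text(graph, name: str = "minimizer_graph") -> str:
    """Render a minimizer graph (nodes, edges, weights, support) as dot."""
    lines = [f"graph {name} {{\n"]
    for node in sorted(graph.nodes):
        lines.append(f'  "{node}";\n')
    for u, v, data in sorted(
        graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))
    ):
        a, b = (u, v) if u <= v else (v, u)
        support = ",".join(sorted(data.get("support", ())))
        lines.append(
            f'  "{a}" -- "{b}" [weight={data["weight"]:g}, support="{support}"];\n'
        )
    lines.append("}\n")
    return "".join(lines)


def write_dot(graph, path, name: str = "minimizer_graph") -> None:
    with open(path, "w") as fh:
        fh.write(dot_text(graph, name=name))
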