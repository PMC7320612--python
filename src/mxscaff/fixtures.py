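"""Deterministic synthetic reference/target pairs with recorded ground truth.

The generator emulates the situation the scaffolder is built for: a
chromosome-scale reference assembly and a fragmented draft (target) derived
from it.  Chromosomes are i.i.d. uniform random DNA — unique minimizers are
then abundant, which isolates algorithm correctness from repeat handling.
The target is produced by fragmenting the reference at random breakpoints,
optionally reverse-complementing, shuffling and point-mutating the
fragments (the substitution rate models cross-individual or cross-species
divergence), deleting spacer regions so true inter-fragment gaps exist, and
joining fragments from different chromosomes into chimeric (misassembled)
contigs.  Every target base is attributable to exactly one reference
interval, recorded in the layout table, so scaffolding output can be scored
exactly.

:func:`score_against_truth` measures the axes that matter for a
reference-guided scaffolder: correct-order junction recovery, orientation
accuracy, chimera-cut sensitivity and breakpoint displacement, gap-size
error, placed fraction, and NG50 before/after.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import write_fasta
from .sketch import revcomp

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic reference/target pair.

    ``spacer_deletions`` is a list of ``(chrom_index, start, length)``
    triples: those reference intervals are omitted from the target, forcing
    a true gap of ``length`` bases between the flanking fragments.
    Identical spec + seed always produce an identical fixture.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    fragment_length_mean: float = 40_000.0
    fragment_length_sd: float = 10_000.0
    min_fragment_length: int = 2_000
    revcomp_probability: float = 0.5
    shuffle: bool = True
    n_chimeras: int = 0
    spacer_deletions: tuple[tuple[int, int, int], ...] = ()
    snp_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        for p in (self.revcomp_probability, self.snp_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.chrom_length <= 0 or self.fragment_length_mean <= 0:
            raise ValueError("lengths must be positive")
        if self.fragment_length_mean >= self.chrom_length:
            raise ValueError(
                "infeasible spec: fragment mean >= chromosome length"
            )
        if self.n_chimeras > 0 and self.n_chromosomes < 2:
            raise ValueError("chimeras require at least 2 chromosomes")


@dataclass
class Fragment:
    """One target fragment and where it came from.

    ``orientation`` is ``+`` if the fragment appears in its contig in
    reference-forward direction; ``contig_start``/``contig_end`` locate it
    within the (possibly chimeric, possibly reverse-complemented) contig.
    """

    frag_id: str
    chrom: str
    ref_start: int
    ref_end: int
    contig: str = ""
    contig_start: int = 0
    contig_end: int = 0
    orientation: str = "+"
    target_order_index: int = -1

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class Junction:
    """True adjacency between two fragments in reference order."""

    left: str  # frag_id
    right: str
    gap: int  # true reference distance between them (0 or a deletion length)


@dataclass(frozen=True)
class Chimera:
    contig: str
    junction: int  # contig coordinate of the misjoin
    left_frag: str
    right_frag: str


@dataclass
class Fixture:
    spec: FixtureSpec
    reference: dict[str, str]
    target: dict[str, str]
    fragments: list[Fragment]
    junctions: list[Junction]
    chimeras: list[Chimera]

    def fragment(self, frag_id: str) -> Fragment:
        return next(f for f in self.fragments if f.frag_id == frag_id)

    def write(self, outdir) -> dict[str, Path]:
        """Write reference FASTA, target FASTA and the layout TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fa",
            "target": outdir / "target.fa",
            "layout": outdir / "layout.tsv",
        }
        write_fasta(self.reference.items(), paths["reference"])
        write_fasta(self.target.items(), paths["target"])
        with open(paths["layout"], "w") as fh:
            fh.write(
                "fragment_id\tsource_chrom\tsource_start\tsource_end\t"
                "orientation\ttarget_order_index\tcontig\tcontig_start\tcontig_end\n"
            )
            for f in self.fragments:
                fh.write(
                    f"{f.frag_id}\t{f.chrom}\t{f.ref_start}\t{f.ref_end}\t"
                    f"{f.orientation}\t{f.target_order_index}\t"
                    f"{f.contig}\t{f.contig_start}\t{f.contig_end}\n"
                )
        return paths


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # substitute with a uniformly chosen *different* base
        codes = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a reference/target pair with full ground-truth bookkeeping."""
    rng = np.random.default_rng(spec.rng_seed)
    reference = {
        f"chr{i + 1}": _random_dna(rng, spec.chrom_length)
        for i in range(spec.n_chromosomes)
    }

    deletions: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ci, start, length in spec.spacer_deletions:
        chrom = f"chr{ci + 1}"
        if chrom not in reference:
            raise ValueError(f"spacer deletion on unknown chromosome index {ci}")
        if not 0 < start < start + length < spec.chrom_length:
            raise ValueError(f"spacer deletion ({ci},{start},{length}) out of bounds")
        deletions[chrom].append((start, start + length))

    # fragment the kept intervals of each chromosome
    fragments: list[Fragment] = []
    junctions: list[Junction] = []
    frag_no = 0
    for chrom in reference:
        kept = []
        cursor = 0
        for s, e in sorted(deletions[chrom]):
            if s < cursor:
                raise ValueError("overlapping spacer deletions")
            kept.append((cursor, s))
            cursor = e
        kept.append((cursor, spec.chrom_length))

        chrom_frags: list[Fragment] = []
        for s, e in kept:
            cur = s
            while cur < e:
                ln = int(rng.normal(spec.fragment_length_mean, spec.fragment_length_sd))
                ln = max(spec.min_fragment_length, ln)
                if e - cur - ln < spec.min_fragment_length:
                    ln = e - cur
                frag_no += 1
                chrom_frags.append(
                    Fragment(f"frag_{frag_no:04d}", chrom, cur, cur + ln)
                )
                cur += ln
        for a, b in zip(chrom_frags, chrom_frags[1:]):
            junctions.append(Junction(a.frag_id, b.frag_id, b.ref_start - a.ref_end))
        fragments.extend(chrom_frags)

    # chimeras: join fragments from different chromosomes
    chimeras: list[Chimera] = []
    in_chimera: dict[str, tuple[str, int]] = {}  # frag_id -> (contig, part index)
    if spec.n_chimeras:
        by_chrom: dict[str, list[Fragment]] = defaultdict(list)
        for f in fragments:
            by_chrom[f.chrom].append(f)
        chroms = sorted(by_chrom)
        for j in range(spec.n_chimeras):
            ca, cb = chroms[j % len(chroms)], chroms[(j + 1) % len(chroms)]
            avail_a = [f for f in by_chrom[ca] if f.frag_id not in in_chimera]
            avail_b = [f for f in by_chrom[cb] if f.frag_id not in in_chimera]
            if not avail_a or not avail_b:
                raise ValueError("not enough fragments to form requested chimeras")
            fa = avail_a[int(rng.integers(len(avail_a)))]
            fb = avail_b[int(rng.integers(len(avail_b)))]
            contig = f"chim_{j + 1:02d}"
            in_chimera[fa.frag_id] = (contig, 0)
            in_chimera[fb.frag_id] = (contig, 1)
            chimeras.append(Chimera(contig, fa.length, fa.frag_id, fb.frag_id))

    # assemble contigs (chimeras first by id, then plain fragments)
    contig_parts: dict[str, list[Fragment]] = {}
    for f in fragments:
        if f.frag_id in in_chimera:
            contig, idx = in_chimera[f.frag_id]
            contig_parts.setdefault(contig, [None, None])[idx] = f  # type: ignore
        else:
            contig_parts[f.frag_id] = [f]

    target: dict[str, str] = {}
    for contig in contig_parts:
        parts = contig_parts[contig]
        seq = "".join(reference[p.chrom][p.ref_start : p.ref_end] for p in parts)
        pos = 0
        for p in parts:
            p.contig = contig
            p.contig_start = pos
            p.contig_end = pos + p.length
            p.orientation = "+"
            pos += p.length
        if rng.random() < spec.revcomp_probability:
            seq = revcomp(seq)
            total = len(seq)
            for p in parts:
                p.contig_start, p.contig_end = total - p.contig_end, total - p.contig_start
                p.orientation = "-"
        seq = _mutate(rng, seq, spec.snp_rate)
        target[contig] = seq
    # chimera junction coordinates follow the contig's final orientation
    chimeras = [
        Chimera(
            c.contig,
            len(target[c.contig]) - c.junction
            if next(f for f in fragments if f.frag_id == c.left_frag).orientation == "-"
            else c.junction,
            c.left_frag,
            c.right_frag,
        )
        for c in chimeras
    ]

    order = list(target)
    if spec.shuffle:
        order = [order[i] for i in rng.permutation(len(order))]
    target = {cid: target[cid] for cid in order}
    order_index = {cid: i for i, cid in enumerate(order)}
    for f in fragments:
        f.target_order_index = order_index[f.contig]

    logger.info(
        "fixture: %d chromosomes x %d bp -> %d fragments, %d contigs, %d chimeras",
        spec.n_chromosomes,
        spec.chrom_length,
        len(fragments),
        len(target),
        len(chimeras),
    )
    return Fixture(spec, reference, target, fragments, junctions, chimeras)


# ---------------------------------------------------------------------------
# scoring

def ng50(lengths, genome_size: int) -> int:
    """Length L such that pieces >= L cover at least half the genome size."""
    total = 0
    for ln in sorted(lengths, reverse=True):
        total += ln
        if 2 * total >= genome_size:
            return ln
    return 0


@dataclass
class TruthMetrics:
    n_true_junctions: int = 0
    n_evaluable_junctions: int = 0
    n_correct_junctions: int = 0
    n_placed_fragments: int = 0
    n_fragments: int = 0
    n_incorrect_orientation: int = 0
    chimera_cuts_correct: int = 0
    n_chimeras: int = 0
    chimera_displacements: list[int] = field(default_factory=list)
    gap_pairs: list[tuple[int, int]] = field(default_factory=list)  # (true, est)
    ng50_before: int = 0
    ng50_after: int = 0
    fraction_placed: float = 0.0

    @property
    def gap_errors(self) -> list[int]:
        return [abs(est - true) for true, est in self.gap_pairs]

    @property
    def spacer_gap_errors(self) -> list[int]:
        """Gap errors restricted to junctions with a real (>0) spacer."""
        return [abs(est - true) for true, est in self.gap_pairs if true > 0]

    @property
    def junction_fraction(self) -> float:
        if not self.n_evaluable_junctions:
            return 0.0
        return self.n_correct_junctions / self.n_evaluable_junctions

    @property
    def orientation_fraction(self) -> float:
        if not self.n_placed_fragments:
            return 0.0
        return 1.0 - self.n_incorrect_orientation / self.n_placed_fragments

    @property
    def chimera_sensitivity(self) -> float:
        if not self.n_chimeras:
            return 0.0
        return self.chimera_cuts_correct / self.n_chimeras


def _fragments_in_run(run, frags: list[Fragment]) -> list[Fragment]:
    """Fragments of ``run.contig`` mostly covered by the run's interval."""
    hit = []
    for f in frags:
        overlap = min(run.end, f.contig_end) - max(run.start, f.contig_start)
        if overlap > 0.5 * (f.contig_end - f.contig_start):
            hit.append(f)
    hit.sort(key=lambda f: f.contig_start)
    return hit


def score_against_truth(result, fixture: Fixture) -> TruthMetrics:
    """Score a :class:`~mxscaff.pipeline.ScaffoldingResult` against truth.

    Junction recovery counts a true reference adjacency (A, B) as correct
    when some scaffold presents A then B both reference-forward, or B then A
    both reference-reverse.  Orientation correctness is judged against the
    length-weighted consensus direction of each scaffold, so a wholly
    reversed scaffold is not penalized.  Gap errors compare each recovered
    true junction's emitted gap with the true spacer length.
    """
    m = TruthMetrics()
    frags_by_contig: dict[str, list[Fragment]] = defaultdict(list)
    for f in fixture.fragments:
        frags_by_contig[f.contig].append(f)
    m.n_fragments = len(fixture.fragments)

    # per-scaffold ordered fragment lists with effective (vs reference)
    # orientations, plus the emitted gap between consecutive fragments
    scaffold_frags: list[list[tuple[Fragment, str]]] = []
    adjacency_gap: dict[tuple[str, str], int] = {}
    placed_ids: set[str] = set()
    for sp in result.paths:
        flist: list[tuple[Fragment, str]] = []
        for i, run in enumerate(sp.runs):
            hit = _fragments_in_run(run, frags_by_contig.get(run.contig, []))
            if run.orientation == "-":
                hit.reverse()
            for f in hit:
                eff = "+" if f.orientation == run.orientation else "-"
                if flist:
                    prev = flist[-1][0]
                    # gap applies to the junction between consecutive runs
                    key = (prev.frag_id, f.frag_id)
                    if i > 0 and hit and f is hit[0]:
                        adjacency_gap[key] = sp.gaps[i - 1]
                    else:
                        adjacency_gap[key] = 0
                flist.append((f, eff))
                placed_ids.add(f.frag_id)
        scaffold_frags.append(flist)

    m.n_placed_fragments = len(placed_ids)
    realized: dict[tuple[str, str, str, str], tuple[str, str]] = {}
    for flist in scaffold_frags:
        for (f1, e1), (f2, e2) in zip(flist, flist[1:]):
            realized[(f1.frag_id, e1, f2.frag_id, e2)] = (f1.frag_id, f2.frag_id)

    m.n_true_junctions = len(fixture.junctions)
    for j in fixture.junctions:
        if j.left not in placed_ids or j.right not in placed_ids:
            continue
        m.n_evaluable_junctions += 1
        fwd = (j.left, "+", j.right, "+")
        rev = (j.right, "-", j.left, "-")
        hit_key = fwd if fwd in realized else (rev if rev in realized else None)
        if hit_key is not None:
            m.n_correct_junctions += 1
            est = adjacency_gap.get((hit_key[0], hit_key[2]))
            if est is not None and est > 0:
                m.gap_pairs.append((j.gap, est))

    # orientation vs per-scaffold length-weighted consensus
    for flist in scaffold_frags:
        if not flist:
            continue
        signed = sum(f.length if e == "+" else -f.length for f, e in flist)
        consensus = "+" if signed >= 0 else "-"
        m.n_incorrect_orientation += sum(1 for _, e in flist if e != consensus)

    # chimera cutting
    m.n_chimeras = len(fixture.chimeras)
    cuts_by_contig: dict[str, list] = defaultdict(list)
    for cut in result.cuts:
        cuts_by_contig[cut.contig].append(cut)
    for chim in fixture.chimeras:
        best = None
        for cut in cuts_by_contig.get(chim.contig, []):
            disp = abs(cut.pos - chim.junction)
            if best is None or disp < best[0]:
                best = (disp, cut)
        if best is None:
            continue
        disp, cut = best
        m.chimera_displacements.append(disp)
        half_spacing = (cut.right_anchor_start - cut.left_anchor_end) / 2
        if disp <= half_spacing + 1:
            m.chimera_cuts_correct += 1

    genome_size = sum(len(s) for s in fixture.reference.values())
    m.ng50_before = ng50((len(s) for s in fixture.target.values()), genome_size)
    m.ng50_after = ng50((len(r.sequence) for r in result.records), genome_size)
    m.fraction_placed = result.report["fraction_placed"]
    return m
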