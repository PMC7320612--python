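"""Ordered minimizer sketches of DNA sequences.

A minimizer sketch compactly represents a sequence by keeping, for every
window of ``w`` consecutive k-mers, only the k-mer with the smallest
canonical hash.  Hashes are strand-neutral: a k-mer and its reverse
complement always receive the same value, so sketches of the two strands of
a locus agree.  The position-sorted list of selected k-mers (the *ordered*
sketch) preserves the layout of the sequence at roughly 2/(w+1) of the
original k-mer density, which is what makes the downstream minimizer graph
small enough to build for whole assemblies.

Hash definition (fixed, documented, deterministic): a k-mer is fingerprinted
as the degree-(k-1) polynomial of its 2-bit base codes (A=0, C=1, G=2, T=3)
evaluated at a fixed odd 64-bit multiplier, modulo 2**64; the fingerprint is
salted and finalized with the splitmix64 mixer.  The canonical hash is the
minimum of the forward and reverse-complement hashes.  The odd multiplier is
invertible modulo 2**64, which allows all fingerprints of a sequence to be
computed with vectorized prefix sums instead of a per-k-mer loop.

K-mers containing ambiguous (non-ACGT) bases are assigned an "infinite"
sentinel hash: they are never selected, and a window in which every k-mer is
ambiguous contributes no minimizer at all.  Sequences are uppercased before
hashing, so soft-masking has no effect.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np

from .io_formats import read_fasta

logger = logging.getLogger(__name__)

MASK64 = (1 << 64) - 1
#: sentinel hash assigned to k-mers containing ambiguous bases
EMPTY_HASH = MASK64

_MULT = 0x9E3779B97F4A7C15  # odd, hence invertible modulo 2**64
_MULT_INV = pow(_MULT, -1, 1 << 64)
_SALT = 0x3C79AC492BA7B653

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT characters pass through unchanged."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SketchParams:
    """Sketching parameters: k-mer length and window size (in k-mers).

    A sequence yields a non-empty sketch only if it is at least
    ``k + w - 1`` bases long.
    """

    k: int = 32
    w: int = 1000

    def __post_init__(self):
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")

    @property
    def min_seq_len(self) -> int:
        return self.k + self.w - 1


@dataclass(frozen=True)
class MinimizerRecord:
    """One selected minimizer: strand-neutral hash, position, winning strand."""

    hash: int
    seq_id: str
    pos: int
    strand: str


@dataclass
class OrderedSketch:
    seq_id: str
    records: list[MinimizerRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & MASK64
    return x ^ (x >> 31)


def canonical_hash(kmer: str) -> tuple[int, str]:
    """Strand-neutral 64-bit hash of ``kmer`` and the strand that won.

    Returns ``(value, strand)`` with strand ``+`` if the forward k-mer
    achieved the canonical (minimum) hash, ``-`` if the reverse complement
    did; palindromic ties report ``+``.  Raises :class:`ValueError` on
    ambiguous bases.
    """
    kmer = kmer.upper()
    f = r = 0
    for b in kmer:
        c = _CODE.get(b)
        if c is None:
            raise ValueError(f"unhashable k-mer (ambiguous base {b!r})")
        f = (f * _MULT + c) & MASK64
    for b in reversed(kmer):
        r = (r * _MULT + (3 - _CODE[b])) & MASK64
    hf = _splitmix64(f ^ _SALT)
    hr = _splitmix64(r ^ _SALT)
    if hf == EMPTY_HASH:
        hf -= 1
    if hr == EMPTY_HASH:
        hr -= 1
    if hf <= hr:
        return hf, "+"
    return hr, "-"


def _splitmix64_arr(x: np.ndarray) -> np.ndarray:
    x = x + np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-ASCII character in sequence: {exc}") from exc
    codes = np.zeros(arr.size, dtype=np.uint64)
    valid = np.zeros(arr.size, dtype=bool)
    for base, code in zip(b"ACGT", range(4)):
        m = arr == base
        codes[m] = code
        valid |= m
    return codes, valid


def _kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical hashes of every k-mer of ``seq`` plus minus-strand flags.

    Ambiguous k-mers get :data:`EMPTY_HASH`.  Vectorized via prefix sums of
    the polynomial fingerprint in the wrap-around uint64 ring.
    """
    codes, valid = _encode(seq)
    n = codes.size
    nk = n - k + 1

    cpow = np.full(n, _MULT, dtype=np.uint64)
    cpow[0] = 1
    np.multiply.accumulate(cpow, out=cpow)  # cpow[t] = MULT**t mod 2**64
    cinv = np.full(n, np.uint64(_MULT_INV), dtype=np.uint64)
    cinv[0] = 1
    np.multiply.accumulate(cinv, out=cinv)

    def fingerprints(cod: np.ndarray) -> np.ndarray:
        t = np.zeros(n + 1, dtype=np.uint64)
        np.cumsum(cod * cinv, out=t[1:])
        return cpow[k - 1 : n] * (t[k:] - t[:nk])

    fwd = fingerprints(codes)
    rev = fingerprints((np.uint64(3) - codes)[::-1])[::-1]

    hf = _splitmix64_arr(fwd ^ np.uint64(_SALT))
    hr = _splitmix64_arr(rev ^ np.uint64(_SALT))
    hf[hf == np.uint64(EMPTY_HASH)] -= np.uint64(1)
    hr[hr == np.uint64(EMPTY_HASH)] -= np.uint64(1)
    canon = np.minimum(hf, hr)
    minus = hr < hf

    invalid = np.concatenate(([0], np.cumsum(~valid)))
    ambiguous = (invalid[k:] - invalid[:nk]) > 0
    canon[ambiguous] = np.uint64(EMPTY_HASH)
    return canon, minus


def compute_sketch(sequence: str, seq_id: str, params: SketchParams) -> OrderedSketch:
    """Ordered minimizer sketch of one sequence.

    Every window of ``w`` consecutive k-mers contributes its minimum-hash
    k-mer (leftmost on ties); consecutive windows selecting the same
    position collapse to a single record.  Sequences shorter than
    ``k + w - 1`` yield an empty sketch.
    """
    if len(sequence) < params.min_seq_len:
        logger.debug(
            "sequence %s (%d bp) shorter than k+w-1=%d; empty sketch",
            seq_id,
            len(sequence),
            params.min_seq_len,
        )
        return OrderedSketch(seq_id)

    canon, minus = _kmer_hashes(sequence, params.k)
    hashes = canon.tolist()
    minus_l = minus.tolist()
    nk = len(hashes)
    w = params.w

    records: list[MinimizerRecord] = []
    dq: deque[int] = deque()  # candidate positions, hashes increasing
    last = -1
    for p in range(nk):
        h = hashes[p]
        while dq and hashes[dq[-1]] > h:
            dq.pop()
        dq.append(p)
        start = p - w + 1
        if start < 0:
            continue
        while dq[0] < start:
            dq.popleft()
        m = dq[0]
        if hashes[m] != EMPTY_HASH and m != last:
            records.append(
                MinimizerRecord(
                    hashes[m], seq_id, m, "-" if minus_l[m] else "+"
                )
            )
            last = m
    return OrderedSketch(seq_id, records)


def sketch_assembly(
    fasta_path, params: SketchParams
) -> tuple[dict[str, OrderedSketch], Counter]:
    """Sketch every sequence of an assembly FASTA.

    Returns the per-sequence sketches and a counter of how many times each
    hash occurs across all sketch records of the assembly (used downstream
    to select unique anchor minimizers).
    """
    seqs = read_fasta(fasta_path)
    sketches: dict[str, OrderedSketch] = {}
    counts: Counter = Counter()
    for seq_id, seq in seqs.items():
        sk = compute_sketch(seq, seq_id, params)
        sketches[seq_id] = sk
        counts.update(rec.hash for rec in sk.records)
    logger.info(
        "sketched %s: %d sequences, %d minimizers, %d distinct hashes",
        fasta_path,
        len(sketches),
        sum(len(s) for s in sketches.values()),
        len(counts),
    )
    return sketches, counts


def sketch_tsv_text(sketches: dict[str, OrderedSketch]) -> str:
    """Optional TSV dump of sketches (seq_id, pos, strand, hash)."""
    lines = ["seq_id\tpos\tstrand\thash\n"]
    for seq_id in sketches:
        for rec in sketches[seq_id].records:
            lines.append(f"{seq_id}\t{rec.pos}\t{rec.strand}\t{rec.hash}\n")
    return "".join(lines)
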