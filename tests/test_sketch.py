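"""Minimizer sketching: hash definition, window semantics, invariants."""

from __future__ import annotations

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mxscaff.sketch import (
    EMPTY_HASH,
    SketchParams,
    canonical_hash,
    compute_sketch,
    revcomp,
    sketch_assembly,
)
from _oracles import naive_sketch_positions


def test_canonical_hash_is_deterministic():
    assert canonical_hash("ACGT") == canonical_hash("ACGT")


def test_canonical_hash_strand_symmetric(rng):
    for _ in range(50):
        k = int(rng.integers(2, 33))
        s = "".join(rng.choice(list("ACGT"), size=k))
        h1, f1 = canonical_hash(s)
        h2, f2 = canonical_hash(revcomp(s))
        assert h1 == h2
        if s != revcomp(s):
            assert {f1, f2} == {"+", "-"}


def test_canonical_hash_rejects_ambiguous_bases():
    with pytest.raises(ValueError, match="unhashable"):
        canonical_hash("ACGNACGT")


def test_canonical_hash_matches_independent_definition(rng):
    """Recompute the documented hash from scratch for 100 random 16-mers.

    The fingerprint is the polynomial of 2-bit base codes at the fixed odd
    multiplier mod 2**64, salted and passed through splitmix64; canonical
    value is the min over the two strands.
    """
    MULT = 0x9E3779B97F4A7C15
    SALT = 0x3C79AC492BA7B653
    M = 1 << 64
    code = dict(zip("ACGT", range(4)))

    def mix(x):
        x = (x + 0x9E3779B97F4A7C15) % M
        x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) % M
        x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) % M
        return x ^ (x >> 31)

    for _ in range(100):
        kmer = "".join(rng.choice(list("ACGT"), size=16))
        expected = min(
            mix(
                sum(code[b] * pow(MULT, 15 - i, M) for i, b in enumerate(s)) % M
                ^ SALT
            )
            for s in (kmer, revcomp(kmer))
        )
        assert canonical_hash(kmer)[0] == expected


def test_w1_keeps_every_valid_kmer_position(rng):
    seq = "".join(rng.choice(list("ACGT"), size=80))
    sk = compute_sketch(seq, "s", SketchParams(k=5, w=1))
    assert [r.pos for r in sk.records] == list(range(len(seq) - 4))


def test_sequence_below_minimum_length_gives_empty_sketch():
    params = SketchParams(k=8, w=4)
    seq = "A" * (params.min_seq_len - 1)
    assert len(compute_sketch(seq, "s", params)) == 0


@pytest.mark.parametrize("seed,k,w", [(0, 15, 10), (1, 4, 7), (2, 21, 32), (3, 9, 3)])
def test_sketch_matches_bruteforce_window_minimum(seed, k, w):
    rng = np.random.default_rng(seed)
    seq = "".join(
        rng.choice(list("ACGTN"), size=2000, p=[0.24, 0.24, 0.24, 0.24, 0.04])
    )
    sk = compute_sketch(seq, "s", SketchParams(k=k, w=w))
    assert [r.pos for r in sk.records] == naive_sketch_positions(seq, k, w)
    for rec in sk.records:
        assert rec.hash == canonical_hash(seq[rec.pos : rec.pos + k].upper())[0]


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    seq=st.text(alphabet="ACGTN", min_size=20, max_size=300),
    k=st.integers(2, 13),
    w=st.integers(1, 20),
)
def test_sketch_equals_oracle_property(seq, k, w):
    sk = compute_sketch(seq, "s", SketchParams(k=k, w=w))
    assert [r.pos for r in sk.records] == naive_sketch_positions(seq, k, w)


def test_sketch_records_strictly_increasing_and_window_optimal(rng):
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    params = SketchParams(k=15, w=25)
    sk = compute_sketch(seq, "s", params)
    positions = [r.pos for r in sk.records]
    assert positions == sorted(set(positions))
    assert all(0 <= p <= len(seq) - params.k for p in positions)


def test_strand_invariance_of_sketch(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2500))
    params = SketchParams(k=16, w=12)
    fwd = compute_sketch(seq, "s", params)
    rev = compute_sketch(revcomp(seq), "s", params)
    assert sorted(r.hash for r in fwd.records) == sorted(r.hash for r in rev.records)
    # positions mirror: pos' = len - k - pos
    assert sorted(len(seq) - params.k - r.pos for r in rev.records) == sorted(
        r.pos for r in fwd.records
    )


def test_increasing_w_never_grows_sketch(rng):
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    sizes = [len(compute_sketch(seq, "s", SketchParams(k=14, w=w))) for w in (1, 4, 16, 64)]
    assert sizes == sorted(sizes, reverse=True)


def test_all_ambiguous_windows_contribute_nothing():
    seq = "ACGTACGTAC" + "N" * 50 + "GTACGTACGT"
    sk = compute_sketch(seq, "s", SketchParams(k=4, w=2))
    for rec in sk.records:
        assert "N" not in seq[rec.pos : rec.pos + 4]


def test_sketch_assembly_counts_match_recount(rng, tmp_path):
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT"), size=1200)) for i in range(3)
    }
    fa = tmp_path / "asm.fa"
    fa.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
    params = SketchParams(k=12, w=8)
    sketches, counts = sketch_assembly(fa, params)
    recount = {}
    for sid, seq in seqs.items():
        for rec in compute_sketch(seq, sid, params).records:
            recount[rec.hash] = recount.get(rec.hash, 0) + 1
    assert dict(counts) == recount
    assert set(sketches) == set(seqs)


def test_duplicated_sequence_forces_multiplicity(rng, tmp_path):
    seq = "".join(rng.choice(list("ACGT"), size=900))
    fa = tmp_path / "dup.fa"
    fa.write_text(f">a\n{seq}\n>b\n{seq}\n")
    _, counts = sketch_assembly(fa, SketchParams(k=12, w=10))
    assert counts and all(c >= 2 for c in counts.values())


def test_empty_fasta_yields_empty_maps(tmp_path, caplog):
    fa = tmp_path / "empty.fa"
    fa.write_text("")
    sketches, counts = sketch_assembly(fa, SketchParams(k=12, w=10))
    assert sketches == {} and not counts


def test_gzipped_fasta_is_read(rng, tmp_path):
    seq = "".join(rng.choice(list("ACGT"), size=800))
    fa = tmp_path / "asm.fa.gz"
    with gzip.open(fa, "wt") as fh:
        fh.write(f">s1\n{seq}\n")
    sketches, _ = sketch_assembly(fa, SketchParams(k=12, w=10))
    assert len(sketches["s1"]) > 0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SketchParams(k=1, w=5)
    with pytest.raises(ValueError):
        SketchParams(k=10, w=0)
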