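# Methods

## Model of the problem

`mxscaff` treats scaffolding as a graph-linearization problem over a shared
minimizer vocabulary instead of an alignment problem. The underlying
assumption is structural synteny: the target's contigs are (possibly
rearranged, reverse-complemented, point-mutated) pieces of the same genome
architecture the reference exhibits. Wherever that assumption is violated —
true structural variation between target and reference — the method will,
by design, fit the target to the reference's structure; `no_cut` limits the
damage to ordering decisions by never splitting input contigs.

## Sketching

The k-mer hash is fixed and documented so that sketches are reproducible
across runs and machines: a k-mer maps to the polynomial of its 2-bit base
codes evaluated at the odd constant `0x9E3779B97F4A7C15` modulo 2^64,
XOR-salted and finalized with the splitmix64 mixer; the canonical value is
the minimum over the forward and reverse-complement hashes. Because the
multiplier is odd (hence invertible mod 2^64), all fingerprints of a
sequence are computed with vectorized prefix sums; window minima are then
selected with a monotonic deque, which keeps exact leftmost-tie semantics.

Numerical/edge choices:

- **Ties.** Two k-mers in one window can share a canonical hash (typically a
  k-mer co-occurring with its reverse complement at small k). The leftmost
  one wins. A consequence worth knowing: strand invariance of the sketch is
  exact only in the absence of such ties, because "leftmost" mirrors to
  "rightmost" on the other strand. At assembly scale with k ≥ 20 ties are
  vanishingly rare.
- **Ambiguous bases.** K-mers containing non-ACGT characters get a sentinel
  "infinite" hash; they are never selected, and a window whose k-mers are
  all ambiguous contributes nothing. This prevents N-runs in two assemblies
  from producing spurious shared minimizers.
- **Case.** Sequences are uppercased before hashing; soft-masking
  conventions differ between assemblies and must not affect the mapping.
- **Defaults.** `k=32`, `w=1000` are conservative assembly-scale defaults
  (sketch density ~1/500 bases). For small test genomes the examples use
  `k=20–24`, `w=100–250`, which keeps anchor spacing well below fragment
  sizes.

## Anchors

Only minimizers occurring **exactly once in every input** become graph
nodes. Uniqueness within each input gives an unambiguous node-to-position
mapping; presence in all inputs makes edge weights comparable across the
graph (every potential edge had the same chance of support from every
input). With several references this is the strict "present in all"
variant; a divergent reference therefore shrinks the anchor set rather than
diluting edge weights. An empty anchor set aborts with advice (smaller `w`
or `k`, or a closer reference).

## Graph filtering

Edges carry the set of supporting inputs; the weight is always recomputed
as the sum of the support's weights, so filtering can never desynchronize
weight and support. The three linearization stages are:

1. **Global threshold `n`** (default: minimum reference weight). The
   default guarantees reference-supported adjacencies survive while
   target-only adjacencies — e.g. the two sides of a chimeric junction —
   are removed when the target weight is below every reference weight.
2. **Branch resolution.** Nodes are processed in sorted-hash order (pure
   determinism; no ordering is inherently preferable). For a node of degree
   > 2 the distinct incident weights are tried ascending as thresholds,
   dropping lighter incident edges, stopping once degree < 3; if all
   survivors tie at the maximum weight the node's remaining incident edges
   are all removed (the tie cannot be resolved by weight).
3. **Cycle breaking.** A component that is still a cycle is broken at its
   minimum-weight edge (ties: smallest sorted hash pair).

## Path translation, cutting, gaps

Anchors of a linear path are looked up in the target; maximal blocks from
one contig, split further at monotonicity breaks in target position, become
oriented runs. Single-anchor blocks are dropped (orientation would be a
guess) and counted in the report. Each path is finally flipped, if needed,
so that the majority of its bases are on forward-oriented runs — the
path direction itself is arbitrary, and this makes self-scaffolding
reproduce inputs forward, byte-stable.

**Misassembly cutting** is purely structural: a contig whose anchors fall
in ≥ 2 runs is cut at the midpoint of the unanchored interval between
adjacent anchored spans. The true breakpoint is unobservable between
anchors; the midpoint bounds the displacement by half the local anchor
spacing. Outermost pieces extend to the contig ends. Under `no_cut` a
contested contig goes, whole, to the run with the most of its anchors
(ties: larger anchored span, then the earliest path), and is removed from
the others; both halves of every decision stay in the output (placed or
unplaced), so base conservation holds in every mode.

**Gap estimation** between adjacent runs: the reference distance between
the two boundary anchors, minus the runs' own unanchored flanks, clamped
below at `min_gap` (default 20 bp — a small positive floor that keeps
junction coordinates valid and visible; gaps are otherwise fully
reference-derived). If the boundary anchors never co-occur on one reference
sequence the gap falls back to `min_gap`. The estimate's error is bounded
by the local anchor spacing (order `w` bases), not by the spacer size.

## Synthetic fixtures: what they do and do not show

The generator emulates the intended use-cases at desk scale: uniform random
chromosomes, a target made of shuffled / reverse-complemented / point-mutated
fragments, optional chimeric contigs joining fragments of different
chromosomes, and spacer deletions that create known true gaps. Default study
conditions used by the tests and the acceptance script: 2 chromosomes ×
1 Mb, fragments ~N(40 kb, 10 kb) (≈ 50 fragments), 50% reverse-complement
probability, shuffling on, and, per scenario, 1% substitution rate
(divergence proxy), 5 chimeras, or 5 spacer deletions of 100–2000 bp;
pipeline parameters k = 24, w = 250, weights 1 (target) / 2 (reference).

Uniform DNA makes unique minimizers abundant, so these fixtures test the
algorithm's correctness, not its robustness to repeats: real genomes have
repeat families that deplete anchors locally and can leave repeat-spanning
contigs unplaced or unordered. Passing these tests therefore demonstrates
correct order/orientation recovery, chimera detection and gap estimation
under clean synteny — not performance on repeat-rich or highly diverged
genomes.

## Known limitations

- Anchors must be unique in *every* input; large genomes with heavy
  duplication need larger `w`/`k` to retain a usable anchor set.
- Contigs contributing fewer than two anchors are never placed (orientation
  would be arbitrary); with default parameters this is anything shorter
  than a few times `w` bases.
- One target per run; no iterative re-scaffolding.
- Gap estimates inherit reference indel structure; a reference insertion
  between two target contigs inflates the estimated gap.
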