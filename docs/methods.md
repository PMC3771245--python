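# Methods

`gonet` infers **split networks** from gene-order data. A genome is a
linear signed permutation of integer gene labels (absolute value =
homologous marker, sign = strand); all genomes in a dataset share one
gene set, and the only evolutionary operation modelled is the
**inversion** (reversal of a contiguous interval with sign flips).
Because a single tree often cannot represent the conflicting signal in
rearrangement data, the package converts genome sets into three kinds of
intermediate data and feeds each to a network-construction algorithm
whose universal output is a weighted set of taxon bipartitions
(*splits*). No split filtering is applied anywhere beyond what each
algorithm itself defines: weights are reported exactly as produced.

## Exact inversion distance

The pairwise distance between two signed permutations is the minimum
number of inversions transforming one into the other, computed exactly
by the Hannenhalli–Pevzner breakpoint-graph decomposition

    d = (n + 1) − c + h + f,

with `c` the number of alternating cycles, `h` the number of hurdles and
`f = 1` for a fortress. Each gene is doubled into two endpoints, framed
by 0 and 2n+1; black edges join consecutive position pairs, gray edges
join consecutive value pairs. A gray edge is oriented iff its endpoint
positions share parity; connected components of the gray-edge
interleaving graph with no oriented edge (and at least one breakpoint)
are the unoriented components. Component extents are laminar, so the
hurdle test reduces to checking whether all other unoriented components
occupy a single arc of the position circle after removing the
component; a hurdle is *super* if deleting it promotes a non-hurdle to a
hurdle, and a fortress has an odd number of hurdles, all super.

Correctness is not taken on faith: an independent breadth-first-search
oracle over the inversion move graph (feasible up to 8 genes; the full
space has 2^n·n! states) arbitrates. The test suite compares the two
exhaustively over all signed permutations of up to 5 genes and on 200+
random pairs at 6 and 7 genes.

## The three intermediates and four network methods

**Jackknife trees → consensus network.** Each replicate removes the
same randomly chosen 40% of genes (`floor(0.4·n)`, shared across all
genomes so the common-gene-set invariant holds), preserving order and
signs of the rest; 100 replicates by default. The built-in tree
estimator is neighbor joining on exact inversion distances, with two
determinism-motivated choices: ties in the Q criterion break toward the
lowest creation-order pair, and internal edges whose *estimated* length
is non-positive are contracted, so edges without distance signal appear
as multifurcations rather than as an arbitrary but systematic
resolution (important here because jackknifed integer distances tie
often; externally built trees, e.g. from a gene-order parsimony
program, can be supplied instead as multi-tree Newick). The consensus
network keeps every split present in ≥ 10% of the trees, weighted by
that fraction (the jackknife support). The threshold comparison is done
with exact rationals, so the boundary (10 of 100 trees) is included and
9 of 100 is not, regardless of floating-point representation.

**Distance matrix → split decomposition / Neighbor-Net.** Split
decomposition keeps every split with strictly positive isolation index
α (weight = α); the output is provably weakly compatible. It is built
by the hereditary taxon-insertion algorithm and cross-checked in tests
against exhaustive enumeration up to 8 taxa. Neighbor-Net agglomerates
taxa into a circular ordering (NJ-style selection over clusters of one
or two linked nodes; 3-node paths reduce to 2 with the 2/3–1/3
averaging formulas) and then fits non-negative least-squares weights to
all n(n−1)/2 arc splits of the ordering against the observed distances.
Weights below 1e−9 × max distance are treated as numerical zeros of the
NNLS solver and dropped; every weight above that is kept. On additive
inputs both methods reduce to the generating tree (splits and branch
lengths), which the acceptance tests assert at 1e−6 on random 6–8-taxon
tree metrics. Distances are used raw (no rearrangement-saturation
correction).

**Binary encoding → parsimony splits.** The encoding has one column
per gene pair {N < M} in each of four relative orientations
(+N +M / +M +N / +N −M / −N +M), 2n(n−1) columns total. An ordered
adjacency (a, b) and its reverse reading (−b, −a) denote the same
junction, so adjacencies are canonicalized with the smaller absolute
label first; exactly one column fires per junction, each row of an
m-gene linear genome has m−1 ones, and a genome and its full reversal
encode identically. Parsimony splits uses quartet pattern counts
c(ij|kl) and the index β(ij|kl) = c(ij|kl) − max(c(ik|jl), c(il|jk));
a split is kept iff β > 0 (strict dominance) for every quartet across
it, weighted by the minimal β (an integer ≥ 1). Construction is again
incremental with an exhaustive small-n oracle. Trivial splits have no
defining quartet; they are reported unconditionally with a degenerate
pair-count weight, which is presentation-only since evaluation ignores
trivial splits.

## Evaluation and simulation

Networks are scored against a known tree on **nontrivial splits only,
ignoring weights**: sensitivity = tp/(tp+fn), PPV = tp/(tp+fp). When a
ratio's denominator is zero (star true tree, or an empty network) it is
reported as 1.0 with an explicit degenerate flag so aggregation stays
honest.

The simulation draws a Yule (pure-birth) topology — two initial
lineages, a uniformly chosen extant lineage splits until n leaves —
assigns each branch k ~ Poisson(λ) inversions, and evolves the identity
permutation of 100 genes from the root, each inversion reversing an
interval drawn uniformly among all m(m+1)/2 intervals (single-gene sign
flips included). Leaf permutations go to all four methods, so methods
are compared on identical inputs; everything derives from one master
seed via spawned substreams and is bit-reproducible.

Poisson zeros are **kept**: a topologically binary true tree can carry
branches with no inversions. This matters for interpretation: at λ = 1
about e⁻¹ ≈ 37% of internal branches leave no trace in the data, so no
method can be expected to exceed ≈ 63% sensitivity plus whatever
zero-signal edges it recovers by chance, and mean sensitivity *rises*
with λ (more branches become detectable) while PPV falls for the
less conservative methods (Neighbor-Net most visibly, from ≈ 1.0 to
≈ 0.4 across λ = 1..10 in the scaled runs). Had zero-length branches
been resampled, sensitivity would instead start high and decay; the
untruncated distribution was chosen because zero is in the Poisson
support and truncation is an extra assumption. The weight-blindness of
the scoring also means a vanishingly small split counts fully — a
conservative bias against weight-rich methods that is inherent to this
evaluation design.

Default problem sizes for the shipped experiments were scaled for a
desk run: the simulation acceptance check uses 10 taxa, 20 replicate
trees per λ over λ = 1..10 with 50 jackknife replicates inside the
consensus route, and the acceptance script uses λ ∈ {1, 5, 10} with 10
replicates; the library defaults remain the reference protocol values
(100 replicate trees, 100 jackknife replicates).

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.Generator`; jackknife
  replicate r uses seed `master + r`, simulation replicates use spawned
  `SeedSequence` children. Seeds are plain Python ints < 2³¹.
- NJ branch lengths are clamped at 0 after estimation; the collapse
  rule uses the pre-clamp estimate.
- Isolation indices on integer matrices involve only exact
  float-representable arithmetic; the strict α > 0 inclusion rule is
  therefore exact for integer inputs. For float matrices the caller
  should be aware that additivity violations at round-off scale can
  create tiny positive indices (test fixtures use dyadic branch lengths
  so path sums are exact).
- `is_circular` without a candidate ordering searches all cyclic orders
  and is guarded at 10 taxa; Neighbor-Net outputs carry their ordering
  so the check is O(k·n²).
- Fewer than 4 taxa: Neighbor-Net and parsimony splits return trivial
  splits only; 3-taxon NJ returns the star.

## What the generator does and does not emulate

The simulator produces inversion-only, equal-gene-content, linear,
unichromosomal histories with uniform interval choice. Real gene-order
datasets add phenomena outside this model: unequal gene content,
duplications and inverted repeats (circular chloroplast genomes must be
linearized and reduced to shared single-copy markers before input),
translocations/DCJ in multichromosomal genomes, and hotspot-biased
rather than uniform breakpoints. Passing simulation checks therefore
demonstrates correctness of the algorithms and the qualitative
method ranking under the inversion model, not performance guarantees on
real genomes.

## Known limitations

- The built-in jackknife tree estimator is distance-based NJ, not
  gene-order parsimony; support values will differ from pipelines that
  use a parsimony or median-based tree program (plug such trees in via
  Newick if needed).
- Hurdle/fortress analysis is O(E²) per pair in the worst case —
  ample at desk scale (hundreds of genes, tens of taxa), not tuned for
  thousands of genes.
- Network *drawing* is out of scope; outputs are SplitsTree4-readable
  NEXUS splits blocks.
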