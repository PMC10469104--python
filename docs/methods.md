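# Methods

`pepspace` analyzes the chemical space of short bioactive peptides
(antimicrobial peptides and related classes, typically ≤ ~50 residues).
The pipeline is: sequences → per-residue physicochemical profiles →
aggregation-operator descriptors → (optional) unsupervised feature
selection → pairwise similarities → networks → communities, centralities
and scaffolds → one-class screening models. This note records the
models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Physicochemical model

Net charge uses the two-sided Henderson–Hasselbalch sum over ionizable
groups — N-terminus and K/R/H side chains contribute
`10^pKa / (10^pKa + 10^pH)`, C-terminus and D/E/C/Y side chains
contribute `-10^pH / (10^pKa + 10^pH)` — with the Lehninger pKa set
(N-term 9.69, C-term 2.34, K 10.53, R 12.48, H 6.0, D 3.65, E 4.25,
C 8.33, Y 10.07). The charge is strictly decreasing in pH, so the
isoelectric point is the unique root, found by bisection on [0, 14] to
|charge| < 1e-4. Nine per-residue scales ship embedded
(`pepspace.scales`): Kyte–Doolittle and Eisenberg hydrophobicity,
nominal side-chain charge at pH 7, average residue mass (Da), free-residue
pI, residue volume (Å³), Grantham polarity, normalized B-factor
flexibility, and Chou–Fasman helix propensity. The unknown residue `X`
always takes the arithmetic mean of the 20 canonical values of a scale,
so any valid sequence stays computable; `X` carries no ionizable group
and scores 0 against everything in alignments.

## Descriptors

Each (peptide, scale) pair yields a per-residue profile, collapsed to a
scalar by 14 operators: 12 statistical (min, max, range, sum, mean,
median, population variance, std, skewness, kurtosis, q1, q3 — moments
of constant profiles are 0 by convention, quartiles use linear
interpolation), the discrete **Choquet integral**, and **GOWAWA**. With
9 scales this gives the default 126-column matrix; both lists are
configurable.

The Choquet integral uses a Sugeno λ-measure with uniform densities
`g_i = 0.9/n` per profile position (λ solved by bisection of
`∏(1+λg_i) = 1+λ`; the 0.9 total gives a genuinely non-additive measure
with positive interaction while keeping a single parameter). When the
densities sum to 1 the measure is additive and the integral reduces
exactly to the weighted mean — the property the test suite exploits as
an oracle. GOWAWA computes
`(Σ_j v̂_j b_j^λ_g)^(1/λ_g)` over the descending-sorted profile with
`v̂_j = β v_j + (1-β) w_{σ(j)}`; defaults λ_g = 1, β = 0.5, both weight
vectors uniform (reducing to the arithmetic mean until a user overrides
them). Named weight generators ("uniform", quantifier `Q(r) = r²`)
adapt to each peptide's length automatically; explicit vectors are
truncated or last-value-extended, then renormalized. Both fuzzy/non-fuzzy
operators require non-negative comparable inputs, so profiles are
min–max scaled per scale across the dataset first; statistical operators
see raw profiles. Sorting ties break by original position (stable sort)
for determinism. λ_g = 0 is rejected rather than silently replaced by
the geometric-mean limit.

A fitted `DescriptorCalculator` stores the per-scale min/max, so
external query sequences are projected into the *same* space (clipped to
[0, 1]) — this is what makes k-NN overlay and descriptor-based screening
coherent.

## Feature selection

Two unsupervised stages sharing one equal-width binning (default 10
bins): (1) drop columns with Shannon entropy below
`rel_cutoff · log2(bins)` (default rel_cutoff 0.3); (2) visit the
survivors by entropy descending (ties by name) and greedily keep a
column only if its normalized mutual information to every kept column is
below `nmi_cutoff` (default 0.7). NMI is `MI / min(H_x, H_y)`, which
reaches exactly 1 for deterministic dependence under shared bins, and is
defined as 0 when either entropy is 0. The greedy order keeps the most
informative representative of each redundant group; the pipeline is
deterministic and idempotent on its own output.

## Similarities and networks

Eight distances over descriptor rows: Euclidean, Manhattan, Chebyshev,
Canberra, Soergel, Bhattacharyya, angular separation, Wave–Hedges.
Bhattacharyya is implemented in its Matusita (metric) form
`√Σ(√x−√y)²`, which needs no unit-sum normalization; 0/0 terms in
Canberra/Soergel/Wave–Hedges contribute 0; the angular distance of a
zero vector against a non-zero vector is 1 (0 against another zero
vector). Distances map to similarities by `s = 1/(1+d)` (default,
dataset-independent) or `s = 1 − d/d_max` with the dataset's off-diagonal
maximum (tight [0, 1] cutoff semantics). Matrices containing negative
values are min–max normalized before the non-negative-only metrics.

**CSN** (chemical space network): edge iff similarity ≥ θ; monotone
non-increasing in θ; θ = 0 is the complete graph. **HSPN** (half-space
proximal network): from each node, repeatedly take the nearest remaining
point `v` (ties by node index), connect, and discard every remaining `w`
with `d(w,v) < d(w,u)` — strict, so equidistant candidates survive; the
per-node directed selections are merged by union. The HSPN needs no
threshold, its edges are a subset of the complete CSN, and under the
Euclidean metric it is empirically connected for points in general
position. An optional similarity floor can prune its edges afterwards
(off by default). **METN**: bipartite peptide × "relation:term" graph,
unit weights, one edge per distinct annotation triple.

## Graph analytics

Path-based measures use edge length `1/w` (identical peptides, w = 1,
sit at distance 1 — no zero-length edges), via networkx: Brandes
betweenness (unnormalized by default; normalization divides by
(N−1)(N−2)/2), harmonic centrality (unreachable pairs contribute 0), and
Dijkstra shortest paths (unreachable → empty path, +∞). Weighted Newman
modularity `Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j)` is
implemented directly and cross-checked against networkx in the tests.

**Hub-bridge centrality** has no published closed form; this package
concretizes it as `weighted_degree(v) · (1 + P(v))` with
`P(v) = 1 − Σ_c (k_{v,c}/k_v)²` the weighted participation coefficient —
equal to weighted degree for a node whose neighbors all share its
community, and up to twice that for a node spreading evenly across many
communities. Treat cross-study comparisons of this quantity with care.

Community detection: Louvain (seed-shuffled node order, via networkx;
the partition's Q is always reported so nondeterminism is auditable),
k-means and average-linkage hierarchical clustering in *descriptor*
space (they group nodes by descriptor profile, not by graph topology),
and a Uclust-style greedy centroid pass over the similarity matrix
(visit by weighted degree descending; join the first centroid with
similarity ≥ θ_c, else found a new one). Singletons are nodes that are
isolated or alone in their community — both readings are included.
Scaffold extraction takes the top-k (default 1) nodes per non-singleton
community by a chosen centrality (ties by id) plus all singletons.

## Alignment

Needleman–Wunsch (global) and Smith–Waterman (local) with affine gaps —
a gap of length L costs `gap_open + (L−1)·gap_extend`, defaults 10/0.5 —
through Bio.Align.PairwiseAligner with BLOSUM62 (X row/column zeroed).
When several tracebacks are optimal the aligner's first (deterministic)
alignment is reported; scores and identity contracts do not depend on
the tie order. Identity = matches / alignment length (columns including
gaps) for global, matches / aligned-region length for local; a local
alignment with no positive-scoring cell is empty with identity 0.
Non-redundant sets are built greedily longest-first (ties by id),
accepting a peptide iff its identity to every accepted one is strictly
below the threshold — deterministic and idempotent.

## mQSSM screening

A model is a query set (typically a scaffold), a similarity kind, a
fusion rule (MAX/MEAN/MIN) and a threshold θ_q ∈ [0, 1]; a target is
positive iff the fused similarity ≥ θ_q. No negative examples are read
at any point — the builder's interface takes none. The default
similarity, `local_identity`, is **coverage-corrected**: Smith–Waterman
matches divided by the *shorter sequence length*, not by the aligned
columns. The aligned-column normalization lets a single-residue perfect
segment between unrelated peptides score 1.0, which destroys
specificity at any useful threshold; dividing by the shorter sequence
rewards alignments that actually cover a sequence. `global_identity`
(alignment-column normalized) and `descriptor` (reciprocal similarity of
descriptor vectors) are alternatives. Models persist as plain FASTA plus
a key–value sidecar.

## Synthetic data

Fixtures emulate the clustered structure of curated peptide
collections: each family is a uniform-random seed peptide (default
length 25) mutated per member with i.i.d. substitutions (uniform over
the 19 alternatives) and optional rare indels (off by default so
alignment identities have analytic expectations); backgrounds are
uniform-random sequences of length 15–35. The generator is
deterministic given its seed. It deliberately has no residue-composition
bias, no length–family correlation, and no physicochemical realism, so
passing tests demonstrate correct *method* behavior on clustered
sequence data, not predictive performance on real antimicrobial
peptides.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run at desk scale by design:
networks of ~30–75 peptides, 200 random planar point sets for the HSP
property checks, 1000 random vector pairs/triples for the metric suite,
50 random graphs of 6–10 nodes against exhaustive path-enumeration
oracles, all 203 partitions of the 6-node two-triangle graph for the
modularity maximum, and a screening experiment with 20 family members
plus 50 backgrounds (10 members train the scaffold, 10 are held out).
Alignment DP scores are checked against an exhaustive move-enumeration
oracle on a seeded sample of sequence pairs of lengths 1–6 over a
4-letter sub-alphabet. Oracle graph weights are drawn from
{0.25, 0.5, 1.0} so reciprocal path lengths are exact integers and
shortest-path ties are compared exactly.

## Known limitations

- Chemically modified residues, D-amino acids and cyclic peptides are
  out of scope; sequences are strings over the 20 canonical residues
  plus `X`.
- All-pairs alignment and similarity computation are O(n²); the package
  targets datasets of hundreds to a few thousand peptides, not full
  database scale.
- The hub-bridge formula and the coverage-corrected local identity are
  this package's own concretizations of field-named but undefined
  quantities (documented above).
- Louvain is a heuristic: the reported Q is the audit trail, and only on
  tiny instances (e.g. the two-triangle graph) is optimality guaranteed
  by the tests.
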