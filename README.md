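# pepspace

Chemical-space analysis of bioactive peptides — antimicrobial peptides
and related classes — with complex networks and similarity searching
instead of trained classifiers.

Peptide collections overlap heavily across source databases, and the
question "which families live in this set, which members represent
them, and does a new sequence belong?" is naturally a network question.
`pepspace` provides the computational pipeline for it:

1. **Descriptors.** Every peptide becomes a per-residue physicochemical
   profile (9 embedded scales: hydrophobicity, charge, mass, volume,
   polarity, flexibility, helix propensity, …), collapsed to scalars by
   14 aggregation operators — statistical moments, the **Choquet
   integral** with respect to a Sugeno λ-measure
   (`C = Σ (x_(i) − x_(i−1)) μ(A_(i))`, reducing to a weighted mean for
   additive μ), and **GOWAWA**
   (`(Σ_j v̂_j b_j^λ)^{1/λ}`, mixing sorted-position and importance
   weights). Default space: 126 descriptors.
2. **Feature selection.** Two unsupervised stages: Shannon-entropy
   filtering, then greedy redundancy removal by normalized mutual
   information `NMI = MI/min(H_x, H_y)`.
3. **Networks.** Eight similarity metrics (Euclidean … Wave–Hedges)
   feed two builders: threshold **chemical space networks** (edge iff
   `s ≥ θ`) and parameter-free **half-space proximal networks** (connect
   each node to its nearest remaining neighbor, discard every point
   closer to that neighbor than to the source, repeat). Bipartite
   **metadata networks** link peptides to annotation terms.
4. **Analytics.** Density, weighted Newman modularity, four centralities
   (weighted degree, betweenness, harmonic, hub-bridge), community
   detection (Louvain, k-means, hierarchical, Uclust-style), singleton
   identification, scaffold extraction, shortest paths, and k-NN overlay
   of external sequences.
5. **Screening.** Multi-query similarity-searching models (mQSSMs):
   untrained one-class classifiers that fuse a target's similarities to
   a scaffold query set (MAX/MEAN/MIN) and threshold the fused score —
   no negative training data at any point.

Alignment (Needleman–Wunsch / Smith–Waterman, BLOSUM62, affine gaps),
identity queries, non-redundant set construction, a boolean filter
grammar over peptide attributes, and a synthetic generator of planted
peptide families round out the toolbox. See `docs/methods.md` for the
models and design choices in detail.

## Worked example

`examples/03_scaffold_and_screening.py` builds a half-space proximal
network over 10 known members of a synthetic peptide family, extracts a
5-query scaffold via Louvain communities and weighted-degree centrality,
and screens 10 held-out members plus 50 random background peptides:

```
$ python examples/03_scaffold_and_screening.py
scaffold queries: famA_0, famA_3, famA_4, famA_5, famA_7
screened 60 targets (10 held-out positives, 50 backgrounds)
sensitivity = 1.00, specificity = 1.00, MCC = 1.00
```

All held-out family members are recovered and every background peptide
is rejected, from a model that never saw a negative example. The other
examples cover descriptor computation and selection
(`01_descriptors_and_selection.py`), CSN-vs-HSPN construction and
community structure (`02_similarity_networks.py`), and filters,
alignment and redundancy removal (`04_filters_and_alignment.py`).

The same pipeline is scriptable from the shell:

```bash
pepspace synth --families 2 --members 8 --background 10 --seed 7 --out db.fasta
pepspace describe --in db.fasta --out md.csv
pepspace select-features --in md.csv --out sel.csv
pepspace network hspn --in sel.csv --out net.graphml
pepspace analyze communities --net net.graphml --seed 7 --out part.tsv
pepspace scaffold --net net.graphml --fasta db.fasta --communities part.tsv --out scaffold.fasta
pepspace search build --queries scaffold.fasta --model model
pepspace search score --model model --targets db.fasta --out hits.tsv
```

With a fixed `--seed`, every output file is byte-identical across runs.

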