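"""Compute aggregation-operator descriptors and reduce them.

Generates a small synthetic peptide set, projects every peptide into the
default 126-dimensional descriptor space (9 physicochemical scales x 14
aggregation operators), then runs the two-stage unsupervised feature
selection: a Shannon-entropy filter followed by greedy normalized-
mutual-information redundancy removal.
"""

from pepspace import (
    FamilySpec,
    compute_descriptor_matrix,
    make_dataset,
    select_features,
)

peptides, _ = make_dataset(
    [FamilySpec(seed_length=25, n_members=10, substitution_rate=0.1,
                label=f"fam{i}") for i in range(2)],
    n_background=10,
    rng_seed=42,
)

matrix = compute_descriptor_matrix(peptides)
print(f"descriptor matrix: {len(matrix.ids)} peptides x "
      f"{len(matrix.columns)} descriptors")

reduced, report = select_features(matrix)
print(f"after selection:   {len(report.kept)} descriptors kept, "
      f"{len(report.dropped_stage1)} dropped by entropy, "
      f"{len(report.dropped_stage2)} dropped as redundant")
print("first kept descriptors:", ", ".join(report.kept[:4]))

# Each kept column is one scale/operator pair; a column survives only if
# its histogram carries information (stage 1) and it is not a near-copy
# of a more informative column (stage 2).
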