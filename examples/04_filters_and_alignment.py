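"""Physicochemical filters, pairwise alignment and redundancy removal.

Shows the boolean filter grammar over peptide attributes, the
Henderson-Hasselbalch charge/pI model, BLOSUM62 alignment with percent
identity, and greedy construction of a non-redundant set.
"""

from pepspace import (
    FamilySpec,
    align,
    filter_peptides,
    isoelectric_point,
    make_dataset,
    net_charge,
    nonredundant_set,
    percent_identity,
)

peptides, _ = make_dataset(
    [FamilySpec(seed_length=22, n_members=8, substitution_rate=0.1,
                label="famA")],
    n_background=8,
    rng_seed=3,
)

cationic = filter_peptides(list(peptides), "net_charge>0 AND length>=15")
print(f"cationic subset: {len(cationic)}/{len(peptides)} peptides")

p = peptides[0]
print(f"{p.id}: charge(pH 7) = {net_charge(p.sequence):+.2f}, "
      f"pI = {isoelectric_point(p.sequence):.2f}")

a, b = peptides[0], peptides[1]
r = align(a.sequence, b.sequence, mode="global")
print(f"global alignment {a.id} vs {b.id}: score {r.score:.1f}, "
      f"identity {percent_identity(r):.1f}%")

nr = nonredundant_set(peptides, threshold_pct=80.0)
print(f"non-redundant at <80% identity: {len(nr)}/{len(peptides)} kept")
# Family members above the identity threshold collapse onto one
# representative (longest first); random backgrounds all survive.
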