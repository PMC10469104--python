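"""Synthetic peptide datasets with planted family structure.

Families are generated by mutating a random seed peptide: each member is
the seed with i.i.d. per-position substitutions (uniform over the 19
alternative residues) and, optionally, rare indels.  Background peptides
are uniform random sequences.  Every dataset is deterministic given its
seed, so networks, scaffolds and screening models built on it are fully
reproducible.

These fixtures emulate the clustered structure of curated peptide
collections (families of related sequences against an unrelated
background); they make no claim of physicochemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CANONICAL_RESIDUES, Peptide, PeptideSet


@dataclass
class FamilySpec:
    """Parameters of one planted family.

    ``substitution_rate`` is the per-position probability that a member
    differs from the seed; ``indel_rate`` the per-position probability of
    an insertion or deletion (off by default so alignment identities have
    analytic expectations).
    """

    seed_length: int = 20
    n_members: int = 10
    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    label: str = "fam"

    def __post_init__(self) -> None:
        if self.seed_length < 5:
            raise ValueError("seed_length must be >= 5")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if not 0.0 <= self.indel_rate <= 0.1:
            raise ValueError("indel_rate must lie in [0, 0.1]")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_RESIDUES), size=length))


def _mutate(rng: np.random.Generator, seed: str, spec: FamilySpec) -> str:
    out = []
    for residue in seed:
        if spec.indel_rate and rng.random() < spec.indel_rate / 2:
            continue  # deletion
        r = residue
        if rng.random() < spec.substitution_rate:
            alternatives = CANONICAL_RESIDUES.replace(residue, "")
            r = alternatives[rng.integers(len(alternatives))]
        out.append(r)
        if spec.indel_rate and rng.random() < spec.indel_rate / 2:
            out.append(CANONICAL_RESIDUES[rng.integers(20)])  # insertion
    if len(out) < 1:  # pathological all-deleted case
        out.append(seed[0])
    return "".join(out)


def make_family(
    spec: FamilySpec, rng_seed: int, id_prefix: str | None = None
) -> PeptideSet:
    """Generate one family; members carry a ("family", label) annotation."""
    rng = np.random.default_rng(rng_seed)
    seed_seq = _random_sequence(rng, spec.seed_length)
    prefix = id_prefix or spec.label
    peptides = [
        Peptide(
            id=f"{prefix}_{i}",
            sequence=_mutate(rng, seed_seq, spec),
            annotations=[("family", spec.label)],
        )
        for i in range(spec.n_members)
    ]
    return PeptideSet(peptides, source="synthetic")


def make_dataset(
    family_specs: list[FamilySpec],
    n_background: int = 0,
    bg_length_range: tuple[int, int] = (15, 35),
    rng_seed: int = 0,
) -> tuple[PeptideSet, dict[str, str]]:
    """Families plus uniform-random background peptides.

    Ids are ``<label>_<i>`` for family members and ``bg_<i>`` for
    background; the returned label map assigns each id its family label
    or ``"background"``.
    """
    rng = np.random.default_rng(rng_seed)
    peptides: list[Peptide] = []
    labels: dict[str, str] = {}
    for k, spec in enumerate(family_specs):
        fam = make_family(spec, rng_seed=int(rng.integers(2 ** 31)),
                          id_prefix=spec.label)
        for p in fam:
            peptides.append(p)
            labels[p.id] = spec.label
    lo, hi = bg_length_range
    for i in range(n_background):
        length = int(rng.integers(lo, hi + 1))
        p = Peptide(id=f"bg_{i}", sequence=_random_sequence(rng, length),
                    annotations=[("family", "background")])
        peptides.append(p)
        labels[p.id] = "background"
    return PeptideSet(peptides, source="synthetic"), labels


def dataset_annotations(peptides: PeptideSet) -> list[tuple[str, str, str]]:
    """Flatten attached annotations into (id, relation, term) triples."""
    return [(p.id, rel, term) for p in peptides for rel, term in p.annotations]
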