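"""Core domain types: peptides and ordered peptide collections.

A :class:`Peptide` is a single sequence record over the 20 canonical amino
acids plus ``X`` (unknown residue).  A :class:`PeptideSet` is an ordered,
id-unique collection; its order defines the row order of every derived
matrix and network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(CANONICAL_RESIDUES) | {"X"}


@dataclass
class Peptide:
    """One peptide record.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a :class:`PeptideSet`.
    sequence : str
        Residues over ``ACDEFGHIKLMNPQRSTVWY`` plus ``X``; stored uppercased.
    annotations : list of (relation, term)
        Optional metadata triples attached to this peptide, e.g.
        ``("function", "antibacterial")``.
    """

    id: str
    sequence: str
    annotations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("peptide id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"peptide {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"peptide {self.id!r}: illegal residue character(s) "
                f"{sorted(bad)!r}; allowed alphabet is "
                f"{CANONICAL_RESIDUES + 'X'}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class PeptideSet:
    """Ordered collection of peptides with pairwise-distinct ids."""

    def __init__(self, peptides: Iterable[Peptide], source: str = "memory"):
        self.peptides: list[Peptide] = list(peptides)
        self.source = source
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise ValueError(f"duplicate id {p.id}")
            seen.add(p.id)
        self._index = {p.id: p for p in self.peptides}

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, key: int | str) -> Peptide:
        if isinstance(key, str):
            return self._index[key]
        return self.peptides[key]

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def subset(self, ids: Iterable[str], source: str | None = None) -> "PeptideSet":
        """Return the peptides with the given ids, in this set's order."""
        wanted = set(ids)
        return PeptideSet(
            [p for p in self.peptides if p.id in wanted],
            source=source or self.source,
        )

    def __repr__(self) -> str:
        return f"PeptideSet(n={len(self)}, source={self.source!r})"
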