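"""Pairwise sequence alignment, percent identity, identity queries and
non-redundant set construction.

Global alignment is Needleman–Wunsch and local is Smith–Waterman, both
with affine gaps (a gap of length L costs ``gap_open + (L-1)*gap_extend``)
through Bio.Align.PairwiseAligner.  The default substitution matrix is
BLOSUM62 with the ``X`` (unknown residue) row and column set to score 0
against everything.  Identity is counted over alignment columns:
matches / alignment length for global, matches / aligned-region length
for local; an empty local alignment has identity 0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .core import PeptideSet

logger = logging.getLogger(__name__)

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@lru_cache(maxsize=8)
def load_matrix(name: str = DEFAULT_MATRIX):
    """Substitution matrix with the X row/column zeroed."""
    m = substitution_matrices.load(name)
    if "X" in m.alphabet:
        for letter in m.alphabet:
            m["X", letter] = 0.0
            m[letter, "X"] = 0.0
    return m


@dataclass
class AlignmentResult:
    mode: str
    score: float
    aligned_a: str
    aligned_b: str
    identity_fraction: float
    matrix: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)


def _make_aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align(
    a: str,
    b: str,
    mode: str = "global",
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Align two sequences and report score plus identity fraction."""
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    a = a.upper()
    b = b.upper()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend)
    if mode == "local" and aligner.score(a, b) <= 0:
        # no positive-scoring cell: empty alignment by convention
        return AlignmentResult(mode, 0.0, "", "", 0.0, matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    score = float(alignment.score)
    # local alignments from PairwiseAligner span only the aligned region,
    # so columns count directly toward the identity denominator
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    length = len(ga)
    identity = matches / length if length else 0.0
    return AlignmentResult(mode, score, ga, gb, identity, matrix, gap_open, gap_extend)


def percent_identity(result: AlignmentResult) -> float:
    """Identity as a percentage in [0, 100]."""
    return 100.0 * result.identity_fraction


def identity(a: str, b: str, mode: str = "global", **kwargs) -> float:
    """Convenience: identity fraction of the best alignment of a and b."""
    return align(a, b, mode=mode, **kwargs).identity_fraction


def query_by_identity(
    db: PeptideSet,
    queries: PeptideSet,
    threshold_pct: float,
    mode: str = "global",
    **kwargs,
) -> PeptideSet:
    """Database members whose identity to ANY query is >= the threshold.

    Original database order is preserved; the multi-query result is the
    union of the single-query results.
    """
    if not 0.0 < threshold_pct <= 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    hits = []
    for p in db:
        for q in queries:
            r = align(p.sequence, q.sequence, mode=mode, **kwargs)
            if percent_identity(r) >= threshold_pct:
                hits.append(p)
                break
    logger.info("query_by_identity: %d/%d hits at >= %.1f%%",
                len(hits), len(db), threshold_pct)
    return PeptideSet(hits, source=f"query>={threshold_pct}%")


def nonredundant_set(
    peptides: PeptideSet,
    threshold_pct: float,
    mode: str = "global",
    **kwargs,
) -> PeptideSet:
    """Greedy redundancy removal at an identity threshold.

    Peptides are visited longest-first (ties by id, the CD-HIT
    convention); one is accepted iff its identity to every
    already-accepted peptide is strictly below the threshold.  Output is
    in acceptance order.
    """
    if not 0.0 < threshold_pct < 100.0:
        raise ValueError("threshold must lie in (0, 100)")
    order = sorted(peptides, key=lambda p: (-len(p.sequence), p.id))
    accepted = []
    for p in order:
        redundant = False
        for q in accepted:
            r = align(p.sequence, q.sequence, mode=mode, **kwargs)
            if percent_identity(r) >= threshold_pct:
                redundant = True
                break
        if not redundant:
            accepted.append(p)
    logger.info("nonredundant_set: kept %d/%d at < %.1f%%",
                len(accepted), len(peptides), threshold_pct)
    return PeptideSet(accepted, source=f"nonredundant<{threshold_pct}%")
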