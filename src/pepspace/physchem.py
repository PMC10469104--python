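"""Per-peptide physicochemical quantities and boolean attribute filters.

The charge model is the two-sided Henderson–Hasselbalch sum over ionizable
groups (N-/C-terminus plus K, R, H, D, E, C, Y side chains) with the
Lehninger pKa set; the isoelectric point is its unique root in pH, found by
bisection.  Filters are boolean expressions over peptide attributes
(``length``, ``sequence``, ``net_charge``, ``pI``, ``mw``,
``hydrophobicity_mean``, ``id``) with AND/OR/NOT, comparison operators and
a CONTAINS substring test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import scales
from .core import Peptide

# ---------------------------------------------------------------------------
# Charge / pI / profiles


def net_charge(sequence: str, pH: float = 7.0) -> float:
    """Net charge (elementary charges) of a peptide at a given pH.

    Positive groups (free N-terminus and K/R/H side chains) contribute
    ``10^pKa / (10^pKa + 10^pH)``; negative groups (free C-terminus and
    D/E/C/Y side chains) contribute ``-10^pH / (10^pKa + 10^pH)``.
    ``X`` residues carry no ionizable side chain.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    seq = _validated(sequence)

    def positive(pka: float) -> float:
        return 10 ** pka / (10 ** pka + 10 ** pH)

    def negative(pka: float) -> float:
        return -(10 ** pH) / (10 ** pka + 10 ** pH)

    charge = positive(scales.PKA_NTERM) + negative(scales.PKA_CTERM)
    for residue in seq:
        if residue in scales.PKA_SIDECHAIN_POSITIVE:
            charge += positive(scales.PKA_SIDECHAIN_POSITIVE[residue])
        elif residue in scales.PKA_SIDECHAIN_NEGATIVE:
            charge += negative(scales.PKA_SIDECHAIN_NEGATIVE[residue])
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which :func:`net_charge` is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    # charge(0) > 0 > charge(14) for every sequence under this pKa set
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def property_profile(sequence: str, scale: str | dict[str, float]) -> np.ndarray:
    """Per-residue property vector; element i is the scale value of residue i.

    ``scale`` may be an embedded scale name or a residue->value mapping.
    ``X`` maps to the mean of the 20 canonical values.
    """
    table = scales.get_scale(scale) if isinstance(scale, str) else scale
    seq = _validated(sequence)
    if "X" not in table:
        table = dict(table)
        table["X"] = float(np.mean([table[r] for r in scales.CANONICAL_RESIDUES]))
    return np.array([table[r] for r in seq], dtype=float)


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    return float(property_profile(sequence, "residue_mass").sum()) + scales.WATER_MASS


def hydrophobicity_mean(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy over the sequence."""
    return float(property_profile(sequence, "kyte_doolittle").mean())


def _validated(sequence: str) -> str:
    seq = sequence.upper()
    Peptide(id="_", sequence=seq)  # reuse the invariant check
    return seq


# ---------------------------------------------------------------------------
# Filter expressions
#
# Grammar (precedence: NOT > AND > OR; parentheses supported):
#   expr    := term (OR term)*
#   term    := factor (AND factor)*
#   factor  := NOT factor | '(' expr ')' | comparison
#   comparison := attribute op value
#   op      := < | <= | > | >= | == | CONTAINS

FILTER_ATTRIBUTES = {
    "length": lambda p: float(len(p.sequence)),
    "net_charge": lambda p: net_charge(p.sequence, 7.0),
    "pI": lambda p: isoelectric_point(p.sequence),
    "mw": lambda p: molecular_weight(p.sequence),
    "hydrophobicity_mean": lambda p: hydrophobicity_mean(p.sequence),
    "sequence": lambda p: p.sequence,
    "id": lambda p: p.id,
}


class FilterError(ValueError):
    """Malformed filter expression or unknown attribute."""


@dataclass(frozen=True)
class Comparison:
    attribute: str
    op: str
    value: str

    def evaluate(self, peptide: Peptide) -> bool:
        if self.attribute not in FILTER_ATTRIBUTES:
            raise FilterError(
                f"unknown attribute {self.attribute!r}; known: "
                f"{sorted(FILTER_ATTRIBUTES)}"
            )
        actual = FILTER_ATTRIBUTES[self.attribute](peptide)
        if self.op == "CONTAINS":
            return str(self.value).upper() in str(actual).upper()
        if isinstance(actual, str):
            if self.op == "==":
                return actual == str(self.value).upper()
            raise FilterError(
                f"operator {self.op} not supported on string attribute "
                f"{self.attribute}"
            )
        try:
            target = float(self.value)
        except ValueError:
            raise FilterError(
                f"numeric attribute {self.attribute} compared to "
                f"non-numeric value {self.value!r}"
            ) from None
        return {
            "<": actual < target,
            "<=": actual <= target,
            ">": actual > target,
            ">=": actual >= target,
            "==": actual == target,
        }[self.op]


@dataclass(frozen=True)
class Not:
    operand: "FilterExpr"

    def evaluate(self, peptide: Peptide) -> bool:
        return not self.operand.evaluate(peptide)


@dataclass(frozen=True)
class And:
    left: "FilterExpr"
    right: "FilterExpr"

    def evaluate(self, peptide: Peptide) -> bool:
        return self.left.evaluate(peptide) and self.right.evaluate(peptide)


@dataclass(frozen=True)
class Or:
    left: "FilterExpr"
    right: "FilterExpr"

    def evaluate(self, peptide: Peptide) -> bool:
        return self.left.evaluate(peptide) or self.right.evaluate(peptide)


FilterExpr = Comparison | Not | And | Or

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<op><=|>=|==|<|>)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_.]*)|(?P<number>-?\d+(?:\.\d+)?))"
)


def parse_filter(text: str) -> FilterExpr:
    """Parse a filter expression string into an evaluable AST."""
    tokens = _tokenize(text)
    expr, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise FilterError(f"unexpected token {tokens[pos]!r} in filter")
    return expr


def evaluate_filter(peptide: Peptide, expr: FilterExpr | str) -> bool:
    """Evaluate a filter expression (AST or string) against one peptide."""
    if isinstance(expr, str):
        expr = parse_filter(expr)
    return expr.evaluate(peptide)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip():
                raise FilterError(f"cannot tokenize filter at: {text[pos:]!r}")
            break
        tokens.append(m.group(m.lastgroup))
        pos = m.end()
    if not tokens:
        raise FilterError("empty filter expression")
    return tokens


def _parse_or(tokens: list[str], pos: int) -> tuple[FilterExpr, int]:
    left, pos = _parse_and(tokens, pos)
    while pos < len(tokens) and tokens[pos].upper() == "OR":
        right, pos = _parse_and(tokens, pos + 1)
        left = Or(left, right)
    return left, pos


def _parse_and(tokens: list[str], pos: int) -> tuple[FilterExpr, int]:
    left, pos = _parse_factor(tokens, pos)
    while pos < len(tokens) and tokens[pos].upper() == "AND":
        right, pos = _parse_factor(tokens, pos + 1)
        left = And(left, right)
    return left, pos


def _parse_factor(tokens: list[str], pos: int) -> tuple[FilterExpr, int]:
    if pos >= len(tokens):
        raise FilterError("filter expression ended unexpectedly")
    tok = tokens[pos]
    if tok.upper() == "NOT":
        operand, pos = _parse_factor(tokens, pos + 1)
        return Not(operand), pos
    if tok == "(":
        expr, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise FilterError("unbalanced parenthesis in filter")
        return expr, pos + 1
    return _parse_comparison(tokens, pos)


def _parse_comparison(tokens: list[str], pos: int) -> tuple[Comparison, int]:
    attribute = tokens[pos]
    try:
        op = tokens[pos + 1]
        value = tokens[pos + 2]
    except IndexError:
        raise FilterError("incomplete comparison in filter") from None
    if op.upper() == "CONTAINS":
        op = "CONTAINS"
    elif op not in {"<", "<=", ">", ">=", "=="}:
        raise FilterError(f"unknown comparison operator {op!r}")
    return Comparison(attribute, op, value), pos + 3


def filter_peptides(peptides: Sequence[Peptide], expr: FilterExpr | str) -> list[Peptide]:
    """Return the peptides matching the filter, order preserved."""
    if isinstance(expr, str):
        expr = parse_filter(expr)
    return [p for p in peptides if expr.evaluate(p)]
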