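"""Sequence descriptors by aggregation of physicochemical profiles.

Each peptide is mapped to a per-residue property profile for every enabled
scale, and each profile is collapsed to a scalar by three families of
aggregation operators:

* statistical  — central tendency and dispersion (min, max, mean, median,
  variance, quartiles, skewness, kurtosis, ...);
* fuzzy        — the discrete Choquet integral with respect to a Sugeno
  lambda-measure, which generalizes weighted means to non-additive
  (interacting) importance;
* non-fuzzy    — GOWAWA, a generalized ordered-weighted-average/weighted-
  average hybrid mixing position-sorted (OWA) weights with per-position
  importance weights under a generalized-mean exponent.

With the default 9 scales and 14 operators a peptide set becomes an
n x 126 descriptor matrix.  Profiles are min-max scaled per scale across
the dataset before the fuzzy/non-fuzzy operators (both require
non-negative, comparable inputs); statistical operators see raw profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import Peptide, PeptideSet
from .physchem import property_profile
from .scales import PROPERTY_SCALES

# ---------------------------------------------------------------------------
# Statistical operators


def _skewness(x: np.ndarray) -> float:
    s = x.std()  # population
    if s == 0:
        return 0.0
    return float(np.mean(((x - x.mean()) / s) ** 3))


def _kurtosis(x: np.ndarray) -> float:
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean(((x - x.mean()) / s) ** 4))


STATISTICAL_OPERATORS: dict[str, Callable[[np.ndarray], float]] = {
    "min": lambda x: float(x.min()),
    "max": lambda x: float(x.max()),
    "range": lambda x: float(x.max() - x.min()),
    "sum": lambda x: float(x.sum()),
    "mean": lambda x: float(x.mean()),
    "median": lambda x: float(np.median(x)),
    "variance": lambda x: float(x.var()),  # population (divide by n)
    "std": lambda x: float(x.std()),
    "skewness": _skewness,
    "kurtosis": _kurtosis,
    "q1": lambda x: float(np.quantile(x, 0.25)),
    "q3": lambda x: float(np.quantile(x, 0.75)),
}

DEFAULT_OPERATORS = tuple(STATISTICAL_OPERATORS) + ("choquet", "gowawa")


def aggregate_statistical(profile: Sequence[float], operator: str) -> float:
    """Apply one named statistical operator to a non-empty profile.

    Variance is the population variance; skewness/kurtosis are
    standardized central moments with 0 returned for constant profiles;
    quartiles use linear interpolation.
    """
    x = np.asarray(profile, dtype=float)
    if x.size == 0:
        raise ValueError("profile must be non-empty")
    if operator not in STATISTICAL_OPERATORS:
        raise ValueError(
            f"unknown operator {operator!r}; known: "
            f"{sorted(STATISTICAL_OPERATORS)}"
        )
    return STATISTICAL_OPERATORS[operator](x)


# ---------------------------------------------------------------------------
# Choquet integral with a Sugeno lambda-measure


@dataclass
class FuzzyMeasure:
    """Sugeno lambda-measure defined by per-position densities g_i >= 0.

    The interaction parameter ``lambda_`` solves
    ``prod(1 + lambda * g_i) = 1 + lambda`` (with ``lambda = 0`` exactly
    when the densities sum to 1, i.e. the additive case).  The induced set
    function is ``mu(A) = (prod_{i in A}(1 + lambda g_i) - 1) / lambda``
    for ``lambda != 0`` and ``mu(A) = sum_{i in A} g_i`` otherwise.
    """

    densities: np.ndarray
    lambda_: float = field(init=False)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.ndim != 1 or self.densities.size == 0:
            raise ValueError("densities must be a non-empty 1-D vector")
        if (self.densities < 0).any():
            raise ValueError("densities must be non-negative")
        self.lambda_ = _solve_sugeno_lambda(self.densities)

    @classmethod
    def uniform(cls, n: int, total: float = 0.9) -> "FuzzyMeasure":
        """Uniform densities g_i = total/n (default total 0.9 gives a
        genuinely non-additive measure with positive interaction)."""
        return cls(np.full(n, total / n))

    def measure(self, subset: np.ndarray) -> float:
        """mu of a boolean-masked subset of positions."""
        g = self.densities[subset]
        if g.size == 0:
            return 0.0
        if abs(self.lambda_) < 1e-12:
            return float(g.sum())
        return float((np.prod(1.0 + self.lambda_ * g) - 1.0) / self.lambda_)


def _solve_sugeno_lambda(g: np.ndarray) -> float:
    """Root of f(l) = prod(1 + l*g_i) - (1 + l) on (-1, inf), excluding 0.

    sum(g) == 1 -> 0 (additive); sum(g) < 1 -> positive root;
    sum(g) > 1 -> root in (-1, 0).  Solved by bisection.
    """
    total = g.sum()
    if abs(total - 1.0) < 1e-12:
        return 0.0
    if total <= 0:
        raise ValueError("at least one density must be positive")

    def f(lam: float) -> float:
        return float(np.prod(1.0 + lam * g) - (1.0 + lam))

    if total < 1.0:
        lo, hi = 1e-12, 1.0
        while f(hi) < 0 and hi < 1e6:
            hi *= 2.0
    else:
        lo, hi = -1.0 + 1e-12, -1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) * f(lo) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def choquet_integral(profile: Sequence[float], measure: FuzzyMeasure) -> float:
    """Discrete Choquet integral of a non-negative profile.

    ``C = sum_i (x_(i) - x_(i-1)) * mu(A_(i))`` with ``x`` sorted
    ascending, ``x_(0) = 0`` and ``A_(i)`` the set of positions whose
    value is >= ``x_(i)``.  Ties are broken by original position (stable
    sort) for determinism.
    """
    x = np.asarray(profile, dtype=float)
    if x.size != measure.densities.size:
        raise ValueError(
            f"profile length {x.size} != number of densities "
            f"{measure.densities.size}"
        )
    if (x < 0).any():
        raise ValueError("Choquet integral requires a non-negative profile")
    order = np.argsort(x, kind="stable")
    total = 0.0
    prev = 0.0
    n = x.size
    mask = np.ones(n, dtype=bool)
    for rank, pos in enumerate(order):
        xi = x[pos]
        total += (xi - prev) * measure.measure(mask)
        prev = xi
        mask[pos] = False
    return float(total)


# ---------------------------------------------------------------------------
# GOWAWA


@dataclass
class GowawaParams:
    """Parameters of the GOWAWA operator.

    ``lambda_g`` is the generalized-mean exponent (non-zero); ``beta`` in
    [0,1] mixes OWA weights ``v`` (applied by sorted position) with
    importance weights ``w`` (applied by original position).  Weight
    vectors may be given explicitly or as named generators: ``"uniform"``
    or ``"quantifier"`` (regular increasing quantifier Q(r) = r^2), which
    adapt automatically to each profile's length.
    """

    lambda_g: float = 1.0
    beta: float = 0.5
    v: str | Sequence[float] = "uniform"
    w: str | Sequence[float] = "uniform"

    def __post_init__(self) -> None:
        if self.lambda_g == 0:
            raise ValueError("lambda_g must be non-zero")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    def weights(self, which: str, n: int) -> np.ndarray:
        spec = self.v if which == "v" else self.w
        return _adapt_weights(spec, n)


def _adapt_weights(spec: str | Sequence[float], n: int) -> np.ndarray:
    if isinstance(spec, str):
        if spec == "uniform":
            return np.full(n, 1.0 / n)
        if spec == "quantifier":
            r = np.arange(1, n + 1) / n
            q = r ** 2
            return np.diff(np.concatenate([[0.0], q]))
        raise ValueError(f"unknown weight generator {spec!r}")
    w = np.asarray(spec, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.size < n:  # extend by repeating the last value
        w = np.concatenate([w, np.full(n - w.size, w[-1] if w.size else 1.0)])
    elif w.size > n:
        w = w[:n]
    s = w.sum()
    if s <= 0:
        raise ValueError("weight vector must have positive sum")
    return w / s


def gowawa(profile: Sequence[float], params: GowawaParams) -> float:
    """GOWAWA aggregation of a non-negative profile.

    ``((sum_j vhat_j * b_j^lambda_g))^(1/lambda_g)`` where ``b_j`` is the
    j-th largest value, ``vhat_j = beta*v_j + (1-beta)*w_{sigma(j)}`` and
    ``sigma(j)`` is the original position of ``b_j``.  Sorting is stable
    in the original position for determinism under ties.
    """
    x = np.asarray(profile, dtype=float)
    if x.size == 0:
        raise ValueError("profile must be non-empty")
    if (x < 0).any():
        raise ValueError("GOWAWA requires a non-negative profile")
    n = x.size
    v = params.weights("v", n)
    w = params.weights("w", n)
    # stable descending sort: sort ascending on (-x, position)
    sigma = np.argsort(-x, kind="stable")
    b = x[sigma]
    vhat = params.beta * v + (1.0 - params.beta) * w[sigma]
    lam = params.lambda_g
    if (b == 0).any() and lam < 0:
        raise ValueError("negative exponent undefined for zero profile values")
    inner = float(np.sum(vhat * b ** lam))
    if inner <= 0:
        return 0.0
    return float(inner ** (1.0 / lam))


# ---------------------------------------------------------------------------
# Descriptor matrix


@dataclass
class DescriptorMatrix:
    """n x m named descriptor matrix with optional min-max normalization.

    ``values`` is a pandas DataFrame indexed by peptide id, columns named
    ``<scale>_<operator>``.  When normalized, ``normalization`` stores the
    per-column (min, max) needed to invert the transform.
    """

    values: pd.DataFrame
    normalization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def normalized(self) -> "DescriptorMatrix":
        """Min-max scale every column into [0, 1], recording (min, max).

        Constant columns map to 0.  Already-normalized matrices are
        returned unchanged.
        """
        if self.normalization:
            return self
        stats: dict[str, tuple[float, float]] = {}
        out = self.values.copy()
        for col in out.columns:
            lo = float(out[col].min())
            hi = float(out[col].max())
            stats[col] = (lo, hi)
            out[col] = 0.0 if hi == lo else (out[col] - lo) / (hi - lo)
        return DescriptorMatrix(out, normalization=stats)

    def to_csv(self, path) -> None:
        """Export with peptide id as first column, '.' decimal separator."""
        self.values.to_csv(path, index_label="peptide_id", float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        return cls(pd.read_csv(path, index_col="peptide_id"))


class DescriptorCalculator:
    """Computes descriptor matrices and can re-project new sequences.

    The calculator is *fit* on a peptide set: it records, per scale, the
    min and max profile value over all residues of the dataset.  These
    stats scale profiles into [0, 1] before the Choquet and GOWAWA
    operators, and are reused (with clipping) when projecting external
    query sequences into the same space.
    """

    def __init__(
        self,
        scales: Iterable[str] | None = None,
        operators: Iterable[str] | None = None,
        choquet_density_total: float = 0.9,
        gowawa_params: GowawaParams | None = None,
    ):
        self.scales = list(scales) if scales is not None else list(PROPERTY_SCALES)
        self.operators = list(operators) if operators is not None else list(DEFAULT_OPERATORS)
        if not self.scales or not self.operators:
            raise ValueError("need at least one scale and one operator")
        for op in self.operators:
            if op not in STATISTICAL_OPERATORS and op not in ("choquet", "gowawa"):
                raise ValueError(f"unknown operator {op!r}")
        self.choquet_density_total = choquet_density_total
        self.gowawa_params = gowawa_params or GowawaParams()
        self.profile_stats: dict[str, tuple[float, float]] = {}

    # -- fitting -----------------------------------------------------------

    def fit(self, peptides: PeptideSet) -> "DescriptorCalculator":
        if len(peptides) == 0:
            raise ValueError("need at least one peptide")
        for scale in self.scales:
            vals = np.concatenate(
                [property_profile(p.sequence, scale) for p in peptides]
            )
            self.profile_stats[scale] = (float(vals.min()), float(vals.max()))
        return self

    def _scaled_profile(self, sequence: str, scale: str) -> np.ndarray:
        lo, hi = self.profile_stats[scale]
        prof = property_profile(sequence, scale)
        if hi == lo:
            return np.zeros_like(prof)
        return np.clip((prof - lo) / (hi - lo), 0.0, 1.0)

    # -- transformation ----------------------------------------------------

    def transform(self, peptides: PeptideSet | Sequence[Peptide]) -> DescriptorMatrix:
        if not self.profile_stats:
            raise RuntimeError("calculator must be fit before transform")
        ids = [p.id for p in peptides]
        columns = [f"{s}_{op}" for s in self.scales for op in self.operators]
        rows = np.empty((len(ids), len(columns)))
        for i, p in enumerate(peptides):
            rows[i] = self._descriptor_row(p.sequence)
        df = pd.DataFrame(rows, index=pd.Index(ids, name="peptide_id"),
                          columns=columns)
        return DescriptorMatrix(df)

    def _descriptor_row(self, sequence: str) -> np.ndarray:
        out: list[float] = []
        for scale in self.scales:
            raw = property_profile(sequence, scale)
            scaled: np.ndarray | None = None
            measure: FuzzyMeasure | None = None
            for op in self.operators:
                if op in STATISTICAL_OPERATORS:
                    out.append(STATISTICAL_OPERATORS[op](raw))
                    continue
                if scaled is None:
                    scaled = self._scaled_profile(sequence, scale)
                if op == "choquet":
                    if measure is None:
                        measure = FuzzyMeasure.uniform(
                            len(raw), self.choquet_density_total
                        )
                    out.append(choquet_integral(scaled, measure))
                else:  # gowawa
                    out.append(gowawa(scaled, self.gowawa_params))
        return np.asarray(out)

    def fit_transform(self, peptides: PeptideSet) -> DescriptorMatrix:
        return self.fit(peptides).transform(peptides)


def compute_descriptor_matrix(
    peptides: PeptideSet,
    scales: Iterable[str] | None = None,
    operators: Iterable[str] | None = None,
    **kwargs,
) -> DescriptorMatrix:
    """One-shot descriptor computation (fit + transform on one set)."""
    return DescriptorCalculator(scales, operators, **kwargs).fit_transform(peptides)


# ---------------------------------------------------------------------------
# PCA projection


def pca_project(matrix: DescriptorMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Project the descriptor matrix onto its first k principal components.

    Columns are standardized internally (zero mean, unit variance);
    constant columns are dropped with a warning.  Component signs follow
    the convention that each component's largest-magnitude loading is
    positive.

    Returns (scores n x k, explained_variance_ratios length k).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = matrix.as_array()
    std = X.std(axis=0)
    keep = std > 0
    if not keep.all():
        warnings.warn(
            f"pca_project: dropped {int((~keep).sum())} constant column(s)",
            stacklevel=2,
        )
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no non-constant columns to project")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n, m)={min(X.shape)}")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        comp = pca.components_[j]
        lead = np.argmax(np.abs(comp))
        if comp[lead] < 0:
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_
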