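"""The eight pairwise distances over descriptor rows, and their
conversion to similarities in [0, 1].

Naming follows the chemical-similarity literature: "Canberra",
"Wave-Hedges" (wave_edge), and the Matusita (metric) form of the
Bhattacharyya distance, ``sqrt(sum (sqrt(x)-sqrt(y))^2)``, which does not
require unit-sum vectors.  Terms of the form 0/0 in Canberra, Soergel and
Wave-Hedges contribute 0.  Soergel, Bhattacharyya and Wave-Hedges require
non-negative inputs (guaranteed by min-max-normalized descriptors).

Distances convert to similarities by either ``reciprocal``
(s = 1/(1+d), dataset-independent) or ``max_norm`` (s = 1 - d/d_max with
d_max the dataset maximum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import DescriptorMatrix

METRICS = (
    "euclidean", "manhattan", "chebyshev", "canberra",
    "soergel", "bhattacharyya", "angular", "wave_edge",
)
CONVERSIONS = ("reciprocal", "max_norm")
NONNEGATIVE_METRICS = {"soergel", "bhattacharyya", "wave_edge"}


def distance(x, y, metric: str) -> float:
    """One of the eight supported distances between equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; supported: {METRICS}")
    if metric in NONNEGATIVE_METRICS and ((x < 0).any() or (y < 0).any()):
        raise ValueError(f"{metric} distance requires non-negative inputs")
    return _DISPATCH[metric](x, y)


def _euclidean(x, y):
    return float(np.sqrt(((x - y) ** 2).sum()))


def _manhattan(x, y):
    return float(np.abs(x - y).sum())


def _chebyshev(x, y):
    return float(np.abs(x - y).max())


def _canberra(x, y):
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den != 0)
    return float(terms.sum())


def _soergel(x, y):
    den = np.maximum(x, y).sum()
    if den == 0:
        return 0.0
    return float(np.abs(x - y).sum() / den)


def _bhattacharyya(x, y):
    return float(np.sqrt(((np.sqrt(x) - np.sqrt(y)) ** 2).sum()))


def _angular(x, y):
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0 if (nx == 0 and ny == 0) else 1.0
    cos = float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))
    return 1.0 - cos


def _wave_edge(x, y):
    lo = np.minimum(x, y)
    hi = np.maximum(x, y)
    terms = 1.0 - np.divide(lo, hi, out=np.ones_like(lo), where=hi != 0)
    return float(terms.sum())


_DISPATCH = {
    "euclidean": _euclidean,
    "manhattan": _manhattan,
    "chebyshev": _chebyshev,
    "canberra": _canberra,
    "soergel": _soergel,
    "bhattacharyya": _bhattacharyya,
    "angular": _angular,
    "wave_edge": _wave_edge,
}


def to_similarity(d: float, conversion: str = "reciprocal", d_max: float | None = None) -> float:
    """Map a distance to [0, 1]; strictly decreasing in d.

    ``reciprocal``: s = 1/(1+d).  ``max_norm``: s = 1 - d/d_max, with
    s = 1 when d_max = 0; requires d_max >= d.
    """
    if conversion == "reciprocal":
        return 1.0 / (1.0 + d)
    if conversion == "max_norm":
        if d_max is None:
            raise ValueError("max_norm conversion requires d_max")
        if d_max == 0:
            return 1.0
        if d > d_max * (1 + 1e-12):
            raise ValueError(f"d={d} exceeds d_max={d_max}")
        return 1.0 - d / d_max
    raise ValueError(f"unknown conversion {conversion!r}; supported: {CONVERSIONS}")


@dataclass(frozen=True)
class MetricSpec:
    """A distance metric paired with a distance-to-similarity conversion."""

    name: str = "euclidean"
    conversion: str = "reciprocal"

    def __post_init__(self) -> None:
        if self.name not in METRICS:
            raise ValueError(f"unknown metric {self.name!r}; supported: {METRICS}")
        if self.conversion not in CONVERSIONS:
            raise ValueError(
                f"unknown conversion {self.conversion!r}; supported: {CONVERSIONS}"
            )


@dataclass
class SimilarityMatrix:
    """Symmetric n x n similarity values in [0, 1] with unit diagonal."""

    ids: list[str]
    S: np.ndarray
    metric: str
    conversion: str
    d_max: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")

    def similarity(self, id_a: str, id_b: str) -> float:
        i = self.ids.index(id_a)
        j = self.ids.index(id_b)
        return float(self.S[i, j])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.S, index=self.ids, columns=self.ids).to_csv(
            path, index_label="peptide_id", float_format="%.10g"
        )


def pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    """Full symmetric distance matrix over the rows of X."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = distance(X[i], X[j], metric)
            D[i, j] = D[j, i] = d
    return D


def pairwise_similarity(matrix: DescriptorMatrix, spec: MetricSpec) -> SimilarityMatrix:
    """Similarity matrix over descriptor rows under one metric spec.

    A matrix containing negative values is min-max-normalized first when
    the metric requires non-negative inputs; ``max_norm`` conversion uses
    the off-diagonal maximum distance of the dataset.
    """
    if len(matrix.ids) < 2:
        raise ValueError("need at least two rows")
    if spec.name in NONNEGATIVE_METRICS and (matrix.as_array() < 0).any():
        matrix = matrix.normalized()
    X = matrix.as_array()
    D = pairwise_distances(X, spec.name)
    n = D.shape[0]
    off = D[~np.eye(n, dtype=bool)]
    d_max = float(off.max()) if off.size else 0.0
    S = np.ones_like(D)
    for i in range(n):
        for j in range(i + 1, n):
            s = to_similarity(D[i, j], spec.conversion, d_max)
            S[i, j] = S[j, i] = s
    return SimilarityMatrix(
        ids=matrix.ids, S=S, metric=spec.name,
        conversion=spec.conversion, d_max=d_max,
    )
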