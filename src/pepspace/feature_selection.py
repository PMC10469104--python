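"""Two-stage unsupervised feature selection for descriptor matrices.

Stage 1 removes low-information columns by Shannon entropy of an
equal-width histogram; stage 2 removes redundant columns greedily by
normalized mutual information (NMI), visiting columns in descending
entropy order so the most informative representative of each redundant
group survives.  Both stages share one binning; NMI uses the
``MI / min(H_x, H_y)`` normalization, which reaches exactly 1 for
deterministic dependence under shared bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorMatrix

DEFAULT_BINS = 10
DEFAULT_ENTROPY_CUTOFF = 0.3
DEFAULT_NMI_CUTOFF = 0.7


@dataclass
class SelectionReport:
    """Audit trail of a selection run: every column's fate is recorded."""

    kept: list[str] = field(default_factory=list)
    dropped_stage1: list[tuple[str, float]] = field(default_factory=list)
    dropped_stage2: list[tuple[str, str, float]] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tfate\tdetail\n")
            for name in self.kept:
                fh.write(f"{name}\tkept\t\n")
            for name, h in self.dropped_stage1:
                fh.write(f"{name}\tdropped_entropy\tH={h:.6f}\n")
            for name, partner, nmi in self.dropped_stage2:
                fh.write(f"{name}\tdropped_redundant\tpartner={partner};NMI={nmi:.6f}\n")


def _bin_edges(column: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(column.min()), float(column.max())
    if hi == lo:
        hi = lo + 1.0  # single occupied bin; entropy 0 either way
    return np.linspace(lo, hi, bins + 1)


def shannon_entropy(column, bins: int = DEFAULT_BINS) -> float:
    """Shannon entropy in bits of an equal-width histogram over [min, max].

    A constant column has zero entropy.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("column must be non-empty")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, _ = np.histogram(x, bins=_bin_edges(x, bins))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def mutual_information(x, y, bins: int = DEFAULT_BINS) -> float:
    """MI in bits from the joint 2-D equal-width histogram."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    joint, _, _ = np.histogram2d(x, y, bins=[_bin_edges(x, bins), _bin_edges(y, bins)])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float((pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum())


def normalized_mutual_information(x, y, bins: int = DEFAULT_BINS) -> float:
    """NMI(x, y) = MI / min(H(x), H(y)); 0 when either entropy is 0."""
    hx = shannon_entropy(x, bins)
    hy = shannon_entropy(y, bins)
    denom = min(hx, hy)
    if denom <= 0:
        return 0.0
    return mutual_information(x, y, bins) / denom


def entropy_filter(
    matrix: DescriptorMatrix,
    rel_cutoff: float = DEFAULT_ENTROPY_CUTOFF,
    bins: int = DEFAULT_BINS,
) -> SelectionReport:
    """Stage 1: drop columns with H < rel_cutoff * log2(bins)."""
    if not 0.0 <= rel_cutoff <= 1.0:
        raise ValueError("rel_cutoff must lie in [0, 1]")
    report = SelectionReport(
        parameters={"bins": bins, "rel_cutoff": rel_cutoff}
    )
    threshold = rel_cutoff * np.log2(bins)
    for col in matrix.columns:
        h = shannon_entropy(matrix.values[col].to_numpy(), bins)
        if h < threshold:
            report.dropped_stage1.append((col, h))
        else:
            report.kept.append(col)
    return report


def mi_redundancy_filter(
    matrix: DescriptorMatrix,
    nmi_cutoff: float = DEFAULT_NMI_CUTOFF,
    bins: int = DEFAULT_BINS,
) -> SelectionReport:
    """Stage 2: greedy NMI redundancy removal.

    Columns are visited by entropy descending (ties by name); a column is
    kept iff its NMI to every already-kept column is below the cutoff.
    """
    if not 0.0 <= nmi_cutoff <= 1.0:
        raise ValueError("nmi_cutoff must lie in [0, 1]")
    report = SelectionReport(
        parameters={"bins": bins, "nmi_cutoff": nmi_cutoff}
    )
    data = {c: matrix.values[c].to_numpy() for c in matrix.columns}
    entropies = {c: shannon_entropy(v, bins) for c, v in data.items()}
    order = sorted(matrix.columns, key=lambda c: (-entropies[c], c))
    for col in order:
        redundant_with = None
        worst = 0.0
        for kept in report.kept:
            nmi = normalized_mutual_information(data[col], data[kept], bins)
            if nmi >= nmi_cutoff:
                redundant_with, worst = kept, nmi
                break
        if redundant_with is None:
            report.kept.append(col)
        else:
            report.dropped_stage2.append((col, redundant_with, worst))
    return report


def select_features(
    matrix: DescriptorMatrix,
    rel_cutoff: float = DEFAULT_ENTROPY_CUTOFF,
    nmi_cutoff: float = DEFAULT_NMI_CUTOFF,
    bins: int = DEFAULT_BINS,
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Run both stages; returns the reduced matrix and a full report.

    The report's kept/dropped sets partition the original columns, and the
    kept columns appear in their original matrix order.
    """
    stage1 = entropy_filter(matrix, rel_cutoff, bins)
    surviving = DescriptorMatrix(
        matrix.values[stage1.kept], normalization=dict(matrix.normalization)
    )
    stage2 = mi_redundancy_filter(surviving, nmi_cutoff, bins)
    kept_in_order = [c for c in matrix.columns if c in set(stage2.kept)]
    report = SelectionReport(
        kept=kept_in_order,
        dropped_stage1=stage1.dropped_stage1,
        dropped_stage2=stage2.dropped_stage2,
        parameters={
            "bins": bins,
            "rel_cutoff": rel_cutoff,
            "nmi_cutoff": nmi_cutoff,
        },
    )
    reduced = DescriptorMatrix(
        matrix.values[kept_in_order], normalization=dict(matrix.normalization)
    )
    return reduced, report
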