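"""Multi-query similarity-searching models (mQSSMs).

An mQSSM is an untrained one-class classifier: a set of query peptides
(typically the scaffold of a chemical-space network — community
representatives plus singletons), a similarity definition, a group-fusion
rule and a decision threshold.  A target peptide is scored by computing
its similarity to every query and fusing the values (MAX, MEAN or MIN);
it is predicted positive iff the fused score reaches the threshold.  No
negative training set is ever consulted — the model is built from the
positive class alone.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .core import Peptide, PeptideSet
from .descriptors import DescriptorCalculator
from .simmetrics import MetricSpec, distance, to_similarity
from . import alignment as _align
from . import io as _io

logger = logging.getLogger(__name__)

FUSION_RULES = ("MAX", "MEAN", "MIN")
SIMILARITY_KINDS = ("local_identity", "global_identity", "descriptor")


@dataclass
class MQSSModel:
    """Query set + similarity configuration + fusion rule + threshold."""

    queries: PeptideSet
    similarity_kind: str = "local_identity"
    fusion: str = "MAX"
    threshold: float = 0.5
    metric_spec: MetricSpec = field(default_factory=MetricSpec)
    calculator: DescriptorCalculator | None = None

    def __post_init__(self) -> None:
        if len(self.queries) == 0:
            raise ValueError("model needs at least one query")
        if self.similarity_kind not in SIMILARITY_KINDS:
            raise ValueError(
                f"unknown similarity kind {self.similarity_kind!r}; "
                f"supported: {SIMILARITY_KINDS}"
            )
        if self.fusion not in FUSION_RULES:
            raise ValueError(f"unknown fusion {self.fusion!r}; supported: {FUSION_RULES}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")


@dataclass
class ScreeningResult:
    target_id: str
    fused_score: float
    best_query: str
    predicted: str  # "positive" | "negative"


def build_model(
    queries: PeptideSet,
    similarity_kind: str = "local_identity",
    fusion: str = "MAX",
    threshold: float = 0.5,
    metric_spec: MetricSpec | None = None,
    reference: PeptideSet | None = None,
) -> MQSSModel:
    """Build an mQSSM from a query set.

    Duplicate query sequences are collapsed with a warning.  For the
    ``descriptor`` similarity kind a calculator is fitted on
    ``reference`` (or the queries themselves) to define the descriptor
    space.
    """
    seen: dict[str, str] = {}
    unique = []
    for q in queries:
        if q.sequence in seen:
            warnings.warn(
                f"duplicate query sequence: {q.id} collapsed into {seen[q.sequence]}",
                stacklevel=2,
            )
            continue
        seen[q.sequence] = q.id
        unique.append(q)
    model = MQSSModel(
        queries=PeptideSet(unique, source=queries.source),
        similarity_kind=similarity_kind,
        fusion=fusion,
        threshold=threshold,
        metric_spec=metric_spec or MetricSpec(),
    )
    if similarity_kind == "descriptor":
        calc = DescriptorCalculator()
        calc.fit(reference if reference is not None else model.queries)
        model.calculator = calc
    return model


def _local_identity_similarity(a: str, b: str) -> float:
    """Coverage-corrected local identity: Smith-Waterman matches divided
    by the shorter sequence length.

    Normalizing by the aligned columns alone would let a one-residue
    perfect segment between unrelated peptides score 1.0; dividing by
    the shorter sequence rewards alignments that cover a sequence, which
    is what similarity screening needs.
    """
    r = _align.align(a, b, mode="local")
    matches = sum(
        1 for x, y in zip(r.aligned_a, r.aligned_b) if x == y and x != "-"
    )
    return matches / min(len(a), len(b))


def _query_similarities(model: MQSSModel, target: Peptide) -> list[tuple[str, float]]:
    if model.similarity_kind == "local_identity":
        return [
            (q.id, _local_identity_similarity(target.sequence, q.sequence))
            for q in model.queries
        ]
    if model.similarity_kind == "global_identity":
        return [
            (q.id, _align.identity(target.sequence, q.sequence, mode="global"))
            for q in model.queries
        ]
    # descriptor similarity
    assert model.calculator is not None
    rows = model.calculator.transform([target] + list(model.queries))
    rows = rows.normalized()
    X = rows.as_array()
    out = []
    for i, q in enumerate(model.queries, start=1):
        d = distance(X[0], X[i], model.metric_spec.name)
        out.append((q.id, to_similarity(d, "reciprocal")))
    return out


def score_target(model: MQSSModel, target: Peptide | str) -> float:
    """Fused similarity of one target to the model's query set, in [0,1]."""
    return _score_detail(model, target)[0]


def _score_detail(model: MQSSModel, target: Peptide | str) -> tuple[float, str]:
    if isinstance(target, str):
        target = Peptide(id="target", sequence=target)
    sims = _query_similarities(model, target)
    values = [s for _, s in sims]
    if model.fusion == "MAX":
        fused = max(values)
    elif model.fusion == "MIN":
        fused = min(values)
    else:
        fused = sum(values) / len(values)
    best = max(sims, key=lambda t: (t[1], t[0]))[0]
    return fused, best


def screen(model: MQSSModel, targets: PeptideSet) -> list[ScreeningResult]:
    """Score every target; positive iff fused score >= the threshold."""
    results = []
    for t in targets:
        fused, best = _score_detail(model, t)
        results.append(ScreeningResult(
            target_id=t.id,
            fused_score=fused,
            best_query=best,
            predicted="positive" if fused >= model.threshold else "negative",
        ))
    logger.info("screen: %d targets, %d positive",
                len(results), sum(r.predicted == "positive" for r in results))
    return results


def evaluate(
    results: list[ScreeningResult], labels: dict[str, str]
) -> dict[str, float]:
    """Confusion-matrix summary of a screening run against known labels.

    Returns TP/FP/TN/FN counts plus sensitivity, specificity, accuracy,
    precision, F1 and MCC (each 0 when its denominator is 0).
    """
    tp = fp = tn = fn = 0
    for r in results:
        if r.target_id not in labels:
            raise ValueError(f"missing label for target {r.target_id!r}")
        truth = labels[r.target_id]
        if r.predicted == "positive":
            tp += truth == "positive"
            fp += truth == "negative"
        else:
            fn += truth == "positive"
            tn += truth == "negative"

    def ratio(num, den):
        return num / den if den else 0.0

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "sensitivity": sensitivity,
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": precision,
        "F1": ratio(2 * precision * sensitivity, precision + sensitivity)
        if (precision + sensitivity) else 0.0,
        "MCC": (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0,
    }


# ---------------------------------------------------------------------------
# Persistence: plain FASTA + key-value sidecar (no binary formats)


def save_model(model: MQSSModel, prefix: str | Path) -> tuple[Path, Path]:
    """Write <prefix>.fasta (queries) and <prefix>.cfg (configuration)."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fasta")
    cfg = prefix.with_suffix(".cfg")
    _io.write_fasta(model.queries, fasta)
    with open(cfg, "w") as fh:
        fh.write(f"similarity_kind = {model.similarity_kind}\n")
        fh.write(f"fusion = {model.fusion}\n")
        fh.write(f"threshold = {model.threshold}\n")
        fh.write(f"metric = {model.metric_spec.name}\n")
        fh.write(f"conversion = {model.metric_spec.conversion}\n")
    return fasta, cfg


def load_model(prefix: str | Path) -> MQSSModel:
    """Re-create a model saved by :func:`save_model`."""
    prefix = Path(prefix)
    queries = _io.read_fasta(prefix.with_suffix(".fasta"))
    kv: dict[str, str] = {}
    with open(prefix.with_suffix(".cfg")) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    return build_model(
        queries,
        similarity_kind=kv.get("similarity_kind", "local_identity"),
        fusion=kv.get("fusion", "MAX"),
        threshold=float(kv.get("threshold", 0.5)),
        metric_spec=MetricSpec(kv.get("metric", "euclidean"),
                               kv.get("conversion", "reciprocal")),
    )
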