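"""Reading and writing the external formats: FASTA, annotation TSV,
descriptor CSV, similarity CSV, GraphML and edge-list CSV.

FASTA parsing goes through Bio.SeqIO; record ids are the first
whitespace-delimited header token, sequences are uppercased and a trailing
``*`` stop character is stripped with a warning.  Graph export preserves
node attributes (community labels, centralities) and edge weights so a
written network re-reads identically to 6 decimal places.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Peptide, PeptideSet

logger = logging.getLogger(__name__)

GRAPH_FORMATS = ("graphml", "edgelist_csv")


def read_fasta(path: str | Path) -> PeptideSet:
    """Read a (possibly multi-line) FASTA file into a :class:`PeptideSet`.

    Record order is preserved; duplicate ids, illegal residues and empty
    files are hard errors.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate id {record.id} in {path}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            warnings.warn(
                f"record {record.id}: stripped terminal stop character '*'",
                stacklevel=2,
            )
            seq = seq.rstrip("*")
        peptides.append(Peptide(id=record.id, sequence=seq))
    if not peptides:
        raise ValueError(f"no FASTA records found in {path}")
    logger.info("read_fasta: %d peptides from %s", len(peptides), path)
    return PeptideSet(peptides, source=str(path))


def write_fasta(peptides: PeptideSet, path: str | Path, width: int = 60) -> None:
    """Write peptides as FASTA, one record per peptide, wrapped lines."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    logger.info("write_fasta: %d peptides to %s", len(peptides), path)


def read_annotations(
    path: str | Path, known_ids: set[str] | None = None
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Read a TSV of (peptide_id, relation, term) triples.

    A header row is required.  Rows whose peptide_id is absent from
    ``known_ids`` (when given) are retained but reported in the returned
    warning list; joining to peptides happens later.

    Returns
    -------
    (triples, warnings)
    """
    path = Path(path)
    triples: list[tuple[str, str, str]] = []
    warned: list[str] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            next(reader)  # header
        except StopIteration:
            raise ValueError(f"annotation file {path} is empty (no header)") from None
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed row ({len(row)} fields, need 3)"
                )
            pid, relation, term = row[0], row[1], row[2]
            triples.append((pid, relation, term))
            if known_ids is not None and pid not in known_ids:
                warned.append(
                    f"{path}:{lineno}: peptide_id {pid!r} not in the peptide set"
                )
    logger.info("read_annotations: %d triples from %s (%d unmatched)",
                len(triples), path, len(warned))
    return triples, warned


def write_annotations(
    triples: list[tuple[str, str, str]], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["peptide_id", "relation", "term"])
        writer.writerows(triples)


def attach_annotations(
    peptides: PeptideSet, triples: list[tuple[str, str, str]]
) -> list[str]:
    """Join annotation triples onto peptides in place.

    Returns warnings for triples whose id is unknown (those are skipped).
    """
    warned = []
    for pid, relation, term in triples:
        if pid in peptides:
            peptides[pid].annotations.append((relation, term))
        else:
            warned.append(f"annotation for unknown peptide {pid!r} skipped")
    return warned


# ---------------------------------------------------------------------------
# Graph I/O


def write_graph(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a network as GraphML or as an edge-list CSV.

    GraphML carries all node attributes and the edge ``weight``; the CSV
    has a ``source,target,weight`` header and one row per edge.
    """
    if format not in GRAPH_FORMATS:
        raise ValueError(
            f"unknown graph format {format!r}; supported: {GRAPH_FORMATS}"
        )
    path = Path(path)
    if format == "graphml":
        out = nx.Graph()
        out.add_nodes_from(sorted(net.nodes(data=True)))
        out.add_edges_from(
            (u, v, d) for u, v, d in sorted(
                net.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
            )
        )
        out.graph.update({k: v for k, v in net.graph.items() if v is not None})
        nx.write_graphml(out, str(path))
    else:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(["source", "target", "weight"])
            for u, v, data in sorted(
                net.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
            ):
                writer.writerow([u, v, f"{data.get('weight', 1.0):.6f}"])
    logger.info("write_graph: %d nodes / %d edges to %s (%s)",
                net.number_of_nodes(), net.number_of_edges(), path, format)


def read_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_graph`."""
    if format not in GRAPH_FORMATS:
        raise ValueError(
            f"unknown graph format {format!r}; supported: {GRAPH_FORMATS}"
        )
    if format == "graphml":
        return nx.read_graphml(str(path))
    g = nx.Graph()
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader)
        if header[:3] != ["source", "target", "weight"]:
            raise ValueError(f"unexpected edge-list header {header!r} in {path}")
        for source, target, weight in reader:
            g.add_edge(source, target, weight=float(weight))
    return g
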