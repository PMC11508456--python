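"""Protein-protein interaction network construction and pruning.

Interaction records are read from PSI-MI TAB (MITAB) files — the
tab-separated exchange format of the HUPO Proteomics Standards Initiative,
15 columns minimum. Records are filtered to human (taxid 9606) protein-
protein pairs, then restricted to interactions whose *both* endpoints lie in
the candidate list: first interactors (partners outside the list), self-
loops and duplicate edges are discarded, and only connected proteins
(degree >= 1) are kept. Nodes are finally annotated with the univariate
log2 fold change, FDR and regulation direction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import AnnotationError, FormatError, InputError
from .merge import parse_proteoform

MIN_COLUMNS = 15
_UNIPROT_RE = re.compile(r"uniprotkb:([A-Za-z0-9\-]+)")
_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_PROTEIN_TYPE_RE = re.compile(r"MI:0326|\(protein\)")


@dataclass(frozen=True)
class InteractionRecord:
    """One MITAB line, reduced to the fields the pruning workflow uses."""

    id_a: str
    id_b: str
    raw_id_a: str
    raw_id_b: str
    taxid_a: int | None
    taxid_b: int | None
    type_a: str | None
    type_b: str | None
    is_uniprot_a: bool
    is_uniprot_b: bool
    source_line: int


def _parse_identifier(field: str) -> tuple[str, str, bool]:
    """Return (base accession, raw accession, is_uniprot) for an ID column.

    UniProt isoform suffixes are stripped to the base accession; lines with
    non-uniprotkb primary identifiers keep the raw field and are flagged.
    """
    m = _UNIPROT_RE.search(field)
    if m is None:
        return field, field, False
    raw = m.group(1)
    return parse_proteoform(raw).base, raw, True


def _parse_taxid(field: str) -> int | None:
    m = _TAXID_RE.search(field)
    return int(m.group(1)) if m else None


def read_mitab(path: str | Path) -> list[InteractionRecord]:
    """Parse a MITAB file (>= 15 tab-separated columns) into records.

    Interactor-type columns (21/22 of the extended dialect) are read when
    present; the plain 15-column dialect leaves them ``None``. Comment lines
    starting with ``#`` are skipped.
    """
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < MIN_COLUMNS:
                raise FormatError(
                    f"line {lineno}: expected >= {MIN_COLUMNS} columns, got {len(cols)}"
                )
            base_a, raw_a, uni_a = _parse_identifier(cols[0])
            base_b, raw_b, uni_b = _parse_identifier(cols[1])
            type_a = cols[20] if len(cols) > 21 else None
            type_b = cols[21] if len(cols) > 21 else None
            records.append(
                InteractionRecord(
                    id_a=base_a,
                    id_b=base_b,
                    raw_id_a=raw_a,
                    raw_id_b=raw_b,
                    taxid_a=_parse_taxid(cols[9]),
                    taxid_b=_parse_taxid(cols[10]),
                    type_a=type_a,
                    type_b=type_b,
                    is_uniprot_a=uni_a,
                    is_uniprot_b=uni_b,
                    source_line=lineno,
                )
            )
    return records


def _is_protein(type_field: str | None) -> bool:
    # a missing type column (15-column dialect) is assumed to denote protein
    if type_field is None or type_field == "-":
        return True
    return _PROTEIN_TYPE_RE.search(type_field) is not None


def filter_records(
    records: Iterable[InteractionRecord],
    taxid: int = 9606,
    protein_only: bool = True,
) -> list[InteractionRecord]:
    """Keep human (or other target-taxon) protein-protein records.

    Both interactors must carry the target taxid (removing homology-inferred
    cross-species rows) and, when ``protein_only``, an interactor type
    denoting protein. Order is preserved.
    """
    out = []
    for r in records:
        if r.taxid_a != taxid or r.taxid_b != taxid:
            continue
        if protein_only and not (_is_protein(r.type_a) and _is_protein(r.type_b)):
            continue
        out.append(r)
    return out


def prune_to_input(
    records: Iterable[InteractionRecord],
    input_set: Iterable[str],
) -> nx.Graph:
    """Induced simple graph over the candidate list.

    Edges are kept only when *both* endpoints belong to ``input_set`` (this
    removes first interactors); self-loops are dropped, unordered duplicate
    edges collapse, and proteins left without any interaction do not appear
    (only connected proteins are reported). An empty result is valid.
    """
    members = set(input_set)
    if not members:
        raise InputError("input_set must be non-empty")
    g = nx.Graph()
    for r in records:
        a, b = r.id_a, r.id_b
        if a == b:
            continue
        if a in members and b in members:
            g.add_edge(a, b)
    return g


def annotate_directions(graph: nx.Graph, stats: pd.DataFrame) -> dict:
    """Attach log2fc/fdr/direction node attributes from a statistics table.

    ``direction`` is ``"up"`` when log2fc > 0, else ``"down"``. Every node
    must appear in ``stats`` (indexed by accession). Returns the up/down
    counts.
    """
    for node in graph.nodes:
        if node not in stats.index:
            raise AnnotationError(f"no statistics for network node {node!r}")
        lfc = float(stats.loc[node, "log2fc"])
        graph.nodes[node]["log2fc"] = lfc
        graph.nodes[node]["fdr"] = float(stats.loc[node, "fdr"])
        graph.nodes[node]["direction"] = "up" if lfc > 0 else "down"
    n_up = sum(1 for n in graph.nodes if graph.nodes[n]["direction"] == "up")
    return {"n_up": n_up, "n_down": graph.number_of_nodes() - n_up}


# ---------------------------------------------------------------------------
# output and packaged reference panel
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Sorted two-column TSV (acc_a, acc_b) of the network's edges."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    with open(path, "w") as fh:
        fh.write("acc_a\tacc_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_node_table(graph: nx.Graph, path: str | Path) -> None:
    """Node TSV with accession, log2fc, fdr, direction, sorted by FDR."""
    rows = [
        {"accession": n, **{k: graph.nodes[n].get(k) for k in ("log2fc", "fdr", "direction")}}
        for n in graph.nodes
    ]
    df = pd.DataFrame(rows, columns=["accession", "log2fc", "fdr", "direction"])
    df = df.sort_values(["fdr", "accession"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_reference_panel() -> pd.DataFrame:
    """Packaged 48-protein OSCC saliva panel (accession, name, log2fc, fdr).

    The connected-protein panel from a salivary proteomics comparison of 10
    oral squamous cell carcinoma patients against 20 healthy controls:
    univariate log2 fold changes (case/control) and BH FDR of the proteins
    that remained physically connected after PPI pruning.
    """
    with resources.files("proteomark").joinpath("data/oscc_saliva_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="accession")
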