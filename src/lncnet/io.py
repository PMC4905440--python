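"""Readers and writers: TSV expression matrices, GMT gene sets, networks.

Expression matrices are tab-separated with a header row of sample ids and
probe ids in the first column; decimal point is ``.`` with no locale
handling. Networks are written as SIF or GraphML for import into Cytoscape.
"""

from __future__ import annotations

import os
from typing import Mapping

import networkx as nx
import pandas as pd

from .core import ExpressionMatrix, GeneSetCollection, ProbeAnnotation, ValidationError

SIF_COEXPRESSED = "coexpressed"
SIF_REGULATES = "regulates"


def read_group_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (sample id, group) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample id(s) in group map: {dups}")
    return dict(zip(df["sample_id"], df["group"]))


def read_expression_matrix(
    path: str | os.PathLike, group_map: str | os.PathLike | Mapping[str, str]
) -> ExpressionMatrix:
    """Load a probe x sample log2-intensity TSV and attach group labels.

    Duplicate ids, missing group labels and non-numeric or missing cells are
    hard errors naming the offending row/column; probe and sample order is
    preserved exactly as in the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if isinstance(group_map, (str, os.PathLike)):
        group_map = read_group_map(group_map)
    return ExpressionMatrix(values, dict(group_map))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path: str | os.PathLike) -> ProbeAnnotation:
    """Read a probe annotation TSV (probe_id, molecule_class, gene_symbol, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    return ProbeAnnotation(df)


def write_annotation(annotation: ProbeAnnotation, path: str | os.PathLike) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: term TAB description TAB member...

    Empty sets and duplicate term ids are errors.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise ValidationError(
                    f"{path}:{lineno}: gene set {fields[0]!r} has no members"
                )
            term, desc = fields[0], fields[1]
            if term in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term!r}")
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            sets[term] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def write_network(graph: nx.Graph, path: str | os.PathLike, fmt: str = "sif") -> None:
    """Write a typed network for Cytoscape import.

    Nodes carry a ``node_class`` attribute in {TF, lncRNA, mRNA}; edges carry
    an ``interaction`` attribute (``coexpressed`` for lncRNA-mRNA pairs,
    ``regulates`` for TF edges) plus ``r`` or ``fdr``. The writer stamps each
    node's ``degree`` attribute with its incident-edge count.
    """
    fmt = fmt.lower()
    if fmt not in {"sif", "graphml"}:
        raise ValidationError(f"unknown network format {fmt!r}; use 'sif' or 'graphml'")
    for node, data in graph.nodes(data=True):
        data["degree"] = graph.degree(node)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                label = data.get("interaction", SIF_COEXPRESSED)
                fh.write(f"{u}\t{label}\t{v}\n")
    else:
        # GraphML rejects None attribute values; drop them
        g = graph.copy()
        for _n, data in g.nodes(data=True):
            for k in [k for k, val in data.items() if val is None]:
                del data[k]
        for _u, _v, data in g.edges(data=True):
            for k in [k for k, val in data.items() if val is None]:
                del data[k]
        nx.write_graphml(g, path)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Result tables are TSV, fixed column order, no index column."""
    df.to_csv(path, sep="\t", index=False)
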