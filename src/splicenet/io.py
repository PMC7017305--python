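"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV with a header row; floats are written with 12
significant digits.  GMT lines are term, description, then member genes,
tab-separated; members are written sorted so serialization is canonical.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .enrichment import AnnotationSet
from .network import Interactome, Network
from .preprocess import ExpressionMatrix, GenePanel

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


def write_table(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_expression_tsv(path, level: str = "probe", stage: str = "raw") -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):  # read_csv would silently mangle these
        dups = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"{path}: duplicated sample ids {dups}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame, level=level, stage=stage)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    write_table(matrix.values, path)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return meta


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    write_table(metadata, path)


def read_probe_map_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    if frame.iloc[:, 0].duplicated().any():
        raise ValueError(f"{path}: probe mapped more than once")
    return pd.Series(frame.iloc[:, 1].to_numpy(),
                     index=pd.Index(frame.iloc[:, 0], name="probe_id"),
                     name="gene_id")


def write_probe_map_tsv(probe_map: pd.Series, path) -> None:
    frame = probe_map.rename("gene_id").to_frame()
    frame.index.name = "probe_id"
    write_table(frame, path)


def read_panel(path) -> GenePanel:
    genes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return GenePanel.from_iterable(genes)


def write_panel(panel: GenePanel, path) -> None:
    Path(path).write_text("\n".join(sorted(panel.gene_ids, key=str)) + "\n")


def read_gmt(path, universe: Iterable | None = None) -> AnnotationSet:
    """Read a GMT file; the universe defaults to the union of all members."""
    terms: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs term, description, members")
        term, desc, members = parts[0], parts[1], parts[2:]
        if term in terms:
            raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
        terms[term] = frozenset(m for m in members if m)
        descriptions[term] = desc
    if not terms:
        raise ValueError(f"{path}: empty GMT file")
    if universe is None:
        universe = frozenset().union(*terms.values())
    return AnnotationSet(terms, frozenset(universe), descriptions)


def write_gmt(annotations: AnnotationSet, path) -> None:
    lines = []
    for term in sorted(annotations.terms):
        desc = annotations.descriptions.get(term, "")
        members = sorted(annotations.terms[term], key=str)
        lines.append("\t".join([term, desc, *map(str, members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list_tsv(path) -> Interactome:
    frame = pd.read_csv(path, sep="\t")
    required = {"node_a", "node_b", "score"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    loops = frame["node_a"] == frame["node_b"]
    if loops.any():
        lineno = int(frame.index[loops][0]) + 2  # header is line 1
        raise ValueError(f"{path}:{lineno}: self-loop edge")
    keys = [frozenset(p) for p in zip(frame["node_a"], frame["node_b"])]
    seen: dict[frozenset, int] = {}
    for i, key in enumerate(keys):
        if key in seen:
            raise ValueError(f"{path}:{i + 2}: duplicate of edge on line {seen[key] + 2}")
        seen[key] = i
    return Interactome(frame)


def write_edge_list_tsv(interactome: Interactome, path) -> None:
    write_table(interactome.edges, path, index=False)


def write_graphml(network: Network | nx.Graph, path) -> None:
    g = network.graph if isinstance(network, Network) else network
    nx.write_graphml(g, path)


def write_sif(network: Network | nx.Graph, path) -> None:
    """Simple interaction format: node_a <tab> pp <tab> node_b."""
    g = network.graph if isinstance(network, Network) else network
    lines = [f"{a}\tpp\t{b}" for a, b in g.edges()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
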