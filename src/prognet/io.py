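"""Readers and writers for the package's plain-text interchange formats.

Expression matrices travel as TSV (first column = gene symbol, header row =
sample ids), clinical tables as CSV indexed by ``sample_id``, interaction
networks as two-column edge lists or BioGRID TAB-style exports, labels and
splits as two-column CSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, InputFormatError

logger = logging.getLogger(__name__)

BIOGRID_SYMBOL_COLUMNS = (
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
)


def read_expression(path, strict: bool = True) -> ExpressionMatrix:
    """Read a genes x samples TSV.

    Duplicate gene rows are collapsed by their mean (the usual
    probe-to-gene reduction), with a logged warning.  In strict mode any
    non-numeric cell raises :class:`InputFormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputFormatError(f"{path}: empty expression file") from exc
    if df.empty and df.columns.empty:
        raise InputFormatError(f"{path}: no sample columns in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if strict and bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise InputFormatError(
            f"{path}: non-numeric value {df.loc[gene, col]!r} "
            f"at gene {gene!r}, sample {col!r}"
        )
    if numeric.isna().any().any():
        raise InputFormatError(f"{path}: missing values in expression matrix")
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning(
            "%s: %d duplicate gene rows collapsed by mean", path, n_dup
        )
        numeric = numeric.groupby(level=0, sort=False).mean()
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index_label="sample_id")


def read_network(path, dialect: str = "edge_list") -> nx.Graph:
    """Read an undirected simple interaction graph.

    ``edge_list`` expects two whitespace/tab-separated gene symbols per line;
    ``biogrid_tab`` expects a tab-delimited table with official-symbol
    interactor columns.  Self-loops and duplicate pairs are dropped and
    counted in the log.
    """
    path = Path(path)
    if dialect == "edge_list":
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) < 2:
                    raise InputFormatError(
                        f"{path}:{lineno}: expected two gene symbols"
                    )
                pairs.append((parts[0], parts[1]))
    elif dialect == "biogrid_tab":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in BIOGRID_SYMBOL_COLUMNS if c not in df.columns]
        if missing:
            raise InputFormatError(
                f"{path}: missing BioGRID columns {missing}"
            )
        pairs = list(
            zip(
                df[BIOGRID_SYMBOL_COLUMNS[0]].astype(str),
                df[BIOGRID_SYMBOL_COLUMNS[1]].astype(str),
            )
        )
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")

    graph = nx.Graph()
    n_self, n_dup = 0, 0
    for a, b in pairs:
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loops and %d duplicate edges",
            path, n_self, n_dup,
        )
    return graph


def write_network(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in graph.edges():
            fh.write(f"{a}\t{b}\n")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, index_col="sample_id")
    return df["label"].astype(str)


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, index_label="sample_id")


def write_ranking(ranking, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\trank\n")
        for i, gene in enumerate(ranking.order, start=1):
            fh.write(f"{gene}\t{i}\n")


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("score").to_csv(path, sep="\t", index_label="gene")


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return df["score"].astype(float)
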