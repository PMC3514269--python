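"""Plain-text readers and writers: expression/weights/basal TSV and SIF.

Expression files are genes-on-rows TSV with a header row (first column gene
identifiers, remaining columns timepoint labels); SIF is the Cytoscape
``source <tab> relation <tab> target`` interchange, with signed relations
encoded as ``pos``/``neg``.  All writers are deterministic; all readers
reject malformed input with the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import ParseError
from .model import ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_basal_tsv",
    "write_basal_tsv",
    "read_weights_tsv",
    "write_weights_tsv",
    "read_network_sif",
    "write_network_sif",
    "write_benchmark_tsv",
]


def _parse_float(cell: str, path, lineno: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric cell {cell!r}") from None


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes-by-timepoints TSV into an :class:`ExpressionMatrix`.

    Timepoints come from the header when every label parses as a number,
    and default to ``0, 1, 2, ...`` otherwise.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: expected a header row and at least one gene row")
    header = lines[0].split("\t")
    n_cols = len(header)
    try:
        times = np.array([float(h) for h in header[1:]])
        if not np.all(np.diff(times) > 0):
            times = None
    except ValueError:
        times = None
    gene_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise ParseError(
                f"{path}:{lineno}: ragged row with {len(cells)} cells, expected {n_cols}"
            )
        gene_ids.append(cells[0])
        rows.append([_parse_float(c, path, lineno) for c in cells[1:]])
    return ExpressionMatrix(
        values=np.array(rows), gene_ids=tuple(gene_ids), times=times
    )


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(f"{t:g}" for t in expr.times) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_basal_tsv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Two-column ``gene <tab> value`` file (header optional)."""
    path = Path(path)
    genes, values = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
        if lineno == 1 and cells[1].lower() in ("value", "basal"):
            continue
        genes.append(cells[0])
        values.append(_parse_float(cells[1], path, lineno))
    return np.array(values), tuple(genes)


def write_basal_tsv(B: np.ndarray, gene_ids, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tvalue\n")
        for gid, v in zip(gene_ids, np.asarray(B, dtype=float)):
            fh.write(f"{gid}\t{float(v)!r}\n")


def read_weights_tsv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Full N-by-N weight matrix with gene-id headers on both axes."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty weights file")
    header = lines[0].split("\t")[1:]
    n = len(header)
    W = np.empty((len(lines) - 1, n))
    gene_ids = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n + 1:
            raise ParseError(f"{path}:{lineno}: ragged row")
        gene_ids.append(cells[0])
        W[lineno - 2] = [_parse_float(c, path, lineno) for c in cells[1:]]
    if W.shape[0] != n:
        raise ParseError(f"{path}: matrix is {W.shape[0]}x{n}, expected square")
    return W, tuple(gene_ids)


def write_weights_tsv(W: np.ndarray, gene_ids, path) -> None:
    W = np.asarray(W, dtype=float)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(gene_ids) + "\n")
        for gid, row in zip(gene_ids, W):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_network_sif(graph: nx.DiGraph, path) -> None:
    """SIF lines ``regulator <tab> pos|neg <tab> target``, sorted."""
    records = []
    for u, v, data in graph.edges(data=True):
        sign = data.get("sign", 1 if data.get("weight", 1.0) >= 0 else -1)
        records.append((str(u), "pos" if sign > 0 else "neg", str(v)))
    with open(path, "w") as fh:
        for rec in sorted(records):
            fh.write("\t".join(rec) + "\n")


def read_network_sif(path, nodes=None) -> nx.DiGraph:
    """Read a signed SIF file; ``nodes`` optionally fixes the full node set
    (isolated nodes do not appear in SIF lines)."""
    path = Path(path)
    g: nx.DiGraph = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(str(n) for n in nodes)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
        src, rel, dst = cells
        if rel not in ("pos", "neg"):
            raise ParseError(f"{path}:{lineno}: unknown relation {rel!r}")
        g.add_edge(src, dst, sign=1 if rel == "pos" else -1)
    return g


def write_benchmark_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
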