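"""Network and heatmap data products derived from a symmetric MR matrix.

Edges connect gene pairs whose MR falls strictly below the construction
threshold (the captions' "MR < 100" convention); isolated vertices are kept
so absent edges remain visible.  The heatmap is a long-format grid whose
ordering follows the input gene order — no clustering is applied.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import AnalysisError, ConfigError

__all__ = [
    "build_network",
    "write_network",
    "heatmap_grid",
    "write_heatmap",
    "render_heatmap",
]

NETWORK_FORMATS = ("graphml", "edge_tsv")


def _check_symmetric(mr_matrix: pd.DataFrame) -> np.ndarray:
    if list(mr_matrix.index) != list(mr_matrix.columns):
        raise AnalysisError("MR matrix rows and columns must list the same genes in order")
    values = mr_matrix.to_numpy(dtype=float)
    off = ~np.eye(len(values), dtype=bool)
    if not np.allclose(values[off], values.T[off], rtol=0.0, atol=1e-9, equal_nan=True):
        raise AnalysisError("MR matrix is not symmetric")
    return values


def build_network(
    mr_matrix: pd.DataFrame,
    threshold: float,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> nx.Graph:
    """Coexpression network with an edge wherever MR < threshold (strict).

    ``node_attrs`` maps gene -> attribute dict (symbol, category flags, fold
    change) copied onto vertices.  All input genes become vertices, so genes
    without a qualifying partner stay as isolated vertices.
    """
    if threshold <= 0:
        raise ConfigError("the edge threshold must be positive")
    if len(mr_matrix) < 2:
        raise AnalysisError("a network needs at least 2 genes")
    values = _check_symmetric(mr_matrix)
    genes = list(mr_matrix.index)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            mr = values[i, j]
            if np.isfinite(mr) and mr < threshold:
                graph.add_edge(genes[i], genes[j], mr=float(mr))
    if node_attrs:
        for gene in genes:
            for key, value in dict(node_attrs.get(gene, {})).items():
                graph.nodes[gene][key] = value
    return graph


def write_network(network: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Serialize as GraphML (vertex attributes + mr edge attribute) or as a
    three-column gene_a/gene_b/mr edge TSV."""
    if fmt not in NETWORK_FORMATS:
        raise ConfigError(f"unknown network format {fmt!r}; expected one of {', '.join(NETWORK_FORMATS)}")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
        return
    records = [
        {"gene_a": a, "gene_b": b, "mr": data["mr"]}
        for a, b, data in sorted(network.edges(data=True))
    ]
    pd.DataFrame(records, columns=["gene_a", "gene_b", "mr"]).to_csv(path, sep="\t", index=False)


def heatmap_grid(mr_matrix: pd.DataFrame, order: list[str] | None = None) -> pd.DataFrame:
    """Long-format (row_gene, col_gene, mr, is_self) records in grid order.

    The k x k grid yields exactly k^2 records; diagonal cells are flagged
    ``is_self`` and carry no MR number.
    """
    _check_symmetric(mr_matrix)
    genes = list(mr_matrix.index) if order is None else list(order)
    if order is not None and set(order) != set(mr_matrix.index):
        raise AnalysisError("heatmap order must be a permutation of the matrix genes")
    records = []
    for row in genes:
        for col in genes:
            is_self = row == col
            records.append(
                {
                    "row_gene": row,
                    "col_gene": col,
                    "mr": np.nan if is_self else float(mr_matrix.loc[row, col]),
                    "is_self": is_self,
                }
            )
    return pd.DataFrame.from_records(records)


def write_heatmap(grid: pd.DataFrame, path: str | Path) -> None:
    out = grid.copy()
    out["mr"] = ["self" if s else f"{m:.10g}" for s, m in zip(out["is_self"], out["mr"])]
    out[["row_gene", "col_gene", "mr"]].to_csv(path, sep="\t", index=False)


def render_heatmap(grid: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Optional raster rendering: low MR (strong coexpression) maps to high
    intensity; self cells are blanked."""
    genes = list(dict.fromkeys(grid["row_gene"]))
    k = len(genes)
    values = grid["mr"].to_numpy(dtype=float).reshape(k, k)
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * k), max(3.2, 0.4 * k)))
    image = ax.imshow(values, cmap="viridis_r", interpolation="nearest")
    ax.set_xticks(range(k), genes, rotation=90, fontsize=7)
    ax.set_yticks(range(k), genes, fontsize=7)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(image, ax=ax, label="Mutual Rank")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
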