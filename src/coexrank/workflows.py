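"""End-to-end workflows tying the modules into the three reference modes.

Each workflow is a pure function of (input files, configuration): it loads
the expression matrix and whatever supporting files the config names, runs
the MR analysis, integrates annotations, and writes the coexpression table,
heatmap grid, network and (where configured) GO enrichment into the output
directory, together with a JSON run manifest recording inputs, parameters,
package versions and every warning emitted.  Repeated runs over identical
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from ._exceptions import AnalysisError, ConfigError
from .annotate import annotate_table, assign_categories
from .enrichment import DEFAULT_MR_THRESHOLD, go_enrichment, select_foreground
from .io import (
    ExpressionMatrix,
    parse_obo,
    read_attribute_map,
    read_category_config,
    read_expression_matrix,
    read_gene_info,
)
from .mr import (
    DEFAULT_TOP_N,
    CoexpressionTable,
    compound_reference,
    pairwise_mr_table,
    targeted_mr_table,
)
from .outputs import build_network, heatmap_grid, write_heatmap, write_network

logger = logging.getLogger("coexrank")

__all__ = ["RunConfig", "run_single", "run_set", "run_compound"]

DEFAULT_GRAPH_GENES = 12


@dataclass
class RunConfig:
    """Everything a run needs; only ``expression``, a reference and
    ``out_dir`` are mandatory.

    ``reference`` names a single reference gene (single mode); ``gene_list``
    names the reference set (set and compound modes); ``aggregate`` picks
    the compound aggregation method.  ``graph_genes`` controls how many of
    the top table rows (plus the reference) enter the pairwise MR matrix
    behind the single-mode heatmap and network.
    """

    expression: str | Path = ""
    out_dir: str | Path = "."
    reference: str | None = None
    gene_list: Sequence[str] | None = None
    aggregate: str | None = None
    compound_label: str = "compound_reference"
    top_n: int = DEFAULT_TOP_N
    mr_threshold: float = DEFAULT_MR_THRESHOLD
    adjust: str = "benjamini_hochberg"
    propagate: bool = False
    graph_genes: int = DEFAULT_GRAPH_GENES
    descriptions: str | Path | None = None
    symbols: str | Path | None = None
    de: str | Path | None = None
    pfam: str | Path | None = None
    go: str | Path | None = None
    obo: str | Path | None = None
    categories: str | Path | None = None
    delimiter: str | None = None
    allow_missing: bool = False

    def describe(self) -> dict:
        out = asdict(self)
        for key, value in out.items():
            if isinstance(value, Path):
                out[key] = str(value)
        if out["gene_list"] is not None:
            out["gene_list"] = list(out["gene_list"])
        return out


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


@dataclass
class _Inputs:
    matrix: ExpressionMatrix
    info: object
    de: object
    pfam: object
    go: object
    ontology: object
    categories: list


def _load_inputs(config: RunConfig) -> _Inputs:
    matrix = read_expression_matrix(
        config.expression, delimiter=config.delimiter, allow_missing=config.allow_missing
    )
    info = (
        read_gene_info(config.descriptions, config.symbols)
        if (config.descriptions or config.symbols)
        else None
    )
    de = read_attribute_map(config.de, "numeric") if config.de else None
    pfam = read_attribute_map(config.pfam, "set") if config.pfam else None
    go = read_attribute_map(config.go, "set") if config.go else None
    ontology = parse_obo(config.obo) if config.obo else None
    categories = read_category_config(config.categories) if config.categories else []
    return _Inputs(matrix, info, de, pfam, go, ontology, categories)


def _decorate(table: CoexpressionTable, inputs: _Inputs, config: RunConfig) -> CoexpressionTable:
    table = annotate_table(table, inputs.info, inputs.de, inputs.pfam, inputs.go)
    if inputs.categories:
        table = assign_categories(
            table,
            inputs.categories,
            pfam=inputs.pfam,
            go=inputs.go,
            ontology=inputs.ontology,
            propagate=config.propagate,
        )
    return table


def _node_attrs(table: CoexpressionTable, inputs: _Inputs) -> dict[str, dict]:
    attrs: dict[str, dict] = {}
    frame = table.frame
    for _, row in frame.iterrows():
        entry: dict[str, object] = {}
        if "symbol" in frame.columns:
            entry["symbol"] = row["symbol"]
        for category in inputs.categories:
            entry[category.name] = row[category.name]
        if "fold_change" in frame.columns and row["fold_change"] != "":
            entry["fold_change"] = float(row["fold_change"])
        attrs[row["gene"]] = entry
    return attrs


def _write_products(
    out_dir: Path,
    table: CoexpressionTable,
    mr_matrix: pd.DataFrame,
    inputs: _Inputs,
    config: RunConfig,
) -> dict[str, str]:
    outputs: dict[str, str] = {}
    table_path = out_dir / "coexpression_table.tsv"
    table.write(table_path)
    outputs["table"] = table_path.name

    grid = heatmap_grid(mr_matrix)
    heatmap_path = out_dir / "heatmap.tsv"
    write_heatmap(grid, heatmap_path)
    outputs["heatmap"] = heatmap_path.name

    graph_rows = table.frame[table.frame["gene"].isin(mr_matrix.index)]
    graph_table = CoexpressionTable(table.reference, graph_rows, table.extra_columns)
    network = build_network(mr_matrix, config.mr_threshold, _node_attrs(graph_table, inputs))
    graphml_path = out_dir / "network.graphml"
    write_network(network, graphml_path, "graphml")
    edges_path = out_dir / "network_edges.tsv"
    write_network(network, edges_path, "edge_tsv")
    outputs["network_graphml"] = graphml_path.name
    outputs["network_edges"] = edges_path.name
    return outputs


def _maybe_enrich(
    out_dir: Path, table: CoexpressionTable, inputs: _Inputs, config: RunConfig
) -> dict[str, str]:
    if inputs.go is None:
        logger.info("no GO assignment file provided; skipping enrichment")
        return {}
    foreground = select_foreground(table, config.mr_threshold)
    result = go_enrichment(
        foreground,
        inputs.matrix,
        inputs.go,
        ontology=inputs.ontology,
        method=config.adjust,
        propagate=config.propagate,
    )
    path = out_dir / "go_enrichment.tsv"
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return {"enrichment": path.name}


def _finish(
    out_dir: Path,
    mode: str,
    config: RunConfig,
    outputs: dict[str, str],
    warnings: list[str],
) -> dict:
    manifest = {
        "tool": "coexrank",
        "version": __version__,
        "mode": mode,
        "config": config.describe(),
        "outputs": outputs,
        "warnings": warnings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _run(mode: str, config: RunConfig) -> dict:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logger.addHandler(collector)
    try:
        inputs = _load_inputs(config)
        if mode == "single":
            reference = config.reference
            if not reference:
                raise ConfigError("single mode needs a reference gene")
            if reference not in inputs.matrix:
                raise AnalysisError(f"reference gene {reference!r} is absent from the matrix")
            matrix = inputs.matrix
        elif mode == "compound":
            if not config.gene_list or not config.aggregate:
                raise ConfigError("compound mode needs a gene list and an aggregation method")
            matrix = compound_reference(
                inputs.matrix, list(config.gene_list), config.aggregate, config.compound_label
            )
            inputs.matrix = matrix
            reference = config.compound_label
        elif mode == "set":
            if not config.gene_list:
                raise ConfigError("set mode needs a gene list")
            matrix = inputs.matrix
            reference = None
        else:  # pragma: no cover - internal
            raise ConfigError(f"unknown mode {mode!r}")

        if mode in ("single", "compound"):
            table = targeted_mr_table(matrix, reference, config.top_n)
            table = _decorate(table, inputs, config)
            graph_set = [reference] + table.candidate_genes[: max(config.graph_genes, 1)]
            _, mr_matrix = pairwise_mr_table(matrix, graph_set)
            outputs = _write_products(out_dir, table, mr_matrix, inputs, config)
            outputs.update(_maybe_enrich(out_dir, table, inputs, config))
        else:
            table, mr_matrix = pairwise_mr_table(matrix, list(config.gene_list))
            table = _decorate(table, inputs, config)
            outputs = _write_products(out_dir, table, mr_matrix, inputs, config)
        return _finish(out_dir, mode, config, outputs, collector.messages)
    finally:
        logger.removeHandler(collector)


def run_single(config: RunConfig) -> dict:
    """Targeted workflow around one reference gene; returns the manifest."""
    return _run("single", config)


def run_set(config: RunConfig) -> dict:
    """All-pairs workflow over a reference gene set (table keyed to the
    first retained gene)."""
    return _run("set", config)


def run_compound(config: RunConfig) -> dict:
    """Targeted workflow around a compound (aggregated) reference gene."""
    return _run("compound", config)
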