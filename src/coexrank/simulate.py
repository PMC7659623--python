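"""Synthetic expression data with planted coexpression modules.

Each module follows an equicorrelated single-latent construction: member
gene *i* is ``sqrt(rho) * latent + sqrt(1 - rho) * noise_i`` with one shared
standard-normal latent factor per module and independent unit-normal noise,
so the expected within-module sample PCC equals ``rho``.  Background genes
are pure noise.  This reproduces the correlation structure a coregulated
biosynthetic pathway leaves in an expression atlas — which is the only
property Mutual Rank analysis consumes — without attempting realistic
RNA-seq count distributions.

``generate_supporting_files`` writes the matching annotation, symbol, GO,
ontology, Pfam, differential-expression and category files so the whole
pipeline can run end-to-end with no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError
from .io import ExpressionMatrix

__all__ = ["ModuleSpec", "generate_expression", "generate_supporting_files"]

BACKGROUND = "background"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: its size, target within-module PCC and the GO
    term planted on every member."""

    module_id: str
    size: int
    latent_correlation: float
    annotated_term: str

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ConfigError(f"module {self.module_id!r} needs size >= 2")
        if not (0.0 < self.latent_correlation <= 1.0):
            raise ConfigError(
                f"module {self.module_id!r} latent correlation must be in (0, 1]"
            )


def generate_expression(
    n_genes: int,
    n_samples: int,
    modules: Sequence[ModuleSpec],
    seed: int,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix with planted modules plus a ground-truth table.

    Module members occupy the first rows in module order; the remainder are
    background noise genes.  Deterministic under ``seed``.  The truth table
    has columns ``gene`` and ``module_id`` (``"background"`` for noise
    genes).
    """
    if n_samples < 4:
        raise ConfigError("need at least 4 samples")
    total_module = sum(m.size for m in modules)
    if total_module > n_genes:
        raise ConfigError(
            f"module sizes sum to {total_module} but only {n_genes} genes requested"
        )
    ids = {m.module_id for m in modules}
    if len(ids) != len(modules) or BACKGROUND in ids:
        raise ConfigError("module IDs must be unique and not 'background'")

    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    sample_ids = [f"S{j:02d}" for j in range(1, n_samples + 1)]

    values = np.empty((n_genes, n_samples))
    membership = [BACKGROUND] * n_genes
    row = 0
    for module in modules:
        latent = rng.standard_normal(n_samples)
        rho = module.latent_correlation
        for _ in range(module.size):
            noise = rng.standard_normal(n_samples)
            values[row] = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
            membership[row] = module.module_id
            row += 1
    values[row:] = rng.standard_normal((n_genes - row, n_samples))

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    truth = pd.DataFrame({"gene": gene_ids, "module_id": membership})
    return matrix, truth


_OBO_HEADER = "format-version: 1.2\nontology: synthetic-toy\n"
_ROOT_TERM = "GO:0008150"


def _write_toy_obo(path: Path, terms: dict[str, str]) -> None:
    """Tiny synthetic ontology: every used term is_a one mid-level parent
    which is_a the biological_process root."""
    mid = "GO:0009987"
    stanzas = [
        _OBO_HEADER,
        f"[Term]\nid: {_ROOT_TERM}\nname: biological_process\nnamespace: biological_process\n",
        f"[Term]\nid: {mid}\nname: cellular process\nnamespace: biological_process\nis_a: {_ROOT_TERM} ! biological_process\n",
    ]
    for term_id, name in sorted(terms.items()):
        stanzas.append(
            f"[Term]\nid: {term_id}\nname: {name}\nnamespace: biological_process\nis_a: {mid} ! cellular process\n"
        )
    path.write_text("\n".join(stanzas))


def generate_supporting_files(
    truth: pd.DataFrame,
    out_dir: str | Path,
    seed: int,
    modules: Sequence[ModuleSpec] | None = None,
) -> dict[str, Path]:
    """Emit the full synthetic supporting-file set next to a truth table.

    Writes description/symbol maps, a GO map planting each module's term on
    its members plus sparse random background terms, a toy OBO covering
    every emitted term, a Pfam map (module-1 members share one domain), a
    differential-expression table with elevated fold changes for module 1,
    and one gene-list category per module with its config.  Module metadata
    (the planted GO term per module) is reconstructed from ``modules`` when
    given, otherwise default term IDs are assigned per module in truth-table
    order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    module_ids = [m for m in dict.fromkeys(truth["module_id"]) if m != BACKGROUND]
    if modules is not None:
        planted_terms = {m.module_id: m.annotated_term for m in modules}
    else:
        planted_terms = {
            mid: f"GO:{2000001 + i:07d}" for i, mid in enumerate(module_ids)
        }
    members = {
        mid: list(truth.loc[truth["module_id"] == mid, "gene"]) for mid in module_ids
    }
    genes = list(truth["gene"])
    gene_module = dict(zip(truth["gene"], truth["module_id"]))
    paths: dict[str, Path] = {}

    # descriptions: full coverage; symbols: module members only (partial coverage)
    desc_lines = []
    symbol_lines = []
    for gene in genes:
        mid = gene_module[gene]
        if mid == BACKGROUND:
            desc_lines.append(f"{gene}\tbackground gene")
        else:
            desc_lines.append(f"{gene}\tplanted {mid} pathway gene")
    for mid in module_ids:
        for i, gene in enumerate(members[mid], start=1):
            symbol_lines.append(f"{gene}\t{mid.lower()}{i}")
    paths["descriptions"] = out_dir / "descriptions.tsv"
    paths["descriptions"].write_text("\n".join(desc_lines) + "\n")
    paths["symbols"] = out_dir / "symbols.tsv"
    paths["symbols"].write_text("\n".join(symbol_lines) + "\n")

    # GO map: planted term on module members; sparse random background terms
    background_terms = [f"GO:{3000001 + i:07d}" for i in range(5)]
    go_lines = []
    for gene in genes:
        mid = gene_module[gene]
        if mid != BACKGROUND:
            go_lines.append(f"{gene}\t{planted_terms[mid]}")
        for term in background_terms:
            if rng.random() < 0.10:
                go_lines.append(f"{gene}\t{term}")
    paths["go"] = out_dir / "go_map.tsv"
    paths["go"].write_text("\n".join(go_lines) + "\n")

    term_names = {t: f"synthetic background process {i + 1}" for i, t in enumerate(background_terms)}
    for mid in module_ids:
        term_names[planted_terms[mid]] = f"planted {mid} pathway process"
    paths["obo"] = out_dir / "ontology.obo"
    _write_toy_obo(paths["obo"], term_names)

    # Pfam map: module-1 members share a domain; random background domains
    domains = [f"PF{10000 + i:05d}" for i in range(4)]
    pfam_lines = []
    if module_ids:
        for gene in members[module_ids[0]]:
            pfam_lines.append(f"{gene}\tPF00067")
    for gene in genes:
        if rng.random() < 0.05:
            pfam_lines.append(f"{gene}\t{rng.choice(domains)}")
    paths["pfam"] = out_dir / "pfam_map.tsv"
    paths["pfam"].write_text("\n".join(pfam_lines) + "\n")

    # DE table: module-1 members strongly induced, everything else near 1
    de_lines = []
    first = set(members[module_ids[0]]) if module_ids else set()
    for gene in genes:
        fc = rng.uniform(4.0, 8.0) if gene in first else float(np.exp(rng.normal(0.0, 0.25)))
        de_lines.append(f"{gene}\t{fc:.4f}")
    paths["de"] = out_dir / "de.tsv"
    paths["de"].write_text("gene\tfold_change\n" + "\n".join(de_lines) + "\n")

    # one gene-list category per module
    config_lines = []
    for mid in module_ids:
        member_file = out_dir / f"category_{mid}.txt"
        member_file.write_text("\n".join(members[mid]) + "\n")
        config_lines.append(f"{mid}\tgene_list\t{member_file.name}")
    paths["categories"] = out_dir / "categories.tsv"
    paths["categories"].write_text("\n".join(config_lines) + "\n" if config_lines else "")

    return paths
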