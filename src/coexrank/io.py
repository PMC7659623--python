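"""Readers and containers for every file format the pipeline touches.

Expression matrices arrive as genes x samples TSV/CSV with gene IDs in the
first column and sample names in the header.  Supporting information
(descriptions, symbols, Pfam domains, GO assignments, fold changes) arrives
as two-column TSV maps, the ontology as OBO 1.2, and custom categories as a
small name/kind/member-file config.  All readers tolerate Windows and Unix
line endings.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import obonet
import pandas as pd

from ._exceptions import AnalysisError, ConfigError, LoadError

logger = logging.getLogger("coexrank")

__all__ = [
    "ExpressionMatrix",
    "GeneInfoMap",
    "AttributeMap",
    "OntologyGraph",
    "CategoryDefinition",
    "read_expression_matrix",
    "read_two_column_map",
    "read_attribute_map",
    "read_gene_info",
    "parse_obo",
    "read_category_config",
    "detect_delimiter",
]


def detect_delimiter(path: str | Path, delimiter: str | None = None) -> str:
    """Tab for ``.tsv``/``.txt``, comma for ``.csv``; explicit ``delimiter`` wins."""
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Genes x samples numeric matrix with unique, trimmed gene identifiers.

    Expression units (FPKM/TPM, logged or not) are treated opaquely: Pearson
    correlation and ranks are the only downstream consumers.

    Parameters
    ----------
    data
        DataFrame indexed by gene ID with one column per sample.  Values must
        be finite; ``NaN`` is only accepted transiently before
        :meth:`drop_missing`.
    """

    def __init__(self, data: pd.DataFrame):
        index = pd.Index([str(g).strip() for g in data.index], name="gene")
        if index.has_duplicates:
            dup = index[index.duplicated()][0]
            raise LoadError(f"duplicate gene ID {dup!r} in expression matrix")
        columns = pd.Index([str(s).strip() for s in data.columns])
        if columns.has_duplicates:
            dup = columns[columns.duplicated()][0]
            raise LoadError(f"duplicate sample name {dup!r} in expression matrix")
        values = data.to_numpy(dtype=float, copy=True)
        if np.isinf(values).any():
            gene = index[np.isinf(values).any(axis=1)][0]
            raise LoadError(f"non-finite expression value for gene {gene!r}")
        self.data = pd.DataFrame(values, index=index, columns=columns)

    # -- basic accessors ----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def expression(self, gene: str) -> np.ndarray:
        """Expression vector of ``gene`` across samples."""
        if gene not in self.data.index:
            raise AnalysisError(f"gene {gene!r} is absent from the expression matrix")
        return self.data.loc[gene].to_numpy()

    def drop_missing(self) -> "ExpressionMatrix":
        """Return a copy without genes containing missing values."""
        mask = self.data.notna().all(axis=1)
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.warning("dropped %d gene(s) with missing expression values", n_dropped)
        return ExpressionMatrix(self.data.loc[mask])

    def with_row(self, gene: str, values: Iterable[float]) -> "ExpressionMatrix":
        """Return a copy with one appended row (used for compound references)."""
        if gene in self.data.index:
            raise ConfigError(f"label {gene!r} is already a gene ID in the matrix")
        row = pd.DataFrame([list(values)], index=[gene], columns=self.data.columns)
        return ExpressionMatrix(pd.concat([self.data, row]))

    def write(self, path: str | Path, delimiter: str | None = None) -> None:
        sep = detect_delimiter(path, delimiter)
        self.data.to_csv(path, sep=sep, index_label="gene")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    allow_missing: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples matrix from TSV/CSV.

    The first column holds gene IDs (its header is arbitrary), the header row
    holds sample names.  Rows with non-numeric cells are rejected with an
    error naming the offending gene; missing cells are an error unless
    ``allow_missing`` is set, in which case genes containing them are dropped.
    """
    path = Path(path)
    sep = detect_delimiter(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise LoadError(f"malformed expression file {path.name}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"expression file {path.name} is empty") from exc

    numeric = raw.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    blank = raw.apply(lambda col: col.str.strip() == "")
    bad = numeric.isna() & ~blank
    if bad.to_numpy().any():
        gene = raw.index[bad.any(axis=1)][0]
        raise LoadError(f"non-numeric expression value in row for gene {str(gene).strip()!r}")
    numeric = numeric.mask(blank)

    if numeric.isna().to_numpy().any():
        if not allow_missing:
            gene = raw.index[numeric.isna().any(axis=1)][0]
            raise LoadError(
                f"missing expression value for gene {str(gene).strip()!r} "
                "(pass allow_missing=True to drop such genes)"
            )
        return ExpressionMatrix(numeric).drop_missing()
    return ExpressionMatrix(numeric)


# ---------------------------------------------------------------------------
# Two-column supporting maps
# ---------------------------------------------------------------------------


@dataclass
class GeneInfoMap:
    """Optional per-gene description and symbol text; lookups never fail."""

    descriptions: dict[str, str] = field(default_factory=dict)
    symbols: dict[str, str] = field(default_factory=dict)

    def description(self, gene: str) -> str:
        return self.descriptions.get(gene, "")

    def symbol(self, gene: str) -> str:
        return self.symbols.get(gene, "")


@dataclass
class AttributeMap:
    """gene -> set of attribute IDs (``kind='set'``) or gene -> number (``kind='numeric'``)."""

    kind: str
    sets: dict[str, set[str]] = field(default_factory=dict)
    numbers: dict[str, float] = field(default_factory=dict)

    def get_set(self, gene: str) -> set[str]:
        return self.sets.get(gene, set())

    def get_value(self, gene: str) -> float | None:
        return self.numbers.get(gene)

    def __len__(self) -> int:
        return len(self.sets) if self.kind == "set" else len(self.numbers)

    @property
    def genes(self) -> set[str]:
        return set(self.sets if self.kind == "set" else self.numbers)


def _read_pairs(path: str | Path, sep: str) -> list[tuple[int, str, str]]:
    """(line number, col1, col2) triples, tolerant of CRLF and trailing newline."""
    pairs: list[tuple[int, str, str]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) < 2:
            raise LoadError(f"{Path(path).name}: line {lineno} has fewer than 2 columns")
        pairs.append((lineno, parts[0].strip(), parts[1].strip()))
    return pairs


def read_two_column_map(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Plain gene -> text map (descriptions or symbols); later rows win."""
    sep = detect_delimiter(path, delimiter)
    return {g: v for _, g, v in _read_pairs(path, sep)}


def read_gene_info(
    descriptions: str | Path | None = None,
    symbols: str | Path | None = None,
    delimiter: str | None = None,
) -> GeneInfoMap:
    info = GeneInfoMap()
    if descriptions is not None:
        info.descriptions = read_two_column_map(descriptions, delimiter)
    if symbols is not None:
        info.symbols = read_two_column_map(symbols, delimiter)
    return info


def _looks_numeric(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def read_attribute_map(
    path: str | Path,
    value_kind: str = "set",
    delimiter: str | None = None,
) -> AttributeMap:
    """Load a many-to-many gene->attribute map or a gene->number map.

    ``set`` kind aggregates repeated gene rows into one set.  ``numeric``
    kind keeps the last value for a duplicated gene (with a warning).  A
    header row is auto-skipped when the numeric kind finds a non-numeric
    second column on line 1.
    """
    if value_kind not in ("set", "numeric"):
        raise ConfigError(f"unknown attribute map kind {value_kind!r}")
    sep = detect_delimiter(path, delimiter)
    pairs = _read_pairs(path, sep)
    out = AttributeMap(kind=value_kind)
    for lineno, gene, value in pairs:
        if value_kind == "set":
            out.sets.setdefault(gene, set()).add(value)
        else:
            if not _looks_numeric(value):
                if lineno == 1:
                    continue  # header row
                raise LoadError(f"{Path(path).name}: non-numeric value {value!r} on line {lineno}")
            if gene in out.numbers:
                logger.warning("duplicate numeric entry for gene %s; keeping the last value", gene)
            out.numbers[gene] = float(value)
    return out


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    term_id: str
    name: str
    namespace: str
    parents: set[str]
    obsolete: bool


class OntologyGraph:
    """GO terms with is_a/part_of parent links, alt-ID resolution and
    transitive ancestor queries.

    Obsolete terms stay in the index (so lookups resolve) but are excluded
    from enrichment.  Parent links pointing at terms the file never defines
    are dropped with a warning.
    """

    def __init__(self, terms: Mapping[str, _Term], alt_ids: Mapping[str, str]):
        self._terms = dict(terms)
        self._alt = dict(alt_ids)

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return self.resolve(term_id) is not None

    def resolve(self, term_id: str) -> str | None:
        """Primary term ID for ``term_id`` (resolving alt_ids), or None."""
        if term_id in self._terms:
            return term_id
        return self._alt.get(term_id)

    def name(self, term_id: str) -> str:
        tid = self.resolve(term_id)
        return self._terms[tid].name if tid else ""

    def namespace(self, term_id: str) -> str:
        tid = self.resolve(term_id)
        return self._terms[tid].namespace if tid else ""

    def is_obsolete(self, term_id: str) -> bool:
        tid = self.resolve(term_id)
        return self._terms[tid].obsolete if tid else False

    def parents(self, term_id: str) -> set[str]:
        tid = self.resolve(term_id)
        return set(self._terms[tid].parents) if tid else set()

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable via is_a/part_of links, excluding the term itself."""
        tid = self.resolve(term_id)
        if tid is None:
            return set()
        seen: set[str] = set()
        stack = list(self._terms[tid].parents)
        while stack:
            current = stack.pop()
            if current in seen:
                continue
            seen.add(current)
            stack.extend(self._terms[current].parents - seen)
        return seen

    @property
    def term_ids(self) -> list[str]:
        return list(self._terms)


_PARENT_RELATIONS = ("is_a", "part_of")


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2 ontology into an :class:`OntologyGraph`.

    [Term] stanzas lacking an ``id`` line are skipped with a warning; dangling
    parent links are dropped with a warning.
    """
    text = Path(path).read_text()
    stanzas = text.replace("\r\n", "\n").split("\n\n")
    kept = []
    for stanza in stanzas:
        if stanza.lstrip().startswith("[Term]") and "\nid:" not in stanza:
            logger.warning("skipping [Term] stanza without an id line")
            continue
        kept.append(stanza)
    graph = obonet.read_obo(_stdio.StringIO("\n\n".join(kept)), ignore_obsolete=False)

    defined = {n for n, d in graph.nodes(data=True) if d}
    terms: dict[str, _Term] = {}
    alt: dict[str, str] = {}
    for node in defined:
        data = graph.nodes[node]
        parents: set[str] = set()
        for _, parent, relation in graph.out_edges(node, keys=True):
            if relation not in _PARENT_RELATIONS:
                continue
            if parent not in defined:
                logger.warning("dropping dangling %s link %s -> %s", relation, node, parent)
                continue
            parents.add(parent)
        terms[node] = _Term(
            term_id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            parents=parents,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
        for alt_id in data.get("alt_id", []):
            alt[alt_id] = node
    return OntologyGraph(terms, alt)


# ---------------------------------------------------------------------------
# Custom categories
# ---------------------------------------------------------------------------

CATEGORY_KINDS = ("gene_list", "pfam_domains", "go_terms")


@dataclass
class CategoryDefinition:
    """A named set of gene IDs, Pfam domain IDs or GO term IDs used to flag
    table rows (e.g. TPS gene lists or specialized-metabolism Pfam domains)."""

    name: str
    kind: str
    members: set[str]

    def __post_init__(self) -> None:
        if self.kind not in CATEGORY_KINDS:
            raise ConfigError(
                f"unknown category kind {self.kind!r} for {self.name!r}; "
                f"expected one of {', '.join(CATEGORY_KINDS)}"
            )
        if not self.members:
            raise ConfigError(f"category {self.name!r} has an empty member set")


def read_category_config(path: str | Path, delimiter: str | None = None) -> list[CategoryDefinition]:
    """Read a category config: one ``name<TAB>kind<TAB>member-file`` line per
    category, member files holding one ID per line (deduplicated).  Relative
    member paths resolve against the config file's directory; declaration
    order is preserved."""
    path = Path(path)
    sep = detect_delimiter(path, delimiter)
    categories: list[CategoryDefinition] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 3:
            raise ConfigError(f"{path.name}: line {lineno} needs name, kind and member-file columns")
        name, kind, member_file = parts[0], parts[1], parts[2]
        member_path = Path(member_file)
        if not member_path.is_absolute():
            member_path = path.parent / member_path
        members = {ln.strip() for ln in member_path.read_text().splitlines() if ln.strip()}
        if not members:
            raise ConfigError(f"category {name!r} member file {member_path.name} is empty")
        categories.append(CategoryDefinition(name=name, kind=kind, members=members))
    return categories
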