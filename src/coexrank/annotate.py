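"""Join supporting information onto a coexpression table.

Descriptions, symbols, fold changes, Pfam domains and GO assignments each
become one column; custom categories each become a flag column holding "Y"
when the gene belongs (member of the gene list, or carrying at least one of
the category's Pfam domains / GO terms).  Missing supporting data yields
empty cells — annotation never drops or reorders rows.
"""

from __future__ import annotations

from typing import Sequence

from ._exceptions import ConfigError
from .io import AttributeMap, CategoryDefinition, GeneInfoMap, OntologyGraph
from .mr import CoexpressionTable

__all__ = ["annotate_table", "assign_categories", "FLAG_YES", "FLAG_NO"]

FLAG_YES = "Y"
FLAG_NO = ""


def annotate_table(
    table: CoexpressionTable,
    info: GeneInfoMap | None = None,
    de: AttributeMap | None = None,
    pfam: AttributeMap | None = None,
    go: AttributeMap | None = None,
) -> CoexpressionTable:
    """Append description/symbol/fold-change/Pfam/GO columns for every row.

    Maps that are ``None`` simply skip their columns; genes absent from a
    supplied map get empty cells.  Fold changes pass through untransformed.
    """
    frame = table.frame.copy()
    extra = list(table.extra_columns)
    genes = frame["gene"]

    if info is not None:
        frame["symbol"] = [info.symbol(g) for g in genes]
        frame["description"] = [info.description(g) for g in genes]
        if "description" not in extra:
            extra.append("description")
    if de is not None:
        frame["fold_change"] = [
            "" if (v := de.get_value(g)) is None else v for g in genes
        ]
        if "fold_change" not in extra:
            extra.append("fold_change")
    if pfam is not None:
        frame["pfam_ids"] = [",".join(sorted(pfam.get_set(g))) for g in genes]
        if "pfam_ids" not in extra:
            extra.append("pfam_ids")
    if go is not None:
        frame["go_ids"] = [",".join(sorted(go.get_set(g))) for g in genes]
        if "go_ids" not in extra:
            extra.append("go_ids")
    return CoexpressionTable(table.reference, frame, extra)


def _gene_terms(gene: str, go: AttributeMap, ontology: OntologyGraph | None, propagate: bool) -> set[str]:
    terms = set(go.get_set(gene))
    if propagate and ontology is not None:
        for term in list(terms):
            terms |= ontology.ancestors(term)
    return terms


def assign_categories(
    table: CoexpressionTable,
    categories: Sequence[CategoryDefinition],
    pfam: AttributeMap | None = None,
    go: AttributeMap | None = None,
    ontology: OntologyGraph | None = None,
    propagate: bool = False,
) -> CoexpressionTable:
    """Add one "Y"/"" flag column per category, in declaration order.

    ``gene_list`` categories test gene membership directly; ``pfam_domains``
    and ``go_terms`` categories test whether the gene carries at least one
    member attribute (and therefore require the corresponding map).  GO
    matching uses direct assignments unless ``propagate`` extends each
    gene's terms with their ontology ancestors.
    """
    frame = table.frame.copy()
    extra = list(table.extra_columns)
    genes = frame["gene"]
    for category in categories:
        if category.kind == "gene_list":
            flags = [FLAG_YES if g in category.members else FLAG_NO for g in genes]
        elif category.kind == "pfam_domains":
            if pfam is None:
                raise ConfigError(
                    f"category {category.name!r} needs a Pfam map but none was provided"
                )
            flags = [
                FLAG_YES if pfam.get_set(g) & category.members else FLAG_NO for g in genes
            ]
        else:  # go_terms; kind validated by CategoryDefinition
            if go is None:
                raise ConfigError(
                    f"category {category.name!r} needs a GO map but none was provided"
                )
            flags = [
                FLAG_YES if _gene_terms(g, go, ontology, propagate) & category.members else FLAG_NO
                for g in genes
            ]
        frame[category.name] = flags
        if category.name not in extra:
            extra.append(category.name)
    return CoexpressionTable(table.reference, frame, extra)
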