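"""GO-term over-representation of the low-MR gene set.

The foreground is every table gene with MR strictly below a cutoff (default
MR < 100) plus the reference itself; the background is every matrix gene
carrying at least one GO assignment.  Each term annotated on at least one
foreground gene is scored with the upper-tail hypergeometric probability
P(X >= k) and the p-values are adjusted for multiple testing
(Benjamini-Hochberg by default; Bonferroni-Holm selectable).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._exceptions import AnalysisError, ConfigError
from .io import AttributeMap, ExpressionMatrix, OntologyGraph
from .mr import CoexpressionTable

logger = logging.getLogger("coexrank")

DEFAULT_MR_THRESHOLD = 100.0

ADJUSTMENT_METHODS = {
    "benjamini_hochberg": "fdr_bh",
    "holm": "holm",
}

ENRICHMENT_COLUMNS = ["term_id", "name", "namespace", "k", "n", "K", "N", "p_raw", "p_adj"]

__all__ = [
    "select_foreground",
    "hypergeom_upper_tail",
    "adjust_pvalues",
    "go_enrichment",
    "DEFAULT_MR_THRESHOLD",
    "ADJUSTMENT_METHODS",
    "ENRICHMENT_COLUMNS",
]


def select_foreground(
    table: CoexpressionTable, mr_threshold: float = DEFAULT_MR_THRESHOLD
) -> set[str]:
    """Genes with MR strictly below the threshold, plus the reference."""
    if mr_threshold <= 0:
        raise ConfigError("the MR threshold must be positive")
    frame = table.frame
    below = frame.loc[~frame["is_self"] & (frame["mr"] < mr_threshold), "gene"]
    foreground = set(below)
    foreground |= set(frame.loc[frame["is_self"], "gene"])
    return foreground


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N and N >= 1):
        raise AnalysisError(
            f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(pvals: Sequence[float], method: str = "benjamini_hochberg") -> list[float]:
    """Multiple-testing adjustment preserving input order, clipped at 1.

    ``benjamini_hochberg`` is the step-up FDR procedure; ``holm`` the
    step-down familywise-error procedure.
    """
    if method not in ADJUSTMENT_METHODS:
        raise ConfigError(
            f"unknown adjustment method {method!r}; expected one of {', '.join(ADJUSTMENT_METHODS)}"
        )
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)) or not np.isfinite(arr).all():
        raise AnalysisError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(arr, method=ADJUSTMENT_METHODS[method])
    return [float(p) for p in np.minimum(adjusted, 1.0)]


def _assignments(
    genes: Iterable[str],
    go: AttributeMap,
    ontology: OntologyGraph | None,
    propagate: bool,
) -> dict[str, set[str]]:
    """Per-gene GO term sets: alt IDs resolved, obsolete terms removed,
    optionally propagated to all ancestors."""
    out: dict[str, set[str]] = {}
    for gene in genes:
        direct = go.get_set(gene)
        if not direct:
            continue
        terms: set[str] = set()
        for term in direct:
            if ontology is None:
                terms.add(term)
                continue
            resolved = ontology.resolve(term) or term
            if ontology.is_obsolete(resolved):
                continue
            terms.add(resolved)
            if propagate:
                terms |= {t for t in ontology.ancestors(resolved) if not ontology.is_obsolete(t)}
        if terms:
            out[gene] = terms
    return out


def go_enrichment(
    foreground: set[str],
    matrix: ExpressionMatrix,
    go: AttributeMap,
    ontology: OntologyGraph | None = None,
    method: str = "benjamini_hochberg",
    propagate: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment table over every term with k >= 1.

    The background universe N is the set of matrix genes with at least one
    (non-obsolete) GO assignment; all namespaces are tested and adjusted
    together.  Rows are sorted by adjusted p-value, then term ID.
    """
    if len(go) == 0:
        raise AnalysisError("the GO assignment map is empty")
    unknown = foreground - set(matrix.gene_ids)
    if unknown:
        raise AnalysisError(
            f"foreground gene(s) absent from the matrix: {', '.join(sorted(unknown))}"
        )
    background = _assignments(matrix.gene_ids, go, ontology, propagate)
    N = len(background)
    fg_annotated = {g: t for g, t in background.items() if g in foreground}
    n = len(fg_annotated)
    if n == 0:
        logger.warning("empty (or unannotated) foreground; returning an empty enrichment table")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    term_bg: dict[str, int] = {}
    for terms in background.values():
        for term in terms:
            term_bg[term] = term_bg.get(term, 0) + 1
    term_fg: dict[str, int] = {}
    for terms in fg_annotated.values():
        for term in terms:
            term_fg[term] = term_fg.get(term, 0) + 1

    records = []
    for term in sorted(term_fg):
        k, K = term_fg[term], term_bg[term]
        records.append(
            {
                "term_id": term,
                "name": ontology.name(term) if ontology else "",
                "namespace": ontology.namespace(term) if ontology else "",
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_raw": hypergeom_upper_tail(k, n, K, N),
            }
        )
    result = pd.DataFrame.from_records(records)
    result["p_adj"] = adjust_pvalues(result["p_raw"].tolist(), method)
    result = result.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(drop=True)
    return result[ENRICHMENT_COLUMNS]
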