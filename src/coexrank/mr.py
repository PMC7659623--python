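"""Pearson correlation profiles, directional ranks and Mutual Rank values.

The Mutual Rank (MR) between genes *a* and *b* is the geometric mean
``sqrt(r_ab * r_ba)`` of the two directional ranks: ``r_ab`` is the rank of
*b* among all genes ordered by descending Pearson correlation (PCC) to *a*,
and symmetrically for ``r_ba``.  Low MR means strong, reciprocal
coexpression; the minimum is 1 (each gene is the other's best correlate).

Computing the full genome-wide MR matrix is quadratic in the gene count, so
the targeted workflow instead takes the N genes with the highest PCC to a
reference (top 200 by default, hard-capped at 1,000) and computes MR only
for those candidates.  Crucially, the directional ranks are still taken over
the FULL gene universe, so each reported MR equals the value the exhaustive
all-pairs matrix would contain.

Ties in PCC receive average (fractional) ranks; genes whose expression has
zero variance have no defined PCC and are excluded from every profile and
rank universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._exceptions import AnalysisError, ConfigError
from .io import ExpressionMatrix

logger = logging.getLogger("coexrank")

MAX_CANDIDATES = 1000  # GUI-style hard cap on the candidate list
DEFAULT_TOP_N = 200

AGGREGATION_METHODS = ("average", "sum", "maximum", "minimum")

__all__ = [
    "CorrelationProfile",
    "MutualRankValue",
    "CoexpressionTable",
    "pcc",
    "correlation_profile",
    "rank_profile",
    "mutual_rank",
    "top_candidates",
    "targeted_mr_table",
    "pairwise_mr_table",
    "compound_reference",
    "MAX_CANDIDATES",
    "DEFAULT_TOP_N",
    "AGGREGATION_METHODS",
]


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    Returns ``nan`` (the undefined marker) when either vector has zero
    variance.  Vectors shorter than 3 samples are rejected: a correlation
    over 2 points is always +/-1 and carries no signal.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise AnalysisError(f"length mismatch: {xv.shape} vs {yv.shape}")
    if xv.size < 3:
        raise AnalysisError("correlation requires at least 3 samples")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise AnalysisError("correlation inputs must be finite")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _standardized_rows(matrix: ExpressionMatrix) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Mean-centered unit-norm rows; zero-variance genes are dropped once.

    Returns (Z, kept gene index, dropped gene index); ``Z @ Z.T`` is then the
    PCC matrix over the kept universe.
    """
    if matrix.n_samples < 3:
        raise AnalysisError("expression matrix needs at least 3 samples for correlation")
    values = matrix.values
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    keep = norms > 0.0
    dropped = matrix.data.index[~keep]
    if len(dropped):
        logger.warning(
            "excluding %d zero-variance gene(s) from the rank universe", len(dropped)
        )
    Z = centered[keep] / norms[keep, None]
    return Z, matrix.data.index[keep], dropped


@dataclass
class CorrelationProfile:
    """PCC of one source gene against every other gene in the universe.

    ``correlations`` is indexed by gene ID (the source itself excluded);
    zero-variance partners carry ``nan`` as an explicit undefined marker.
    """

    source_gene: str
    correlations: pd.Series

    def __post_init__(self) -> None:
        if self.source_gene in self.correlations.index:
            raise AnalysisError("a correlation profile must not contain its own source gene")


def correlation_profile(matrix: ExpressionMatrix, gene: str) -> CorrelationProfile:
    """Profile of ``gene`` against the full matrix (self excluded)."""
    matrix.expression(gene)  # raises if absent
    Z, kept, dropped = _standardized_rows(matrix)
    if gene not in kept:
        raise AnalysisError(f"reference gene {gene!r} has zero expression variance")
    z_ref = Z[kept.get_loc(gene)]
    corr = pd.Series(np.clip(Z @ z_ref, -1.0, 1.0), index=kept)
    corr = corr.drop(gene)
    undefined = pd.Series(np.nan, index=dropped)
    return CorrelationProfile(gene, pd.concat([corr, undefined]))


def rank_profile(profile: CorrelationProfile) -> pd.Series:
    """Descending-PCC ranks (1 = best correlate); ties get average ranks and
    undefined correlations receive no rank."""
    defined = profile.correlations.dropna()
    if defined.empty:
        raise AnalysisError(f"profile of {profile.source_gene!r} has no defined correlations")
    ranks = rankdata(-defined.to_numpy(), method="average")
    return pd.Series(ranks, index=defined.index)


# ---------------------------------------------------------------------------
# Mutual rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutualRankValue:
    """One gene pair's directional ranks and their geometric mean."""

    gene_a: str
    gene_b: str
    rank_ab: float
    rank_ba: float

    @property
    def mr(self) -> float:
        return sqrt(self.rank_ab * self.rank_ba)


def mutual_rank(matrix: ExpressionMatrix, gene_a: str, gene_b: str) -> MutualRankValue:
    """MR of a single pair; both directional ranks are taken over the full
    gene universe.  Symmetric in its arguments up to field naming."""
    if gene_a == gene_b:
        raise AnalysisError("mutual rank of a gene with itself is undefined")
    rank_ab = rank_profile(correlation_profile(matrix, gene_a))
    rank_ba = rank_profile(correlation_profile(matrix, gene_b))
    for source, ranks, other in ((gene_a, rank_ab, gene_b), (gene_b, rank_ba, gene_a)):
        if other not in ranks.index:
            raise AnalysisError(f"gene {other!r} has zero expression variance")
    return MutualRankValue(gene_a, gene_b, float(rank_ab[gene_b]), float(rank_ba[gene_a]))


# ---------------------------------------------------------------------------
# Coexpression table
# ---------------------------------------------------------------------------

_CORE_COLUMNS = ["gene", "symbol", "mr", "pcc", "rank_ab", "rank_ba"]
_SELF_MARKER = "self"


@dataclass
class CoexpressionTable:
    """Per-candidate MR records for one reference (or compound reference).

    ``frame`` columns: gene, pcc, rank_ab, rank_ba, mr, is_self, plus any
    annotation/category/fold-change columns added by the integration step.
    Targeted tables are sorted by ascending MR (ties broken by descending
    PCC, then gene ID); reference-set tables preserve input order.  The
    reference's own row carries ``is_self=True`` and is serialized with the
    literal marker ``self`` in place of an MR number.
    """

    reference: str
    frame: pd.DataFrame
    extra_columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return int((~self.frame["is_self"]).sum())

    @property
    def candidate_genes(self) -> list[str]:
        return list(self.frame.loc[~self.frame["is_self"], "gene"])

    @property
    def genes(self) -> list[str]:
        return list(self.frame["gene"])

    def sorted(self) -> "CoexpressionTable":
        """Ascending MR, ties by descending PCC then gene ID; self row first."""
        frame = self.frame.copy()
        frame["_neg_pcc"] = -frame["pcc"]
        frame = frame.sort_values(
            ["is_self", "mr", "_neg_pcc", "gene"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).drop(columns="_neg_pcc")
        return CoexpressionTable(self.reference, frame.reset_index(drop=True), list(self.extra_columns))

    def to_frame(self) -> pd.DataFrame:
        """Serializable view with the stable public column order."""
        out = self.frame.copy()
        if "symbol" not in out.columns:
            out["symbol"] = ""
        out["mr"] = [
            _SELF_MARKER if s else _format_number(m)
            for s, m in zip(out["is_self"], out["mr"])
        ]
        for col in ("pcc", "rank_ab", "rank_ba"):
            out[col] = [
                "" if s else _format_number(v) for s, v in zip(out["is_self"], out[col])
            ]
        ordered = _CORE_COLUMNS + [c for c in self.extra_columns if c != "symbol"]
        return out[ordered]

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CoexpressionTable":
        """Re-load a table previously written by :meth:`write`."""
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        frame = pd.DataFrame({"gene": raw["gene"]})
        frame["is_self"] = raw["mr"] == _SELF_MARKER
        for col in ("mr", "pcc", "rank_ab", "rank_ba"):
            frame[col] = pd.to_numeric(raw[col], errors="coerce")
        extra = [c for c in raw.columns if c not in ("gene", "mr", "pcc", "rank_ab", "rank_ba")]
        for col in extra:
            frame[col] = raw[col]
        selfs = frame.loc[frame["is_self"], "gene"]
        reference = selfs.iloc[0] if len(selfs) else ""
        return cls(reference, frame, [c for c in extra if c != "symbol"])


def _format_number(value: float) -> str:
    return f"{value:.10g}"


def _self_row(gene: str) -> dict:
    return {
        "gene": gene,
        "pcc": np.nan,
        "rank_ab": np.nan,
        "rank_ba": np.nan,
        "mr": np.nan,
        "is_self": True,
    }


# ---------------------------------------------------------------------------
# Targeted workflow
# ---------------------------------------------------------------------------


def _clamp_n(n: int) -> int:
    if n < 1:
        raise ConfigError("candidate count must be at least 1")
    if n > MAX_CANDIDATES:
        logger.warning(
            "requested %d candidates; clamping to the maximum of %d", n, MAX_CANDIDATES
        )
        return MAX_CANDIDATES
    return n


def top_candidates(matrix: ExpressionMatrix, reference: str, n: int = DEFAULT_TOP_N) -> pd.Series:
    """The ``n`` genes with the highest signed PCC to the reference.

    Returns a PCC series ordered descending (ties broken by gene ID for
    determinism).  ``n`` is clamped at 1,000 with a warning; if fewer
    rankable genes exist, all are returned.  Strong *negative* correlates are
    deliberately never candidates.
    """
    n = _clamp_n(n)
    profile = correlation_profile(matrix, reference).correlations.dropna()
    order = sorted(profile.index, key=lambda g: (-profile[g], g))
    return profile[order[:n]]


def _rank_of(row: np.ndarray, universe_mask: np.ndarray, target_pos: int) -> float:
    """Average-tie rank of ``target_pos`` within ``row`` restricted to the mask."""
    values = row[universe_mask]
    ranks = rankdata(-values, method="average")
    # position of target within the masked universe
    idx = int(universe_mask[:target_pos].sum())
    return float(ranks[idx])


def targeted_mr_table(
    matrix: ExpressionMatrix, reference: str, n: int = DEFAULT_TOP_N
) -> CoexpressionTable:
    """MR table for the top-``n`` PCC candidates of a single reference gene.

    Every directional rank is computed against the full (nonzero-variance)
    gene universe, so the reported MRs coincide with the exhaustive all-pairs
    values.  Rows are sorted by ascending MR with the reference's ``self``
    row first.
    """
    matrix.expression(reference)
    n = _clamp_n(n)
    Z, kept, _ = _standardized_rows(matrix)
    if reference not in kept:
        raise AnalysisError(f"reference gene {reference!r} has zero expression variance")
    ref_pos = kept.get_loc(reference)
    z_ref = Z[ref_pos]
    ref_corr = np.clip(Z @ z_ref, -1.0, 1.0)

    not_self = np.ones(len(kept), dtype=bool)
    not_self[ref_pos] = False
    ref_ranks = np.full(len(kept), np.nan)
    ref_ranks[not_self] = rankdata(-ref_corr[not_self], method="average")

    order = sorted(
        (g for g in kept if g != reference),
        key=lambda g: (-ref_corr[kept.get_loc(g)], g),
    )
    candidates = order[:n]

    rows = [_self_row(reference)]
    for gene in candidates:
        pos = kept.get_loc(gene)
        cand_corr = np.clip(Z @ Z[pos], -1.0, 1.0)
        mask = np.ones(len(kept), dtype=bool)
        mask[pos] = False
        rank_ba = _rank_of(cand_corr, mask, ref_pos)
        rank_ab = float(ref_ranks[pos])
        rows.append(
            {
                "gene": gene,
                "pcc": float(ref_corr[pos]),
                "rank_ab": rank_ab,
                "rank_ba": rank_ba,
                "mr": sqrt(rank_ab * rank_ba),
                "is_self": False,
            }
        )
    table = CoexpressionTable(reference, pd.DataFrame(rows))
    return table.sorted()


# ---------------------------------------------------------------------------
# Reference gene-set workflow
# ---------------------------------------------------------------------------


def pairwise_mr_table(
    matrix: ExpressionMatrix, genes: Sequence[str]
) -> tuple[CoexpressionTable, pd.DataFrame]:
    """All-pairs MR among a reference gene set.

    Genes absent from the matrix (or with zero variance) are dropped with a
    warning, mirroring pathway members missing from an expression atlas.
    Returns the coexpression table keyed to the FIRST retained gene (rows in
    input order, self row first) and the full symmetric MR matrix with a
    ``NaN`` diagonal.
    """
    requested = list(dict.fromkeys(genes))  # preserve order, drop duplicates
    Z, kept, _ = _standardized_rows(matrix)
    retained = [g for g in requested if g in kept]
    dropped = [g for g in requested if g not in kept]
    if dropped:
        logger.warning("dropped gene(s) absent or unrankable: %s", ", ".join(dropped))
    if len(retained) < 2:
        raise AnalysisError(
            "fewer than 2 reference genes retained"
            + (f" (dropped: {', '.join(dropped)})" if dropped else "")
        )

    positions = [kept.get_loc(g) for g in retained]
    k = len(retained)
    mr = np.full((k, k), np.nan)
    directional = np.full((k, k), np.nan)  # directional[i, j] = rank of gene j in gene i's profile
    pccs = np.full((k, k), np.nan)
    for i, pos in enumerate(positions):
        corr = np.clip(Z @ Z[pos], -1.0, 1.0)
        mask = np.ones(len(kept), dtype=bool)
        mask[pos] = False
        ranks = np.full(len(kept), np.nan)
        ranks[mask] = rankdata(-corr[mask], method="average")
        for j, other_pos in enumerate(positions):
            if i == j:
                continue
            directional[i, j] = ranks[other_pos]
            pccs[i, j] = corr[other_pos]
    for i in range(k):
        for j in range(i + 1, k):
            mr[i, j] = mr[j, i] = sqrt(directional[i, j] * directional[j, i])

    mr_matrix = pd.DataFrame(mr, index=retained, columns=retained)

    first = retained[0]
    rows = []
    for j, gene in enumerate(retained):
        if gene == first:
            rows.append(_self_row(first))
            continue
        rows.append(
            {
                "gene": gene,
                "pcc": float(pccs[0, j]),
                "rank_ab": float(directional[0, j]),
                "rank_ba": float(directional[j, 0]),
                "mr": float(mr[0, j]),
                "is_self": False,
            }
        )
    table = CoexpressionTable(first, pd.DataFrame(rows))
    return table, mr_matrix


# ---------------------------------------------------------------------------
# Compound reference gene
# ---------------------------------------------------------------------------

_AGGREGATORS = {
    "average": np.mean,
    "sum": np.sum,
    "maximum": np.max,
    "minimum": np.min,
}


def compound_reference(
    matrix: ExpressionMatrix, genes: Sequence[str], method: str, label: str
) -> ExpressionMatrix:
    """Append a synthetic per-sample aggregate of a gene set to the matrix.

    The compound row then serves as the reference of a targeted run and
    participates in every gene's rank universe.  Aggregates with zero
    variance are rejected before any MR is computed.
    """
    if method not in _AGGREGATORS:
        raise ConfigError(
            f"unknown aggregation method {method!r}; "
            f"expected one of {', '.join(AGGREGATION_METHODS)}"
        )
    requested = list(dict.fromkeys(genes))
    present = [g for g in requested if g in matrix]
    missing = [g for g in requested if g not in matrix]
    if missing:
        logger.warning("compound reference drops absent gene(s): %s", ", ".join(missing))
    if len(present) < 2:
        raise AnalysisError("a compound reference needs at least 2 genes present in the matrix")
    block = matrix.data.loc[present].to_numpy()
    aggregate = _AGGREGATORS[method](block, axis=0)
    if np.ptp(aggregate) == 0.0:
        raise AnalysisError(
            f"compound reference {label!r} ({method}) has zero variance across samples"
        )
    return matrix.with_row(label, aggregate)
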