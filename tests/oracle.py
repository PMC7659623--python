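"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own computation paths: the MR oracle
builds the complete G x G correlation matrix with ``np.corrcoef`` and ranks
every full row, and the hypergeometric oracle sums the exact tail with
rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def brute_force_mr_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Full MR matrix over every nonzero-variance gene of a genes x samples
    frame: complete PCC matrix, average-tie descending ranks per row (self
    excluded), then sqrt(r_ab * r_ba)."""
    values = data.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    genes = list(data.index[keep])
    corr = np.corrcoef(values[keep])
    g = len(genes)
    ranks = np.full((g, g), np.nan)
    for i in range(g):
        mask = np.ones(g, dtype=bool)
        mask[i] = False
        ranks[i, mask] = rankdata(-corr[i, mask], method="average")
    mr = np.sqrt(ranks * ranks.T)
    return pd.DataFrame(mr, index=genes, columns=genes)


def exact_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact rational summation of the hypergeometric pmf."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(acc)
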