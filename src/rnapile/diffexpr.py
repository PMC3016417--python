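"""Two-library differential expression by G-test with BH FDR control.

Each gene is tested on a 2x2 contingency table {gene, rest-of-library} x
{condition 0, condition 1} with cells (C0, C1, N0-C0, N1-C1); the G statistic
is the likelihood-ratio statistic 2 * sum O ln(O/E) with expectations from
the table margins (zero cells contribute zero), referred to chi-square with
one degree of freedom.  This is the classic test for count data from two
unreplicated sequencing libraries; without biological replicates it measures
sampling (not biological) variability.  No Williams or continuity correction
is applied by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

__all__ = ["g_test", "g_test_many", "bh_fdr", "expression_ratio", "de_table"]


def g_test_many(C0, C1, N0, N1, williams: bool = False):
    """Vectorised G-test; returns (G, p) arrays.

    ``williams=True`` applies the Williams correction G/q with
    q = 1 + (n/r0 + n/r1 - 1)(n/c0 + n/c1 - 1) / (6 n) for a 2x2 table.
    """
    C0 = np.asarray(C0, dtype=float)
    C1 = np.asarray(C1, dtype=float)
    N0 = np.asarray(N0, dtype=float)
    N1 = np.asarray(N1, dtype=float)
    if (N0 < 1).any() or (N1 < 1).any():
        raise ValueError("library sizes must be >= 1")
    if (C0 < 0).any() or (C1 < 0).any() or (C0 > N0).any() or (C1 > N1).any():
        raise ValueError("counts must satisfy 0 <= C_i <= N_i")
    R0, R1 = C0 + C1, (N0 - C0) + (N1 - C1)   # row margins (gene, rest)
    n = N0 + N1
    # standard expected-frequency form: E = row * col / n, then cell-wise
    # 2 * sum O ln(O/E); numerically stable at large N (each term is O(1) in
    # the deviation) and xlogy sends zero cells to zero
    with np.errstate(divide="ignore", invalid="ignore"):
        G = 2.0 * (xlogy(C0, C0 / (R0 * N0 / n))
                   + xlogy(C1, C1 / (R0 * N1 / n))
                   + xlogy(N0 - C0, (N0 - C0) / (R1 * N0 / n))
                   + xlogy(N1 - C1, (N1 - C1) / (R1 * N1 / n)))
    G = np.maximum(np.nan_to_num(G, nan=0.0), 0.0)
    if williams:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = 1.0 + ((n / np.maximum(R0, 1) + n / np.maximum(R1, 1) - 1.0)
                       * (n / N0 + n / N1 - 1.0)) / (6.0 * n)
        G = G / q
    p = stats.chi2.sf(G, df=1)
    return G, p


def g_test(C0: int, C1: int, N0: int, N1: int,
           williams: bool = False) -> tuple[float, float]:
    """Scalar G-test of one gene's counts between two libraries."""
    G, p = g_test_many([C0], [C1], [N0], [N1], williams=williams)
    return float(G[0]), float(p[0])


def bh_fdr(pvalues, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q-values, rejected mask).

    q_(i) = min over j >= i of m * p_(j) / j, capped at 1; the rejection set
    is the largest k with p_(k) <= k * alpha / m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def expression_ratio(rpkm_0: float, rpkm_1: float) -> float | None:
    """Reported fold change RPKM_1 / RPKM_0, one decimal; None (rendered "-")
    when the denominator is zero."""
    if rpkm_0 < 0 or rpkm_1 < 0:
        raise ValueError("RPKM values must be non-negative")
    if rpkm_0 == 0:
        return None
    return round(rpkm_1 / rpkm_0, 1)


def de_table(expr: pd.DataFrame, alpha: float = 0.01,
             williams: bool = False) -> pd.DataFrame:
    """Differential-expression table from an expression table.

    ``expr`` needs columns C_0, C_1, N_0, N_1, RPKM_0, RPKM_1 (one row per
    gene).  Genes with C_0 = C_1 = 0 are excluded from testing and from the
    number of hypotheses m; their q is NaN and they are never significant.
    """
    df = expr.copy()
    tested = (df["C_0"] + df["C_1"]) > 0
    G = np.full(len(df), np.nan)
    p = np.full(len(df), np.nan)
    if tested.any():
        G_t, p_t = g_test_many(df.loc[tested, "C_0"], df.loc[tested, "C_1"],
                               df.loc[tested, "N_0"], df.loc[tested, "N_1"],
                               williams=williams)
        G[tested.values] = G_t
        p[tested.values] = p_t
    q = np.full(len(df), np.nan)
    sig = np.zeros(len(df), dtype=bool)
    if tested.any():
        q_t, rej_t = bh_fdr(p[tested.values], alpha=alpha)
        q[tested.values] = q_t
        sig[tested.values] = rej_t
    df["G"] = G
    df["p"] = p
    df["q"] = q
    df["significant"] = sig
    df["ratio"] = [expression_ratio(r0, r1)
                   for r0, r1 in zip(df["RPKM_0"], df["RPKM_1"])]
    rel1 = df["C_1"] / df["N_1"]
    rel0 = df["C_0"] / df["N_0"]
    df["direction"] = np.where(rel1 >= rel0, "up", "down")
    return df
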