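"""Horse-race expression/protein dominance between homoeologous gene copies.

In each tissue, a pair's copy "wins the horse race" when its expression is at
least ``fold`` times (default two-fold) its homoeolog's, provided the winner
itself clears a minimal-expression floor (without the floor, a (0, 0) pair
would be "dominant" on both sides).  Percentages of pairs won by each
subgenome are summarised per tissue and per chromatin-environment category;
the same classifier serves FPKM and protein-abundance matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TestResult, paired_t

MAIZE1 = "maize1_dominant"
MAIZE2 = "maize2_dominant"
NO_CALL = "no_call"


def classify_pair(
    value1: float, value2: float, fold: float = 2.0, min_expr: float = 1.0
) -> str:
    """Dominance call for one pair in one tissue (ties at fold* count as dominant)."""
    if value1 < 0 or value2 < 0:
        raise ValueError("expression values must be non-negative")
    if value1 >= fold * value2 and value1 >= min_expr:
        return MAIZE1
    if value2 >= fold * value1 and value2 >= min_expr:
        return MAIZE2
    return NO_CALL


def classify_matrix(
    v1: np.ndarray, v2: np.ndarray, fold: float = 2.0, min_expr: float = 1.0
) -> np.ndarray:
    """Vectorised :func:`classify_pair` (any shape; returns call strings)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if (v1 < 0).any() or (v2 < 0).any():
        raise ValueError("expression values must be non-negative")
    win1 = (v1 >= fold * v2) & (v1 >= min_expr)
    win2 = (v2 >= fold * v1) & (v2 >= min_expr)
    out = np.full(v1.shape, NO_CALL, dtype=object)
    out[win1] = MAIZE1
    out[win2] = MAIZE2
    return out


def dominance_summary(
    matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    fold: float = 2.0,
    min_expr: float = 1.0,
    by_category: bool = True,
) -> pd.DataFrame:
    """Per-tissue dominance percentages for each pair category.

    ``matrix`` is genes x tissues; ``pairs`` needs maize1_gene/maize2_gene and
    (when ``by_category``) a ``category`` column.  Percentages use all pairs
    of the category as denominator, so pct_maize1 + pct_maize2 + pct_no_call
    = 100 per tissue.  The headline numbers are the per-tissue percentages
    averaged across tissues (``mean`` rows, tissue = "__mean__").
    """
    missing = [
        g
        for col in ("maize1_gene", "maize2_gene")
        for g in pairs[col]
        if g not in matrix.index
    ]
    if missing:
        raise KeyError(f"matrix does not cover genes: {missing[:5]}...")
    v1 = matrix.loc[pairs["maize1_gene"]].to_numpy(dtype=float)
    v2 = matrix.loc[pairs["maize2_gene"]].to_numpy(dtype=float)
    calls = classify_matrix(v1, v2, fold=fold, min_expr=min_expr)

    groups = (
        pairs.groupby("category").indices.items()
        if by_category
        else [("all", np.arange(len(pairs)))]
    )
    rows = []
    for category, idx in groups:
        sub = calls[np.asarray(idx)]
        n = sub.shape[0]
        if n == 0:
            continue
        p1 = 100.0 * (sub == MAIZE1).sum(axis=0) / n
        p2 = 100.0 * (sub == MAIZE2).sum(axis=0) / n
        for j, tissue in enumerate(matrix.columns):
            rows.append(
                {
                    "category": category,
                    "tissue": tissue,
                    "n_pairs": n,
                    "pct_maize1": p1[j],
                    "pct_maize2": p2[j],
                    "pct_no_call": 100.0 - p1[j] - p2[j],
                }
            )
        rows.append(
            {
                "category": category,
                "tissue": "__mean__",
                "n_pairs": n,
                "pct_maize1": p1.mean(),
                "pct_maize2": p2.mean(),
                "pct_no_call": 100.0 - p1.mean() - p2.mean(),
            }
        )
    return pd.DataFrame(rows)


def dominance_calls(
    matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    fold: float = 2.0,
    min_expr: float = 1.0,
) -> pd.DataFrame:
    """Long-format calls: one row per pair x tissue."""
    v1 = matrix.loc[pairs["maize1_gene"]].to_numpy(dtype=float)
    v2 = matrix.loc[pairs["maize2_gene"]].to_numpy(dtype=float)
    calls = classify_matrix(v1, v2, fold=fold, min_expr=min_expr)
    long = pd.DataFrame(calls, columns=matrix.columns)
    long.insert(0, "maize1_gene", pairs["maize1_gene"].to_numpy())
    long.insert(1, "maize2_gene", pairs["maize2_gene"].to_numpy())
    return long.melt(
        id_vars=["maize1_gene", "maize2_gene"], var_name="tissue", value_name="call"
    )


def mean_expression_compare(
    matrix: pd.DataFrame, pairs: pd.DataFrame, log_transform: bool = False
) -> dict:
    """Paired comparison of tissue-averaged expression between the subgenomes.

    Each pair contributes its per-copy mean across tissues; a paired t-test
    runs across pairs (optionally on log2(x+1) values).  Returns means,
    difference and the test result.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs for a paired comparison")
    v1 = matrix.loc[pairs["maize1_gene"]].to_numpy(dtype=float).mean(axis=1)
    v2 = matrix.loc[pairs["maize2_gene"]].to_numpy(dtype=float).mean(axis=1)
    if log_transform:
        v1 = np.log2(v1 + 1.0)
        v2 = np.log2(v2 + 1.0)
    res: TestResult = paired_t(v1, v2)
    return {
        "n_pairs": len(pairs),
        "mean_maize1": float(v1.mean()),
        "mean_maize2": float(v2.mean()),
        "difference": float(v1.mean() - v2.mean()),
        "t": res.statistic,
        "df": res.df,
        "pvalue": res.pvalue,
    }
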