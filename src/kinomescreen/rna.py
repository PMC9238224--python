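"""Kinase activity vs gene expression correlation, per organoid line.

mRNA abundance is a poor proxy for kinase enzymatic activity; this module
quantifies that relationship. Expression is consumed as an
already-normalized (TMM-scale) genes x samples matrix; for each organoid
line, activity and expression are paired across the shared kinase symbols
and correlated, with Benjamini-Hochberg adjustment across lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["read_expression", "align_kinases", "correlate_per_line"]


class ExpressionError(ValueError):
    pass


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples normalized-count TSV; validates and case-normalizes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    df.index.name = "gene"
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ExpressionError(f"duplicate gene rows: {dups}")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ExpressionError("expression matrix contains negative values")
    return df.astype(float)


def align_kinases(
    activity: pd.DataFrame, expression: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Inner-join kinase activity (samples x kinases) with expression (genes x samples).

    Returns the two matrices restricted to shared kinase symbols and shared
    samples, plus a report of unmatched symbols on both sides. Requires at
    least 3 shared kinases.
    """
    if expression.index.duplicated().any():
        dups = sorted(set(expression.index[expression.index.duplicated()]))
        raise ExpressionError(f"duplicate gene rows: {dups}")
    act_kin = pd.Index([str(k).strip().upper() for k in activity.columns])
    activity = activity.set_axis(act_kin, axis=1)
    expr_kin = pd.Index([str(g).strip().upper() for g in expression.index])
    expression = expression.set_axis(expr_kin, axis=0)
    shared = sorted(set(act_kin) & set(expr_kin))
    if len(shared) < 3:
        raise ExpressionError(
            f"only {len(shared)} kinase symbol(s) shared between activity and expression"
        )
    samples = [s for s in activity.index if s in expression.columns]
    if not samples:
        raise ExpressionError("no shared samples between activity and expression")
    report = {
        "activity_only": sorted(set(act_kin) - set(expr_kin)),
        "expression_only": sorted(set(expr_kin) - set(act_kin)),
    }
    return activity.loc[samples, shared], expression.loc[shared, samples], report


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def correlate_per_line(
    activity: pd.DataFrame,
    expression: pd.DataFrame,
    method: str = "pearson",
    mode: str = "per_line",
) -> pd.DataFrame:
    """Correlate kinase activity with gene expression.

    ``mode="per_line"`` (default) computes, for each sample line, the
    correlation across the shared kinases — one scatter per organoid line.
    ``mode="per_gene"`` correlates each kinase gene across samples instead
    (underpowered for small panels; provided for completeness).

    Returns a table with r, r2 (= r**2 from the least-squares line), raw and
    Benjamini-Hochberg adjusted p-values, and the pair count n. Zero-variance
    vectors are reported as NA with a reason instead of failing.
    """
    from .biomarker import benjamini_hochberg

    act, expr, _ = align_kinases(activity, expression)
    rows = []
    if mode == "per_line":
        units = [(s, act.loc[s].to_numpy(), expr[s].to_numpy()) for s in act.index]
        unit_col = "sample_id"
    elif mode == "per_gene":
        units = [(k, act[k].to_numpy(), expr.loc[k].to_numpy()) for k in act.columns]
        unit_col = "gene"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for name, x, y in units:
        if len(x) < 3:
            raise ExpressionError(f"fewer than 3 pairs for {name!r}")
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((name, np.nan, np.nan, np.nan, len(x), "zero variance"))
            continue
        r, p = _corr(x, y, method)
        rows.append((name, r, r * r, p, len(x), ""))
    out = pd.DataFrame(rows, columns=[unit_col, "r", "r2", "p", "n", "note"])
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out[[unit_col, "r", "r2", "p", "p_adj", "n", "note"]]
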