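"""Kinase-activity-as-drug-sensitivity-biomarker correlation screen.

For each drug, the per-peptide phosphorylation signal (AUC) is correlated
with the drug response (1 - relative viability) across the organoid lines
carrying both assays. With panels this small (n = 5..8 lines) asymptotic
Spearman p-values are unreliable, so two-sided p-values are computed by
exact enumeration of all n! rank permutations for n <= 8. Per drug, the
peptide family is Benjamini-Hochberg adjusted and significant peptides get
an ordinary-least-squares R^2 against the response.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpearmanResult",
    "spearman_exact",
    "benjamini_hochberg",
    "screen_drug_peptides",
]

EXACT_MAX_N = 8
_EPS = 1e-12


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    note: str = ""


@lru_cache(maxsize=8)
def _perm_index(n: int) -> np.ndarray:
    """All n! permutations of range(n), as an index matrix."""
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _zranks(x: np.ndarray) -> np.ndarray:
    """Population-standardized average ranks; Pearson on these is Spearman rho."""
    r = stats.rankdata(x)
    sd = r.std()
    if sd == 0:
        raise ValueError("constant vector")
    return (r - r.mean()) / sd


def spearman_exact(x, y, exact_max_n: int = EXACT_MAX_N) -> SpearmanResult:
    """Spearman rho with an exact two-sided permutation p-value for small n.

    For n <= ``exact_max_n`` the p-value counts, over all n! permutations of
    one vector's ranks, those with |rho| at least as large as observed
    (ties in the data are handled by average ranks, conditioning on the tie
    pattern). Larger n falls back to the t-distribution approximation.
    Constant input yields NA with a reason rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    try:
        zx, zy = _zranks(x), _zranks(y)
    except ValueError:
        return SpearmanResult(np.nan, np.nan, "constant vector")
    rho = float(zx @ zy / n)
    if n <= exact_max_n:
        null = (_zranks_perms(tuple(np.round(zy, 12))) @ zx) / n
        p = float(np.mean(np.abs(null) >= abs(rho) - _EPS))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return SpearmanResult(rho, p, "")


@lru_cache(maxsize=16)
def _zranks_perms(zy_rounded: tuple[float, ...]) -> np.ndarray:
    zy = np.asarray(zy_rounded)
    return zy[_perm_index(len(zy))]


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Monotone and capped at 1; NaN entries are passed through and excluded
    from the family size. Values outside [0, 1] are an error.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def screen_drug_peptides(
    responses: pd.DataFrame,
    activity: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "per_drug",
    method_exact_max_n: int = EXACT_MAX_N,
) -> pd.DataFrame:
    """Correlate every (drug, peptide) pair across shared samples.

    Parameters
    ----------
    responses : drugs x samples matrix of drug response in [0, 1]
    activity : samples x peptides AUC matrix
    alpha : significance level on the adjusted p
    family : "per_drug" (default; BH across peptides within each drug,
        mirroring per-drug significant-peptide reporting) or "global"
        (one BH family over the whole drug x peptide grid)

    Returns a tidy table: drug, peptide_id, rho, p, p_adj, significant,
    r2 (OLS of response on AUC), n, note.
    """
    if family not in ("per_drug", "global"):
        raise ValueError(f"unknown FDR family {family!r}")
    shared = [s for s in activity.index if s in responses.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sample(s) between assays")
    act = activity.loc[shared]
    n = len(shared)
    x_cols = act.to_numpy(dtype=float)
    peptides = list(act.columns)

    records = []
    for drug in responses.index:
        y = responses.loc[drug, shared].to_numpy(dtype=float)
        try:
            zy = _zranks(y)
        except ValueError:
            for pep in peptides:
                records.append((drug, pep, np.nan, np.nan, np.nan, "constant response"))
            continue
        exact = n <= method_exact_max_n
        null = (_zranks_perms(tuple(np.round(zy, 12))) if exact else None)
        for j, pep in enumerate(peptides):
            xj = x_cols[:, j]
            if np.std(stats.rankdata(xj)) == 0:
                records.append((drug, pep, np.nan, np.nan, np.nan, "constant peptide"))
                continue
            zx = _zranks(xj)
            rho = float(zx @ zy / n)
            if exact:
                p = float(np.mean(np.abs(null @ zx / n) >= abs(rho) - _EPS))
            else:
                p = float(stats.spearmanr(xj, y).pvalue)
            r = np.corrcoef(xj, y)[0, 1]
            records.append((drug, pep, rho, p, float(r * r), ""))
    out = pd.DataFrame(
        records, columns=["drug", "peptide_id", "rho", "p", "r2", "note"]
    )
    out["n"] = n
    if family == "per_drug":
        out["p_adj"] = np.nan
        for drug in out["drug"].unique():
            mask = out["drug"] == drug
            out.loc[mask, "p_adj"] = benjamini_hochberg(out.loc[mask, "p"].to_numpy())
    else:
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out[
        ["drug", "peptide_id", "rho", "p", "p_adj", "significant", "r2", "n", "note"]
    ]
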