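"""Peptide -> upstream-kinase annotation and kinase-level activity scores.

Each array peptide may be phosphorylated by several kinases and each kinase
may act on several peptides (many-to-many). Peptides with no curated
upstream kinase ("orphans") stay in the peptide-level matrix but never
contribute to kinase-level aggregation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationError",
    "read_annotation",
    "kinase_activity",
    "zscore_rows",
]


class AnnotationError(ValueError):
    pass


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a (peptide_id, kinase[, site]) TSV into a validated map.

    Kinase symbols are upper-cased and trimmed; duplicate (peptide, kinase)
    pairs are collapsed with a warning; empty kinase fields are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "peptide_id" not in df.columns or "kinase" not in df.columns:
        raise AnnotationError("annotation needs columns: peptide_id, kinase[, site]")
    if "site" not in df.columns:
        df["site"] = ""
    df = df[["peptide_id", "kinase", "site"]].copy()
    df["kinase"] = df["kinase"].astype(str).str.strip().str.upper()
    if (df["kinase"].isin(("", "NAN")) | df["kinase"].isna()).any():
        raise AnnotationError("annotation contains empty kinase symbols")
    n0 = len(df)
    df = df.drop_duplicates(subset=["peptide_id", "kinase"]).reset_index(drop=True)
    if len(df) < n0:
        warnings.warn(f"dropped {n0 - len(df)} duplicate (peptide, kinase) pairs", stacklevel=2)
    return df


def kinase_activity(
    activity: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str = "mean",
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate peptide AUC to upstream-kinase activity per sample.

    Parameters
    ----------
    activity : samples x peptides matrix (strictly positive AUC)
    annotation : (peptide_id, kinase) map; peptides absent from `activity`
        are ignored, kinases with no surviving peptide are excluded
    method : "mean" (default) or "median" over the kinase's member peptides

    Returns
    -------
    (kinase_matrix, support) : samples x kinases matrix and the per-kinase
        member-peptide count it was computed from.
    """
    if method not in ("mean", "median"):
        raise AnnotationError(f"unknown aggregation method {method!r}")
    present = annotation[annotation["peptide_id"].isin(activity.columns)]
    groups = present.groupby("kinase")["peptide_id"].apply(list)
    cols, support = {}, {}
    for kin in sorted(groups.index):
        peps = groups[kin]
        block = activity[peps]
        cols[kin] = block.mean(axis=1) if method == "mean" else block.median(axis=1)
        support[kin] = len(peps)
    if not cols:
        raise AnnotationError("no annotated kinase has any peptide in the activity matrix")
    out = pd.DataFrame(cols, index=activity.index)
    return out, pd.Series(support, name="n_peptides").sort_index()


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each feature (column) across samples, sample SD (ddof=1).

    Constant features are set to all-zero and returned in the flag list.
    Requires at least two samples.
    """
    if matrix.shape[0] < 2:
        raise AnnotationError("z-scoring requires at least 2 samples")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    sd_safe = sd.replace(0.0, np.nan)
    z = matrix.sub(mean, axis=1).div(sd_safe, axis=1)
    z[constant] = 0.0
    return z, constant
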