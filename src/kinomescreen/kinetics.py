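"""Kinetic-signal preprocessing: from raw Lux time series to AUC activity.

The processing contract, in order:

1. drop the internal positive-control peptide;
2. estimate initial-phase Vmax per replicate, clamp negatives to zero and
   drop peptides whose clamped average is zero (dead substrates);
3. integrate the replicate-averaged signal over the 640-1840 s window
   (trapezoid, with linear interpolation onto the window edges) to get one
   AUC per sample x peptide;
4. replace nonpositive AUC values with the sample's smallest positive AUC;
5. normalize each sample by its CD79A_181_193 control-peptide AUC and drop
   the control column.

Each step is an independently callable function; :func:`preprocess` chains
them and returns the activity matrix plus a processing report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import INTERNAL_CONTROL_ID, NORMALIZATION_CONTROL_ID

__all__ = [
    "InputError",
    "PipelineError",
    "VmaxMatrix",
    "read_signal_table",
    "exclude_internal_control",
    "estimate_vmax",
    "clamp_and_filter_vmax",
    "compute_auc",
    "replace_zero_auc",
    "normalize_by_control",
    "preprocess",
    "PreprocessResult",
]

REQUIRED_COLUMNS = ("sample_id", "peptide_id", "replicate", "time_s", "signal_lux")
KEY_COLUMNS = ("sample_id", "peptide_id", "replicate", "time_s")
AUC_WINDOW = (640.0, 1840.0)


class InputError(ValueError):
    """Malformed input table."""


class PipelineError(RuntimeError):
    """A processing rule left no usable data."""


@dataclass
class VmaxMatrix:
    """Initial-velocity estimates, replicate-level and averaged."""

    #: index (sample_id, replicate), columns peptides; Lux/s
    per_replicate: pd.DataFrame
    #: samples x peptides mean over replicates
    mean: pd.DataFrame


def read_signal_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format kinetic signal TSV.

    Required columns: sample_id, peptide_id, replicate, time_s, signal_lux.
    Rejects missing columns, non-numeric signals (with row numbers) and
    duplicated (sample, peptide, replicate, time) keys.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty signal table: {path}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"signal table missing column(s): {', '.join(missing)}")
    if df.empty:
        raise InputError(f"signal table has no rows: {path}")
    sig = pd.to_numeric(df["signal_lux"], errors="coerce")
    bad = df.index[sig.isna() & df["signal_lux"].notna()] + 2  # 1-based + header
    if len(bad):
        raise InputError(f"non-numeric signal_lux at file row(s): {list(bad[:10])}")
    if sig.isna().any():
        raise InputError("missing signal_lux values")
    df["signal_lux"] = sig.astype(float)
    df["time_s"] = pd.to_numeric(df["time_s"], errors="raise").astype(float)
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        first = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
        raise InputError(f"duplicate (sample, peptide, replicate, time) key: {first}")
    return df


def exclude_internal_control(
    table: pd.DataFrame, control_id: str = INTERNAL_CONTROL_ID
) -> pd.DataFrame:
    """Remove the internal positive-control peptide; warn if absent."""
    mask = table["peptide_id"] == control_id
    if not mask.any():
        warnings.warn(f"internal control peptide {control_id!r} not present", stacklevel=2)
        return table
    return table.loc[~mask].reset_index(drop=True)


def _ols_slopes(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized OLS slope of y (…, T) against t (T,)."""
    tc = t - t.mean()
    denom = (tc**2).sum()
    return (y - y.mean(axis=-1, keepdims=True)) @ tc / denom


def estimate_vmax(
    table: pd.DataFrame,
    initial_phase_end: float = 640.0,
    min_points: int = 3,
) -> VmaxMatrix:
    """Initial reaction velocity per (sample, peptide, replicate).

    Vmax is the ordinary-least-squares slope of signal vs time over the
    earliest timepoints (all points at or before ``initial_phase_end``, at
    least ``min_points`` of them). Cells with fewer than 2 usable timepoints
    are recorded as missing.
    """
    times = np.sort(table["time_s"].unique())
    early = times[times <= initial_phase_end]
    if len(early) < min_points:
        early = times[:min_points]
    if len(early) < 2:
        raise InputError("fewer than 2 timepoints available for Vmax estimation")
    sub = table[table["time_s"].isin(early)]
    wide = sub.pivot_table(
        index=["sample_id", "peptide_id", "replicate"],
        columns="time_s",
        values="signal_lux",
    )
    complete = wide.notna().all(axis=1)
    slopes = pd.Series(np.nan, index=wide.index)
    if complete.any():
        y = wide.loc[complete].to_numpy()
        slopes.loc[complete] = _ols_slopes(wide.columns.to_numpy(dtype=float), y)
    per_rep = slopes.unstack("peptide_id")
    mean = per_rep.groupby(level=0).mean()
    return VmaxMatrix(per_replicate=per_rep, mean=mean)


def clamp_and_filter_vmax(vmax: VmaxMatrix) -> tuple[VmaxMatrix, list[str]]:
    """Clamp negative Vmax to zero; drop peptides with zero clamped average.

    The filter average is taken dataset-wide (over all replicates and
    samples per peptide). Returns the filtered matrix and the dropped
    peptide IDs. Idempotent.
    """
    clamped = vmax.per_replicate.clip(lower=0.0)
    pep_mean = clamped.mean(axis=0, skipna=True)
    dropped = sorted(pep_mean.index[~(pep_mean > 0)])
    kept = [p for p in clamped.columns if p not in set(dropped)]
    if not kept:
        raise PipelineError("no peptides survive Vmax filtering")
    per_rep = clamped[kept]
    return VmaxMatrix(per_replicate=per_rep, mean=per_rep.groupby(level=0).mean()), dropped


def _window_weights(t: np.ndarray, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    """Augmented grid and trapezoid weights for the integral over [t0, t1].

    Interpolates linearly onto the window edges when they are not sampled;
    the integral of a curve y (sampled on t) over the window is then
    ``w @ y_aug`` with y_aug the values on the augmented grid.
    """
    if t0 >= t1:
        raise InputError("AUC window must satisfy t0 < t1")
    inside = t[(t > t0) & (t < t1)]
    grid = np.unique(np.concatenate([[t0], inside, [t1]]))
    if np.sum((t >= t0) & (t <= t1)) < 2 and not (t.min() <= t0 and t.max() >= t1):
        raise InputError("fewer than 2 timepoints inside AUC window")
    d = np.diff(grid)
    w = np.zeros(len(grid))
    w[:-1] += d / 2
    w[1:] += d / 2
    return grid, w


def compute_auc(
    table: pd.DataFrame,
    window: tuple[float, float] = AUC_WINDOW,
    peptides: list[str] | None = None,
) -> pd.DataFrame:
    """Windowed trapezoidal AUC of the replicate-mean signal.

    Replicate signals are averaged per timepoint first, then integrated over
    ``window`` (default 640-1840 s) with linear interpolation onto the window
    edges. Returns a samples x peptides matrix in Lux*s. Negative signals
    contribute negatively.
    """
    t0, t1 = float(window[0]), float(window[1])
    sub = table if peptides is None else table[table["peptide_id"].isin(peptides)]
    mean_sig = (
        sub.groupby(["sample_id", "peptide_id", "time_s"], sort=True)["signal_lux"]
        .mean()
        .unstack("time_s")
    )
    t = mean_sig.columns.to_numpy(dtype=float)
    if t.min() > t0 or t.max() < t1:
        # window edges outside the sampled range: fall back to the covered part
        raise InputError(
            f"sampled times [{t.min()}, {t.max()}] do not cover AUC window [{t0}, {t1}]"
        )
    if mean_sig.isna().any().any():
        raise InputError("incomplete time grid: some curves lack shared timepoints")
    grid, w = _window_weights(t, t0, t1)
    y = mean_sig.to_numpy()
    # interpolate every curve onto the augmented grid (linear, exact on t)
    y_aug = np.empty((y.shape[0], len(grid)))
    for i in range(y.shape[0]):
        y_aug[i] = np.interp(grid, t, y[i])
    auc = y_aug @ w
    out = pd.Series(auc, index=mean_sig.index).unstack("peptide_id")
    out.index.name = "sample_id"
    return out


def replace_zero_auc(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace nonpositive AUC values with the sample's smallest positive AUC.

    Applies per sample (row); returns the repaired matrix and a boolean
    flag matrix marking replaced cells. A sample with no positive AUC at all
    is an error. Idempotent.
    """
    values = matrix.to_numpy(dtype=float).copy()
    flags = values <= 0
    for i, sample in enumerate(matrix.index):
        row = values[i]
        pos = row[row > 0]
        if flags[i].any():
            if len(pos) == 0:
                raise PipelineError(f"sample {sample!r} has no positive AUC value")
            row[flags[i]] = pos.min()
    out = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    return out, pd.DataFrame(flags, index=matrix.index, columns=matrix.columns)


def normalize_by_control(
    matrix: pd.DataFrame,
    control_peptide: str = NORMALIZATION_CONTROL_ID,
    drop_control: bool = True,
) -> pd.DataFrame:
    """Divide every sample's values by its control-peptide value.

    The control column becomes exactly 1 and is dropped by default. A control
    value that is missing or <= 0 in any sample aborts with that sample named.
    """
    if control_peptide not in matrix.columns:
        raise PipelineError(f"control peptide {control_peptide!r} not in matrix")
    ctrl = matrix[control_peptide]
    bad = ctrl.index[~(ctrl > 0) | ctrl.isna()]
    if len(bad):
        raise PipelineError(
            f"control peptide {control_peptide!r} nonpositive/missing in sample(s): "
            f"{list(bad)}"
        )
    out = matrix.div(ctrl, axis=0)
    if drop_control:
        out = out.drop(columns=[control_peptide])
    return out


@dataclass
class PreprocessResult:
    """Activity matrix plus processing provenance."""

    activity: pd.DataFrame  # samples x peptides, strictly positive
    zero_replaced: pd.DataFrame  # boolean flags, same shape pre-normalization
    dropped_peptides: list[str] = field(default_factory=list)
    vmax: VmaxMatrix | None = None

    def report(self) -> dict:
        rows, cols = np.nonzero(self.zero_replaced.to_numpy())
        replaced = [
            [str(self.zero_replaced.index[i]), str(self.zero_replaced.columns[j])]
            for i, j in zip(rows, cols)
        ]
        return {
            "n_samples": int(self.activity.shape[0]),
            "n_peptides": int(self.activity.shape[1]),
            "dropped_peptides": list(self.dropped_peptides),
            "zero_replaced_cells": replaced,
        }


def preprocess(
    table: pd.DataFrame,
    internal_control: str = INTERNAL_CONTROL_ID,
    normalization_control: str = NORMALIZATION_CONTROL_ID,
    window: tuple[float, float] = AUC_WINDOW,
    normalize_auc: bool = True,
    filter_by_vmax: bool = True,
) -> PreprocessResult:
    """Run the full signal -> activity chain (see module docstring)."""
    table = exclude_internal_control(table, internal_control)
    dropped: list[str] = []
    vmax = None
    if filter_by_vmax:
        vmax, dropped = clamp_and_filter_vmax(estimate_vmax(table))
        # the normalization control must survive to normalize with
        if normalize_auc and normalization_control in dropped:
            raise PipelineError(
                f"normalization control {normalization_control!r} removed by Vmax filter"
            )
        keep = list(vmax.per_replicate.columns)
    else:
        keep = None
    auc = compute_auc(table, window=window, peptides=keep)
    auc, flags = replace_zero_auc(auc)
    if normalize_auc:
        auc = normalize_by_control(auc, normalization_control)
    return PreprocessResult(activity=auc, zero_replaced=flags, dropped_peptides=dropped, vmax=vmax)
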