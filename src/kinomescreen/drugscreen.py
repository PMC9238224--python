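"""Organoid drug-screen analysis: viability, ATP calibration, efficacy calls.

Luminescence (RLU) from an ATP-based viability readout is converted to
viability relative to each line's vehicle-control wells, optionally on the
ATP-concentration scale via a per-line standard curve (4x dilution series,
20 µM down to ~4.9 nM). A drug effectively inhibits a line when its
viability falls strictly below mean - 3*SD of the vehicle controls of the
same line. Across tumor lines at the analysis dose (default 10 µM) drugs
are classified as pan-effective (all lines), selective (some) or
ineffective (none); a drug effective in tumor lines only is additionally
flagged tumor-selective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AtpCalibration",
    "CalibrationError",
    "ScreenError",
    "fit_atp_standard_curve",
    "relative_viability",
    "efficacy_call",
    "classify_drugs",
    "process_drug_screen",
    "DrugScreenResult",
]

ANALYSIS_DOSE_UM = 10.0


class CalibrationError(ValueError):
    pass


class ScreenError(ValueError):
    pass


@dataclass
class AtpCalibration:
    """Linear RLU-vs-concentration standard curve."""

    slope: float  # RLU per µM (or per log µM in log-log mode)
    intercept: float
    r_squared: float
    conc_range_um: tuple[float, float]
    loglog: bool = False

    def to_atp_um(self, rlu: np.ndarray | float) -> np.ndarray | float:
        """Invert the calibration: luminescence -> ATP concentration (µM)."""
        if self.loglog:
            return 10 ** ((np.log10(rlu) - self.intercept) / self.slope)
        return (rlu - self.intercept) / self.slope


def fit_atp_standard_curve(
    conc_um: np.ndarray, rlu: np.ndarray, loglog: bool = False
) -> AtpCalibration:
    """Ordinary-least-squares standard curve from >= 3 ATP standards.

    Native scale by default; ``loglog`` fits log10(RLU) vs log10(conc) for
    saturating luminescence. A nonpositive slope is a calibration error.
    """
    conc = np.asarray(conc_um, dtype=float)
    y = np.asarray(rlu, dtype=float)
    if len(conc) < 3:
        raise CalibrationError(f"need >= 3 ATP standards, got {len(conc)}")
    if (conc <= 0).any():
        raise CalibrationError("ATP standard concentrations must be positive")
    x = np.log10(conc) if loglog else conc
    yy = np.log10(y) if loglog else y
    fit = stats.linregress(x, yy)
    if fit.slope <= 0:
        raise CalibrationError(f"nonpositive standard-curve slope ({fit.slope:.3g})")
    return AtpCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range_um=(float(conc.min()), float(conc.max())),
        loglog=loglog,
    )


def _well_groups(table: pd.DataFrame) -> None:
    required = {"well_type", "drug", "dose_um", "sample_id", "rlu"}
    missing = required - set(table.columns)
    if missing:
        raise ScreenError(f"drug-screen table missing column(s): {sorted(missing)}")


def _sample_calibrations(table: pd.DataFrame, loglog: bool) -> dict[str, AtpCalibration]:
    cals = {}
    std = table[table["well_type"] == "standard"]
    for sample, grp in std.groupby("sample_id"):
        cals[str(sample)] = fit_atp_standard_curve(
            grp["conc_um"].to_numpy(), grp["rlu"].to_numpy(), loglog=loglog
        )
    return cals


def relative_viability(
    table: pd.DataFrame,
    dose_um: float = ANALYSIS_DOSE_UM,
    metric: str = "atp",
    loglog_calibration: bool = False,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, AtpCalibration]]:
    """Viability of every (drug, sample) at a dose, relative to vehicle.

    viability = mean(treated) / mean(vehicle), computed on the ATP scale
    when ``metric="atp"`` and per-line standards exist (falling back to raw
    RLU otherwise), or on raw RLU with ``metric="rlu"``.

    Returns (drugs x samples viability matrix, per-sample vehicle well
    fractions of their own mean, per-sample calibrations used).
    """
    _well_groups(table)
    if metric not in ("atp", "rlu"):
        raise ScreenError(f"unknown metric {metric!r}")
    cals = _sample_calibrations(table, loglog_calibration) if metric == "atp" else {}

    def measure(sample: str, rlu: np.ndarray) -> np.ndarray:
        if metric == "atp" and sample in cals:
            return np.asarray(cals[sample].to_atp_um(rlu), dtype=float)
        return np.asarray(rlu, dtype=float)

    veh = table[table["well_type"] == "vehicle"]
    vehicle_mean: dict[str, float] = {}
    vehicle_fracs: dict[str, np.ndarray] = {}
    for sample, grp in veh.groupby("sample_id"):
        vals = measure(str(sample), grp["rlu"].to_numpy())
        m = vals.mean()
        if m <= 0:
            raise ScreenError(f"vehicle mean <= 0 for sample {sample!r}")
        vehicle_mean[str(sample)] = m
        vehicle_fracs[str(sample)] = vals / m

    treated = table[(table["well_type"] == "treated") & (table["dose_um"] == dose_um)]
    if treated.empty:
        raise ScreenError(f"no treated wells at dose {dose_um} µM")
    cells = {}
    for (drug, sample), grp in treated.groupby(["drug", "sample_id"]):
        sample = str(sample)
        if sample not in vehicle_mean:
            raise ScreenError(f"no vehicle wells for sample {sample!r}")
        cells[(str(drug), sample)] = measure(sample, grp["rlu"].to_numpy()).mean() / vehicle_mean[
            sample
        ]
    viability = pd.Series(cells).unstack()
    viability.index.name = "drug"
    viability.columns.name = "sample_id"
    return viability.sort_index(), vehicle_fracs, cals


def efficacy_call(
    viability: float, vehicle_fractions: np.ndarray
) -> tuple[bool, float]:
    """Apply the mean - 3*SD vehicle rule to one viability value.

    ``vehicle_fractions`` are the line's vehicle wells divided by their own
    mean (so their mean is 1). The threshold is mean - 3*SD (sample SD,
    ddof=1) and the call uses a strict '<'. Needs >= 2 vehicle wells.
    """
    v = np.asarray(vehicle_fractions, dtype=float)
    if len(v) < 2:
        raise ScreenError("need >= 2 vehicle wells to estimate the threshold SD")
    threshold = float(v.mean() - 3.0 * v.std(ddof=1))
    return bool(viability < threshold), threshold


def classify_drugs(
    effective: pd.DataFrame,
    tumor_samples: list[str],
    nontumor_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-drug efficacy class over the tumor lines.

    pan_effective: effective in every tumor line; selective: in >= 1 but not
    all; ineffective: in none. ``tumor_selective`` flags drugs effective in
    >= 1 tumor line and in no non-tumor line.
    """
    missing = [s for s in tumor_samples if s not in effective.columns]
    if missing:
        raise ScreenError(f"efficacy calls missing for tumor line(s): {missing}")
    nontumor_samples = [
        s for s in (nontumor_samples or []) if s in effective.columns
    ]
    rows = []
    for drug in effective.index:
        hits = int(effective.loc[drug, tumor_samples].sum())
        if hits == len(tumor_samples):
            cls = "pan_effective"
        elif hits > 0:
            cls = "selective"
        else:
            cls = "ineffective"
        nt_hits = int(effective.loc[drug, nontumor_samples].sum()) if nontumor_samples else 0
        rows.append(
            {
                "drug": drug,
                "class": cls,
                "n_tumor_hit": hits,
                "n_tumor": len(tumor_samples),
                "n_nontumor_hit": nt_hits,
                "tumor_selective": bool(hits > 0 and nt_hits == 0 and nontumor_samples),
            }
        )
    return pd.DataFrame(rows).set_index("drug").sort_index()


@dataclass
class DrugScreenResult:
    viability: pd.DataFrame  # drugs x samples
    response: pd.DataFrame  # clip(1 - viability, 0, 1)
    effective: pd.DataFrame  # boolean calls
    thresholds: pd.Series  # per-sample efficacy threshold
    classification: pd.DataFrame
    calibrations: dict[str, AtpCalibration] = field(default_factory=dict)
    dose_um: float = ANALYSIS_DOSE_UM


def process_drug_screen(
    table: pd.DataFrame,
    dose_um: float = ANALYSIS_DOSE_UM,
    metric: str = "atp",
    tumor_samples: list[str] | None = None,
    nontumor_samples: list[str] | None = None,
) -> DrugScreenResult:
    """Full screen analysis at one dose: viability, response, calls, classes."""
    viability, vehicle_fracs, cals = relative_viability(table, dose_um, metric)
    thresholds = {}
    effective = pd.DataFrame(index=viability.index, columns=viability.columns, dtype=bool)
    for sample in viability.columns:
        for drug in viability.index:
            eff, thr = efficacy_call(viability.at[drug, sample], vehicle_fracs[sample])
            effective.at[drug, sample] = eff
            thresholds[sample] = thr
    response = (1.0 - viability).clip(lower=0.0, upper=1.0)
    if tumor_samples is None:
        tumor_samples = [s for s in viability.columns if str(s).lower().startswith(("tumor", "ccao"))]
    if nontumor_samples is None:
        nontumor_samples = [s for s in viability.columns if s not in tumor_samples]
    classification = (
        classify_drugs(effective, tumor_samples, nontumor_samples)
        if tumor_samples
        else pd.DataFrame()
    )
    return DrugScreenResult(
        viability=viability,
        response=response,
        effective=effective,
        thresholds=pd.Series(thresholds, name="threshold"),
        classification=classification,
        calibrations=cals,
        dose_um=dose_um,
    )
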