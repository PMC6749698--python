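"""Plate-reader readings to enzymatic activity units.

Amylase activity comes from a colorimetric kinetic read: absorbance at
405 nm measured once per minute over six minutes at 23 degC, with one
activity unit defined as a rise of one absorbance unit per minute.  A
calibration series of standards with known concentration converts slopes
to concentration units by inverse prediction.  Reporter-gene activity is
expressed in Miller units (nmol * OD^-1 * min^-1) from endpoint A420/A550
readings of a lysed culture of measured OD600.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line of response (slope) vs standard concentration."""

    gain: float  # response per concentration unit
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float

    @property
    def valid(self) -> bool:
        return self.gain > 0


def kinetic_slope(time_min, absorbance) -> float:
    """Least-squares slope of absorbance vs time, in absorbance units/min.

    This is the assay's activity readout: one unit of amylase activity is
    one absorbance unit per minute.  The fit uses every timepoint (not the
    endpoint difference) and is invariant to a constant baseline offset.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if t.size != y.size:
        raise ValueError("time and absorbance must have equal length")
    if t.size < 3:
        raise ValueError("a kinetic trace needs at least 3 timepoints")
    if not (np.diff(t) > 0).all():
        raise ValueError("timepoints must be strictly increasing")
    result = stats.linregress(t, y)
    return float(result.slope)


def slopes_from_trace_table(traces: pd.DataFrame) -> pd.Series:
    """Per-sample kinetic slopes from a long trace table.

    Expects columns ``sample, time_min, absorbance`` (plus an optional
    ``replicate`` column, in which case technical replicates are averaged
    per timepoint before the fit).
    """
    def one(group: pd.DataFrame) -> float:
        if "replicate" in group.columns:
            group = group.groupby("time_min", as_index=False)["absorbance"].mean()
        group = group.sort_values("time_min")
        return kinetic_slope(group["time_min"], group["absorbance"])

    return traces.groupby("sample").apply(one, include_groups=False).rename("slope")


def fit_calibration(concentrations, responses) -> CalibrationCurve:
    """Ordinary least-squares calibration line with an R^2 diagnostic."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size != y.size:
        raise ValueError("concentrations and responses must have equal length")
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    result = stats.linregress(c, y)
    return CalibrationCurve(
        gain=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue**2),
        conc_min=float(c.min()),
        conc_max=float(c.max()),
    )


def concentration_from_slope(curve: CalibrationCurve, slope: float) -> tuple[float, bool]:
    """Inverse prediction (slope - intercept) / gain.

    Returns ``(concentration, extrapolated)`` where the flag marks values
    outside the standard range.
    """
    if not curve.valid:
        raise ValueError("calibration curve has nonpositive gain")
    conc = (slope - curve.intercept) / curve.gain
    # tolerance guards boundary standards against float rounding
    tol = 1e-9 * max(1.0, curve.conc_max - curve.conc_min)
    extrapolated = conc < curve.conc_min - tol or conc > curve.conc_max + tol
    return float(conc), extrapolated


def miller_units(
    od600: float,
    a420: float,
    a550: float = 0.0,
    time_min: float = 15.0,
    volume_ml: float = 0.1,
    scatter_factor: float = 1.75,
) -> float:
    """Beta-galactosidase activity in Miller units.

    1000 * (A420 - scatter_factor * A550) / (time_min * volume_ml * OD600),
    where the A550 term corrects for light scattering by cell debris.  The
    classical 1.75 correction factor is the default and configurable.
    """
    if od600 <= 0:
        raise ValueError("od600 must be positive")
    if time_min <= 0 or volume_ml <= 0:
        raise ValueError("time_min and volume_ml must be positive")
    return 1000.0 * (a420 - scatter_factor * a550) / (time_min * volume_ml * od600)


def miller_units_table(readings: pd.DataFrame, scatter_factor: float = 1.75) -> pd.Series:
    """Miller units for each row of a readings table.

    Expects columns ``od600, a420, a550, time_min, volume_ml``; technical
    duplicate rows of the same ``sample`` are averaged on the reading scale
    before conversion when a ``sample`` column is present.
    """
    df = readings
    if "sample" in df.columns:
        df = df.groupby("sample", as_index=True).mean(numeric_only=True)
    return pd.Series(
        [
            miller_units(
                row["od600"],
                row["a420"],
                row["a550"],
                row["time_min"],
                row["volume_ml"],
                scatter_factor,
            )
            for _, row in df.iterrows()
        ],
        index=df.index,
        name="miller_units",
    )
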