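"""Measurement models: melting temperature from nanoDSF melt curves, the
diffusion interaction parameter kD from DLS dilution series, and retained
monomer after agitation stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "DlsDilutionSeries",
    "MeltCurve",
    "NoTransitionError",
    "fit_kd",
    "retained_monomer",
    "tm_from_curve",
    "read_dilution_series",
    "read_melt_curve",
]

DEFAULT_DLS_CONCENTRATIONS = (2.0, 3.25, 4.5, 5.75, 7.0)  # mg/mL


class NoTransitionError(ValueError):
    """Melt curve shows no unfolding transition above the prominence floor."""


@dataclass
class DlsDilutionSeries:
    """Diffusion coefficients measured over a protein dilution series.

    ``concentrations`` are in mg/mL; ``D_values`` are in any consistent
    unit (kD only involves the slope/intercept ratio).
    """

    concentrations: np.ndarray
    D_values: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.D_values = np.asarray(self.D_values, dtype=float)
        if len(self.concentrations) != len(self.D_values):
            raise ValueError("concentration/D length mismatch")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(self.concentrations)) < 2:
            raise ValueError("need at least two distinct concentrations")


@dataclass
class MeltCurve:
    """Fluorescence ratio (350 nm / 330 nm) on an increasing temperature grid."""

    temperatures: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.temperatures) != len(self.ratio):
            raise ValueError("temperature/ratio length mismatch")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def fit_kd(series: DlsDilutionSeries) -> tuple[float, float, float]:
    """Fit D = D0 (1 + kD c) by ordinary least squares.

    Returns (D0, kD in mL/g, R^2).  With c in mg/mL the raw slope/intercept
    ratio is in mL/mg, hence the factor 1000 to mL/g.  A zero or negative
    intercept leaves kD undefined and raises; a perfectly flat series gives
    kD = 0 with R^2 = 0 by convention.
    """
    c = series.concentrations
    D = series.D_values
    slope, intercept = np.polyfit(c, D, 1)
    if intercept <= 0:
        raise ValueError("non-positive intercept D0; kD undefined")
    kd = float(slope / intercept * 1e3)
    resid = D - (intercept + slope * c)
    ss_tot = float(np.sum((D - D.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(intercept), kd, r2


def retained_monomer(c_ref: float, c_shaken: float) -> float:
    """Retained monomer (%) after agitation: 100 - (c_ref - c_shaken)/c_ref * 100.

    Values above 100 (shaken concentration exceeding the reference) are
    returned as-is; callers may flag them.
    """
    if c_ref <= 0:
        raise ValueError("reference concentration must be positive")
    if c_shaken < 0:
        raise ValueError("shaken concentration must be non-negative")
    return 100.0 - (c_ref - c_shaken) / c_ref * 100.0


def tm_from_curve(
    curve: MeltCurve,
    window: int = 9,
    polyorder: int = 3,
    min_prominence: float = 5e-3,
) -> float:
    """Melting temperature: location of the first-derivative maximum of the
    fluorescence ratio.

    The ratio is smoothed with a Savitzky-Golay filter, differentiated by
    central differences, and the global derivative maximum is refined by a
    local quadratic fit.  ``min_prominence`` (ratio units per degree C) is
    the floor below which the curve is declared transition-free.
    """
    T, r = curve.temperatures, curve.ratio
    if len(T) < 7:
        raise ValueError("need at least 7 grid points")
    w = min(window, len(r) if len(r) % 2 else len(r) - 1)
    smooth = savgol_filter(r, w, min(polyorder, w - 1))
    deriv = np.gradient(smooth, T)
    i = int(np.argmax(deriv))
    if deriv[i] < min_prominence:
        raise NoTransitionError(
            f"max derivative {deriv[i]:.2e} per degC below prominence floor"
        )
    if 0 < i < len(T) - 1:
        # quadratic through the three points around the max
        y0, y1, y2 = deriv[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            offset = 0.5 * (y0 - y2) / denom
            return float(T[i] + offset * (T[i + 1] - T[i]))
    return float(T[i])


def read_dilution_series(path) -> list[DlsDilutionSeries]:
    """Read a DLS CSV (columns conc_mg_mL, D, replicate) into one series
    per replicate."""
    df = pd.read_csv(path)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return [
        DlsDilutionSeries(g["conc_mg_mL"].to_numpy(), g["D"].to_numpy())
        for _, g in df.groupby("replicate", sort=True)
    ]


def read_melt_curve(path) -> MeltCurve:
    """Read a melt-curve CSV with columns T_C, ratio."""
    df = pd.read_csv(path)
    return MeltCurve(df["T_C"].to_numpy(), df["ratio"].to_numpy())
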