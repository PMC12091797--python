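"""Oxygen uptake rates from dissolved-oxygen traces.

A chemostat gas-liquid mass balance on the dissolved-oxygen fraction
DO = c/c*,

    dDO/dt = kLa (1 - DO) - qO2 X / c*,

is inverted pointwise to recover the specific oxygen uptake rate

    qO2 = (c*/X) [ kLa (1 - DO) - dDO/dt ],

with dDO/dt estimated by a Savitzky-Golay (local least-squares polynomial)
derivative of order 2.  The filter is implemented as local polynomial
regression in real time coordinates so the irregular sampling of metabolic-
cycle time series is handled exactly; endpoints use one-sided windows.
The exchange flux is vO2 = -qO2 (negative = consumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DissolvedOxygenSeries",
    "CultureParams",
    "OxygenFluxSeries",
    "savgol_derivative",
    "oxygen_uptake_rate",
    "read_do_table",
    "write_oxygen_table",
]


@dataclass
class DissolvedOxygenSeries:
    """Dissolved-oxygen fraction of saturation sampled over time (h)."""

    times: np.ndarray
    do: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.do = np.asarray(self.do, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.do.shape:
            raise ValueError("times and DO must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.do < 0) or np.any(self.do > 1):
            warnings.warn(
                "DO values outside [0, 1] clipped (instrument noise)", stacklevel=2
            )
            self.do = np.clip(self.do, 0.0, 1.0)


@dataclass(frozen=True)
class CultureParams:
    """Chemostat parameters for the oxygen balance.

    kla: volumetric O2 transfer coefficient (1/h).
    c_star: O2 saturation concentration (mmol/L); default 0.236 is water at
        30 degC (assumption, not a measured value).
    biomass: biomass concentration X (g/L); default 5 is an assumption.
    dilution_rate: chemostat dilution rate (1/h), equal to the biomass
        growth rate at steady state.
    """

    kla: float = 225.0
    c_star: float = 0.236
    biomass: float = 5.0
    dilution_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("kla", "c_star", "biomass", "dilution_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class OxygenFluxSeries:
    """Specific O2 uptake qO2 (positive) and exchange flux vO2 = -qO2."""

    times: np.ndarray
    qo2: np.ndarray
    vo2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.qo2 = np.asarray(self.qo2, dtype=float)
        if self.vo2 is None:
            self.vo2 = -self.qo2
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if not np.allclose(self.vo2, -self.qo2):
            raise ValueError("vO2 must equal -qO2 elementwise")


def savgol_derivative(
    series: DissolvedOxygenSeries, order: int = 2, window: int = 5
) -> np.ndarray:
    """Savitzky-Golay first derivative of DO(t), supporting non-uniform time.

    At each sample, a degree-``order`` polynomial is fit by least squares to
    the ``window`` points centered there (one-sided at the ends) in actual
    time coordinates, and its derivative is evaluated at that sample.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    t, y = series.times, series.do
    n = len(t)
    if n < window:
        raise ValueError(f"series has {n} points, fewer than window={window}")
    half = window // 2
    deriv = np.empty(n)
    for i in range(n):
        lo = min(max(0, i - half), n - window)
        sel = slice(lo, lo + window)
        # center the fit at t[i] for numerical conditioning
        coeffs = np.polynomial.polynomial.polyfit(t[sel] - t[i], y[sel], order)
        deriv[i] = coeffs[1]  # d/dt at the expansion point
    return deriv


def oxygen_uptake_rate(
    series: DissolvedOxygenSeries,
    params: CultureParams,
    ddo_dt: np.ndarray,
) -> OxygenFluxSeries:
    """Invert the DO mass balance pointwise into qO2 (and vO2 = -qO2)."""
    ddo_dt = np.asarray(ddo_dt, dtype=float)
    if ddo_dt.shape != series.times.shape:
        raise ValueError("dDO/dt length must match the DO series")
    qo2 = (params.c_star / params.biomass) * (
        params.kla * (1.0 - series.do) - ddo_dt
    )
    return OxygenFluxSeries(times=series.times.copy(), qo2=qo2)


def read_do_table(path) -> DissolvedOxygenSeries:
    """Read a two-column delimited file (time_h, DO_fraction)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("expected two columns: time_h, DO_fraction")
    return DissolvedOxygenSeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def write_oxygen_table(flux: OxygenFluxSeries, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_h": flux.times, "qO2": flux.qo2, "vO2": flux.vo2}).to_csv(
        path, sep="\t", index=False
    )
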