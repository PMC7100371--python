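"""Drift-tube ion mobility: mobility regression and Mason–Schamp CCS.

In a linear drift tube the arrival time scales with the inverse drift
voltage, ``t_arr = L²/(K·V) + t0``, so an ordinary least-squares fit of
arrival time on 1/V yields the mobility K (slope = L²/K) and the
non-drift time offset t0.  The collision cross section follows from the
Mason–Schamp relation

    Ω = (3 q / 16 N) · sqrt(2π / (μ k_B T)) · 1/K

with N the buffer-gas number density, μ the ion–buffer reduced mass and
q the ion charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants, stats

__all__ = ["DriftSeries", "MobilityResult", "fit_drift", "mason_schamp_ccs", "analyze_drift_series"]

TORR_TO_PA = 133.32236842105263
#: Relative systematic uncertainty floor on absolute CCS measurements.
CCS_SYSTEMATIC = 0.02


@dataclass(frozen=True)
class DriftSeries:
    """Arrival-time vs drift-voltage series with instrument parameters.

    Defaults match a 79 cm drift tube with helium buffer at 4 Torr and
    room temperature (298 K assumed; configurable).
    """

    voltages: tuple[float, ...]
    arrival_times: tuple[float, ...]
    ion_mass: float
    drift_length: float = 0.79
    temperature: float = 298.0
    pressure: float = 4.0
    buffer_mass: float = 4.002602
    charge: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        t = np.asarray(self.arrival_times, dtype=float)
        if v.size != t.size or v.size < 2:
            raise ValueError("need >= 2 matched (voltage, arrival time) points")
        if np.any(v <= 0):
            raise ValueError("drift voltages must be positive")
        if min(self.temperature, self.pressure, self.drift_length, self.ion_mass) <= 0:
            raise ValueError("physical parameters must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


@dataclass(frozen=True)
class MobilityResult:
    """Mobility, reduced mobility, time offset and Mason–Schamp CCS."""

    mobility: float  # m^2 / (V s)
    reduced_mobility: float  # at 760 Torr, 273.15 K
    t0: float  # s
    ccs: float  # Angstrom^2
    se_ccs: float  # Angstrom^2

    def __post_init__(self) -> None:
        if self.mobility <= 0 or self.ccs <= 0:
            raise ValueError("mobility and CCS must be positive")


def fit_drift(series: DriftSeries) -> tuple[float, float]:
    """OLS of arrival time on 1/V; returns ``(mobility, t0)``.

    The slope L²/K must be positive; flat or inverted series raise.
    """
    mobility, t0, _ = _fit_drift_full(series)
    return mobility, t0


def _fit_drift_full(series: DriftSeries) -> tuple[float, float, float]:
    inv_v = 1.0 / np.asarray(series.voltages, dtype=float)
    t = np.asarray(series.arrival_times, dtype=float)
    if np.unique(inv_v).size < 2:
        raise ValueError("need at least two distinct drift voltages")
    res = stats.linregress(inv_v, t)
    if not res.slope > 0:
        raise ValueError("non-positive drift slope; arrival times do not scale with 1/V")
    mobility = series.drift_length**2 / res.slope
    rel_se = 0.0 if np.isnan(res.stderr) else res.stderr / res.slope
    return float(mobility), float(res.intercept), float(rel_se)


def mason_schamp_ccs(
    mobility: float,
    series: DriftSeries,
    *,
    t0: float = 0.0,
    rel_se_mobility: float = 0.0,
) -> MobilityResult:
    """Convert a mobility into a Mason–Schamp collision cross section.

    Reports Ω in Å² and the reduced mobility K0 (760 Torr, 273.15 K).
    ``se_ccs`` combines the mobility regression error with a 2% absolute
    systematic floor, in quadrature.
    """
    if mobility <= 0:
        raise ValueError("mobility must be positive")
    kb = constants.k
    temp = series.temperature
    number_density = series.pressure * TORR_TO_PA / (kb * temp)
    mu = (
        series.ion_mass
        * series.buffer_mass
        / (series.ion_mass + series.buffer_mass)
        * constants.u
    )
    q = series.charge * constants.e
    omega_m2 = (
        (3.0 * q / (16.0 * number_density))
        * math.sqrt(2.0 * math.pi / (mu * kb * temp))
        / mobility
    )
    ccs = omega_m2 * 1e20
    k0 = mobility * (series.pressure / 760.0) * (273.15 / temp)
    se = ccs * math.sqrt(rel_se_mobility**2 + CCS_SYSTEMATIC**2)
    return MobilityResult(
        mobility=mobility, reduced_mobility=k0, t0=t0, ccs=ccs, se_ccs=se
    )


def analyze_drift_series(series: DriftSeries) -> MobilityResult:
    """Full chain: drift regression then Mason–Schamp conversion."""
    mobility, t0, rel_se = _fit_drift_full(series)
    return mason_schamp_ccs(mobility, series, t0=t0, rel_se_mobility=rel_se)
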