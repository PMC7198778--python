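"""Headspace N2O concentrations -> net production rates -> cumulative emission.

The static-enclosure calculation assumes N2O accumulates linearly in the
sealed headspace over the enclosure period (supported for 24 h enclosures at
these rates), so the net rate is simply the headspace mass increment divided
by dry soil mass and the enclosure duration.

Units are fixed package-wide at ng N2O-N per g dry soil per day; headers of
all CSV interfaces carry the unit string.  Whether literature rates are per
moist or dry gram is often left unstated — here everything is per *dry* gram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignUnit

__all__ = [
    "R_GAS",
    "N_PER_N2O",
    "GasMeasurement",
    "NetRate",
    "conc_to_mass",
    "net_rate",
    "cumulative_emission",
    "rates_from_gas_table",
]

R_GAS = 8.31446261815324   # J mol-1 K-1
N_PER_N2O = 28.0134        # g N per mol N2O (two N atoms)


class FluxError(ValueError):
    """Invalid flux-calculation input."""


@dataclass(frozen=True)
class GasMeasurement:
    """Paired headspace N2O concentrations for one bottle enclosure."""

    unit: DesignUnit | None
    conc_t0_ppbv: float
    conc_t24_ppbv: float
    headspace_volume_l: float
    temperature_k: float
    dry_mass_g: float
    pressure_pa: float = 101325.0
    enclosure_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.conc_t0_ppbv < 0 or self.conc_t24_ppbv < 0:
            raise FluxError("concentrations must be non-negative")
        if self.headspace_volume_l <= 0:
            raise FluxError("headspace volume must be positive")
        if not 270.0 < self.temperature_k < 320.0:
            raise FluxError(f"temperature {self.temperature_k} K outside plausible 270-320 K")
        if self.dry_mass_g <= 0:
            raise FluxError("dry soil mass must be positive")
        if self.enclosure_hours <= 0:
            raise FluxError("enclosure duration must be positive")


@dataclass(frozen=True)
class NetRate:
    """Net N2O production rate, ng N2O-N g-1 dry soil d-1 (negative = uptake)."""

    unit: DesignUnit | None
    rate: float
    se: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise FluxError("rate must be finite")


def conc_to_mass(
    conc_ppbv: float,
    headspace_volume_l: float,
    temperature_k: float,
    pressure_pa: float = 101325.0,
) -> float:
    """Convert a headspace mixing ratio to mass of N2O-N, in ng.

    Ideal-gas headspace inventory: moles of N2O = (ppbv * 1e-9) * pV/RT,
    times 28 g N per mol N2O.  Linear in concentration.
    """
    if headspace_volume_l <= 0 or temperature_k <= 0 or pressure_pa <= 0:
        raise FluxError("volume, temperature and pressure must be positive")
    if conc_ppbv < 0:
        raise FluxError("concentration must be non-negative")
    total_mol = pressure_pa * (headspace_volume_l * 1e-3) / (R_GAS * temperature_k)
    n2o_mol = conc_ppbv * 1e-9 * total_mol
    return n2o_mol * N_PER_N2O * 1e9  # g -> ng


def mass_to_conc(
    mass_ng_n: float,
    headspace_volume_l: float,
    temperature_k: float,
    pressure_pa: float = 101325.0,
) -> float:
    """Inverse of :func:`conc_to_mass` (used by the synthetic generator)."""
    per_ppbv = conc_to_mass(1.0, headspace_volume_l, temperature_k, pressure_pa)
    return mass_ng_n / per_ppbv


def net_rate(m: GasMeasurement) -> NetRate:
    """Net N2O production rate of one bottle from its paired concentrations."""
    delta_ng = conc_to_mass(
        m.conc_t24_ppbv, m.headspace_volume_l, m.temperature_k, m.pressure_pa
    ) - conc_to_mass(m.conc_t0_ppbv, m.headspace_volume_l, m.temperature_k, m.pressure_pa)
    rate = delta_ng / m.dry_mass_g / (m.enclosure_hours / 24.0)
    return NetRate(m.unit, rate)


def cumulative_emission(
    series: list[tuple[float, float]],
    day0_rule: str = "constant",
) -> float:
    """Trapezoidal integral of a (day, mean rate) series from day 0, ng N g-1.

    ``day0_rule``: how to extend from day 0 to the first measured day —
    ``"constant"`` holds the first rate constant back to day 0 (default),
    ``"zero"`` ramps linearly from zero at day 0.
    """
    if not series:
        raise FluxError("empty rate series")
    days = np.asarray([d for d, _ in series], dtype=float)
    rates = np.asarray([r for _, r in series], dtype=float)
    if len(np.unique(days)) != len(days):
        raise FluxError("duplicate days in rate series")
    if np.any(np.diff(days) <= 0):
        raise FluxError("days must be strictly increasing")
    if day0_rule not in ("constant", "zero"):
        raise FluxError(f"unknown day0_rule {day0_rule!r}")
    if len(series) == 1:
        warnings.warn("single time point: cumulative = span * rate", stacklevel=2)

    if days[0] > 0:
        r0 = rates[0] if day0_rule == "constant" else 0.0
        days = np.concatenate([[0.0], days])
        rates = np.concatenate([[r0], rates])
    return float(np.trapezoid(rates, days))


def rates_from_gas_table(
    gas: pd.DataFrame,
    dry_mass_g: float = 18.0,
    default_headspace_l: float | None = None,
    enclosure_hours: float = 24.0,
) -> pd.DataFrame:
    """Vectorized net-rate computation over a gas.csv-layout table.

    Expected columns: the design key (fertilization, temperature_C, replicate,
    c2h2_level, day, arm) plus conc_t0_ppbv, conc_t24_ppbv, and optionally
    headspace_volume_L and pressure_Pa.  Gas-law temperature is the incubation
    temperature.  Returns the design key + rate_ngN_g_d.
    """
    required = {"fertilization", "temperature_C", "replicate", "c2h2_level",
                "day", "conc_t0_ppbv", "conc_t24_ppbv"}
    missing = required - set(gas.columns)
    if missing:
        raise FluxError(f"gas table missing columns: {sorted(missing)}")
    vol = (
        gas["headspace_volume_L"].to_numpy(float)
        if "headspace_volume_L" in gas.columns
        else np.full(len(gas), default_headspace_l or np.nan)
    )
    if np.any(~np.isfinite(vol)):
        raise FluxError("headspace volume absent and no default supplied")
    pres = (
        gas["pressure_Pa"].to_numpy(float)
        if "pressure_Pa" in gas.columns
        else np.full(len(gas), 101325.0)
    )
    temp_k = gas["temperature_C"].to_numpy(float) + 273.15
    per_ppbv = pres * (vol * 1e-3) / (R_GAS * temp_k) * 1e-9 * N_PER_N2O * 1e9
    delta = (gas["conc_t24_ppbv"].to_numpy(float) - gas["conc_t0_ppbv"].to_numpy(float))
    rate = delta * per_ppbv / dry_mass_g / (enclosure_hours / 24.0)
    key_cols = [c for c in ("fertilization", "temperature_C", "replicate",
                            "c2h2_level", "day", "arm") if c in gas.columns]
    out = gas[key_cols].copy()
    out["rate_ngN_g_d"] = rate
    return out
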