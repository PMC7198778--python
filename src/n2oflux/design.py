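"""Factorial microcosm design: domain types, enumeration and balance checks.

The experimental layout emulated throughout the package is a soil-microcosm
incubation crossing fertilization history (unfertilized control CT, mineral
NPK, manure-amended MNPK) with incubation temperature (15/25/35 degC) and four
replicates.  Bottles belong to one of three arms:

* ``net_monitoring`` — a fixed set of bottles whose headspace is enclosed for
  24 h on each monitoring day to yield net N2O production rates (these double
  as the 0 Pa acetylene controls on campaign days);
* ``c2h2_campaign`` — bottles receiving 10 Pa or 10 kPa C2H2 on the gross-rate
  campaign days (3, 15, 30);
* ``destructive`` — bottles sacrificed for soil chemistry and DNA.

Day-0 baseline bottles are destructively sampled before temperature
assignment, so their ``temperature`` is ``None``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Fertilization",
    "C2H2Level",
    "Arm",
    "DesignUnit",
    "Scenario",
    "BalanceReport",
    "TEMPERATURES_C",
    "CAMPAIGN_DAYS",
    "NET_MONITORING_DAYS",
    "enumerate_design",
    "validate_balance",
    "design_to_frame",
]


class Fertilization(str, Enum):
    """Long-term fertilization regime of the source plots."""

    CT = "CT"        # no fertilizer
    NPK = "NPK"      # synthetic N, P, K
    MNPK = "MNPK"    # half-rate NPK plus composted manure


class C2H2Level(str, Enum):
    """Headspace acetylene partial pressure.

    P0    — 0 Pa, untreated control (net rate).
    P10   — 10 Pa, autotrophic nitrification inhibited.
    KP10  — 10 kPa, nitrification and N2O consumption inhibited.
    """

    P0 = "P0"
    P10 = "P10"
    KP10 = "KP10"


class Arm(str, Enum):
    NET_MONITORING = "net_monitoring"
    C2H2_CAMPAIGN = "c2h2_campaign"
    DESTRUCTIVE = "destructive"


TEMPERATURES_C: tuple[int, ...] = (15, 25, 35)
CAMPAIGN_DAYS: tuple[int, ...] = (3, 15, 30)
NET_MONITORING_DAYS: tuple[int, ...] = (1, 3, 5, 7, 10, 15, 20, 25, 30)
_VALID_DAYS = (0, 1, 3, 5, 7, 10, 15, 20, 25, 30)


class DesignError(ValueError):
    """Invalid design configuration."""


_FERT_ORDER = {"CT": 0, "NPK": 1, "MNPK": 2}
_C2H2_ORDER = {"P0": 0, "P10": 1, "KP10": 2}


@dataclass(frozen=True)
class DesignUnit:
    """One microcosm bottle at one observation occasion."""

    fertilization: Fertilization
    temperature: int | None          # degC; None for day-0 baseline bottles
    replicate: int
    c2h2: C2H2Level
    day: int
    arm: Arm

    def __post_init__(self) -> None:
        if self.temperature is not None and self.temperature not in TEMPERATURES_C:
            raise DesignError(f"temperature {self.temperature} not in {TEMPERATURES_C}")
        if self.day not in _VALID_DAYS:
            raise DesignError(f"day {self.day} not a sampling day {_VALID_DAYS}")
        if self.replicate < 1:
            raise DesignError("replicate index is 1-based")
        if self.c2h2 in (C2H2Level.P10, C2H2Level.KP10) and self.day not in CAMPAIGN_DAYS:
            raise DesignError(
                f"C2H2 level {self.c2h2.value} only applied on campaign days {CAMPAIGN_DAYS}"
            )
        if self.day == 0 and self.temperature is not None:
            raise DesignError("day-0 baseline bottles have no temperature assignment")

    @property
    def cell(self) -> tuple[str, int | None, int]:
        """(fertilization, temperature, day) — the treatment cell."""
        return (self.fertilization.value, self.temperature, self.day)

    @property
    def sort_key(self) -> tuple:
        return (
            _FERT_ORDER[self.fertilization.value],
            -1 if self.temperature is None else self.temperature,
            self.replicate,
            _C2H2_ORDER[self.c2h2.value],
            self.day,
        )


@dataclass
class Scenario:
    """Physical configuration shared by all bottles of a study."""

    design: list[DesignUnit] = field(default_factory=list)
    soil_dry_mass_g: float = 18.0
    bottle_volume_ml: float = 125.0
    moisture_whc: float = 0.50
    enclosure_hours: float = 24.0
    bulk_density_g_cm3: float = 1.3

    def __post_init__(self) -> None:
        if self.soil_dry_mass_g <= 0:
            raise DesignError("soil_dry_mass_g must be positive")
        if self.enclosure_hours <= 0:
            raise DesignError("enclosure_hours must be positive")
        if self.bottle_volume_ml <= self.soil_displacement_ml:
            raise DesignError("bottle volume must exceed soil displacement volume")

    @property
    def soil_displacement_ml(self) -> float:
        return self.soil_dry_mass_g / self.bulk_density_g_cm3

    @property
    def headspace_volume_l(self) -> float:
        """Headspace = bottle volume minus soil displacement, in litres."""
        return (self.bottle_volume_ml - self.soil_displacement_ml) / 1000.0


def enumerate_design(
    fertilizations: Sequence[Fertilization] | int = 3,
    temperatures: Sequence[int] | int = 3,
    replicates: int = 4,
    c2h2_levels: Sequence[C2H2Level] = (C2H2Level.P0,),
    days: Sequence[int] = NET_MONITORING_DAYS,
    arm: Arm = Arm.NET_MONITORING,
    fresh_bottles_per_campaign: bool = True,
) -> list[DesignUnit]:
    """Enumerate the full Cartesian product of design factors.

    Counts may be given instead of explicit level lists (``3`` means the three
    packaged fertilization regimes / the three incubation temperatures).  The
    returned list is sorted (fertilization, temperature, replicate, C2H2, day)
    and therefore deterministic.

    ``fresh_bottles_per_campaign`` is a bookkeeping flag only: when False the
    same physical bottles are considered re-used on each campaign day, which
    does not change the enumerated observation units, but is recorded so a
    bottle census can be derived either way.
    """
    if isinstance(fertilizations, int):
        if not 1 <= fertilizations <= 3:
            raise DesignError("fertilization count must be 1..3")
        fert_levels = list(Fertilization)[:fertilizations]
    else:
        fert_levels = list(fertilizations)
    if isinstance(temperatures, int):
        if not 1 <= temperatures <= 3:
            raise DesignError("temperature count must be 1..3")
        temp_levels: list[int | None] = list(TEMPERATURES_C)[:temperatures]
    else:
        temp_levels = list(temperatures)

    if not fert_levels or not temp_levels or not list(c2h2_levels) or not list(days):
        raise DesignError("every factor needs at least one level")
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    if len(set(days)) != len(list(days)):
        raise DesignError("duplicate days in design")

    units = [
        DesignUnit(f, t, r, c, d, arm)
        for f in fert_levels
        for t in temp_levels
        for r in range(1, replicates + 1)
        for c in c2h2_levels
        for d in days
    ]
    units.sort(key=lambda u: u.sort_key)
    return units


@dataclass
class BalanceReport:
    balanced: bool
    replicates_per_cell: dict[tuple, int]
    deficient_cells: list[tuple]
    message: str


def validate_balance(units: Iterable[DesignUnit]) -> BalanceReport:
    """Report per-cell replicate counts; flag any imbalance.

    A *cell* here is (fertilization, temperature, day, C2H2 level, arm); a
    balanced design has the same replicate count in every cell.
    """
    units = list(units)
    if not units:
        raise DesignError("cannot validate an empty design")
    counts = Counter(
        (u.fertilization.value, u.temperature, u.day, u.c2h2.value, u.arm.value)
        for u in units
    )
    n_modal = Counter(counts.values()).most_common(1)[0][0]
    deficient = sorted(k for k, v in counts.items() if v != n_modal)
    balanced = not deficient
    msg = (
        f"balanced, n={n_modal} per cell"
        if balanced
        else f"unbalanced: {len(deficient)} cell(s) deviate from modal n={n_modal}"
    )
    return BalanceReport(balanced, dict(counts), deficient, msg)


def design_to_frame(units: Sequence[DesignUnit]):
    """Design as a tidy DataFrame matching the design.csv layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "fertilization": [u.fertilization.value for u in units],
            "temperature_C": [u.temperature for u in units],
            "replicate": [u.replicate for u in units],
            "c2h2_level": [u.c2h2.value for u in units],
            "day": [u.day for u in units],
            "arm": [u.arm.value for u in units],
        }
    )
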