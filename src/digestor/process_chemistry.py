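"""Stoichiometric and operational accounting for anaerobic digestion.

Theoretical methane potentials from elemental composition, organic loading
rates, hydraulic retention time, digestion efficiency, gas-volume
normalization and stressor molarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._rounding import round_half_up, truncate

#: Molar volume of an ideal gas at 273 K and 1013 hPa, L mol^-1.
MOLAR_VOLUME_STP = 22.414

#: Standard atomic masses, g mol^-1 (CHON only; used for consistency checks).
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


class CompositionError(ValueError):
    """Raised when a species' elemental composition is missing or invalid."""


class NoThroughputError(ValueError):
    """Raised when a retention time is requested with zero digestate exchange."""


@dataclass(frozen=True)
class ChemicalSpecies:
    """A substrate or stressor characterised by its C/H/O/N composition.

    Parameters
    ----------
    name:
        Human-readable label.
    c, h, o, n:
        Non-negative atom counts per formula unit.
    molar_mass:
        Molar mass in g mol^-1. When ``chon_only`` is true it must agree
        with the composition within 1%.
    chon_only:
        Whether the formula contains no elements beyond C/H/O/N. Species
        with other elements (e.g. sodium phosphate) skip the mass
        consistency check and are not valid Buswell substrates.
    organic:
        Whether the species counts toward volatile-solids loading.
    """

    name: str
    c: int
    h: int
    o: int
    n: int
    molar_mass: float
    chon_only: bool = True
    organic: bool = True

    def __post_init__(self) -> None:
        for sym, count in (("c", self.c), ("h", self.h), ("o", self.o), ("n", self.n)):
            if not isinstance(count, int) or count < 0:
                raise CompositionError(
                    f"{self.name}: atom count {sym}={count!r} must be a non-negative integer"
                )
        if self.molar_mass <= 0:
            raise CompositionError(f"{self.name}: molar mass must be positive")
        if self.chon_only:
            implied = (
                self.c * _ATOMIC_MASS["C"]
                + self.h * _ATOMIC_MASS["H"]
                + self.o * _ATOMIC_MASS["O"]
                + self.n * _ATOMIC_MASS["N"]
            )
            if implied == 0 or abs(implied - self.molar_mass) / self.molar_mass > 0.01:
                raise CompositionError(
                    f"{self.name}: molar mass {self.molar_mass} inconsistent with "
                    f"composition-implied {implied:.2f} g/mol"
                )


#: Species used in the digestion experiment.
GLUCOSE = ChemicalSpecies("glucose", c=6, h=12, o=6, n=0, molar_mass=180.16)
NALIDIXIC_ACID = ChemicalSpecies("nalidixic acid", c=12, h=12, o=3, n=2, molar_mass=232.24)
GABA = ChemicalSpecies("GABA", c=4, h=9, o=2, n=1, molar_mass=103.12)
#: Interpreted as anhydrous trisodium phosphate (Na3PO4); inorganic, no CH4 yield.
SODIUM_PHOSPHATE = ChemicalSpecies(
    "sodium phosphate", c=0, h=0, o=4, n=0, molar_mass=163.94, chon_only=False, organic=False
)
CARBON_DIOXIDE = ChemicalSpecies("carbon dioxide", c=1, h=0, o=2, n=0, molar_mass=44.01)

SPECIES: Mapping[str, ChemicalSpecies] = {
    s.name: s for s in (GLUCOSE, NALIDIXIC_ACID, GABA, SODIUM_PHOSPHATE, CARBON_DIOXIDE)
}


@dataclass(frozen=True)
class FeedingEvent:
    """One feeding: substrate and optional stressor dose per litre working volume."""

    day: int
    substrate_load: float = 0.0
    stressor_load: float = 0.0
    stressor_is_organic: bool = True

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.substrate_load < 0 or self.stressor_load < 0:
            raise ValueError("loads must be >= 0")


@dataclass(frozen=True)
class ReactorConfig:
    """Semicontinuous reactor geometry and exchange regime."""

    working_volume: float
    exchange_volume: float
    feedings_per_week: int

    def __post_init__(self) -> None:
        if self.working_volume <= 0:
            raise ValueError("working volume must be positive")
        if not 0 <= self.exchange_volume <= self.working_volume:
            raise ValueError("exchange volume must lie in [0, working volume]")


@dataclass(frozen=True)
class GasMeasurement:
    """A raw gas-volume reading with the temperature/pressure it was taken at."""

    volume: float
    temperature: float
    pressure: float

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be >= 0")
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be positive")


@dataclass(frozen=True)
class BuswellResult:
    """Specific methane potential with a flag for fully oxidised substrates."""

    yield_l_per_g: float
    non_methanogenic: bool = False

    def __float__(self) -> float:
        return self.yield_l_per_g


def buswell_yield(species: ChemicalSpecies) -> BuswellResult:
    """Specific theoretical methane potential, L CH4 (273 K, 1013 hPa) per g.

    Complete anaerobic degradation of CcHhOoNn yields
    ``c/2 + h/8 - o/4 - 3n/8`` mol CH4 per mol of substrate. A negative
    stoichiometric result (over-oxidised carbon) is clamped to zero and
    flagged ``non_methanogenic``.
    """
    if not species.chon_only:
        raise CompositionError(
            f"{species.name}: composition is not pure C/H/O/N; Buswell stoichiometry undefined"
        )
    if species.c < 1:
        raise CompositionError(f"{species.name}: needs at least one carbon atom")
    ch4_mol = species.c / 2 + species.h / 8 - species.o / 4 - 3 * species.n / 8
    if ch4_mol <= 0:
        return BuswellResult(0.0, non_methanogenic=True)
    return BuswellResult(ch4_mol * MOLAR_VOLUME_STP / species.molar_mass)


def theoretical_methane(
    load: float, species: ChemicalSpecies, *, yield_decimals: int | None = 2
) -> float:
    """Theoretical methane potential of a cumulative load, L CH4 per L working volume.

    ``yield_decimals`` rounds the per-gram yield before multiplying, matching
    report arithmetic that chains the printed 2-dp yield (0.58 L/g x 21.11 g/L
    = 12.24 L); pass ``None`` for the unrounded chain.
    """
    if load < 0:
        raise ValueError("load must be >= 0")
    y = buswell_yield(species).yield_l_per_g
    if yield_decimals is not None:
        y = round_half_up(y, yield_decimals)
    return load * y


def organic_loading_rate(events: Iterable[FeedingEvent]) -> float:
    """Mean daily volatile-solids input over one week, gVS L^-1 d^-1.

    Sums substrate plus *organic* stressor loads and divides by 7; inorganic
    stressors contribute nothing. All events must fall within one 7-day window.
    """
    events = list(events)
    if not events:
        return 0.0
    days = [e.day for e in events]
    if max(days) - min(days) > 6:
        raise ValueError("feeding events span more than one 7-day window")
    total = sum(e.substrate_load for e in events)
    total += sum(e.stressor_load for e in events if e.stressor_is_organic)
    return total / 7.0


def hydraulic_retention_time(config: ReactorConfig) -> float:
    """Working volume over mean daily exchange volume, in days."""
    if config.exchange_volume <= 0 or config.feedings_per_week <= 0:
        raise NoThroughputError("retention time undefined without digestate exchange")
    daily_exchange = config.exchange_volume * config.feedings_per_week / 7.0
    return config.working_volume / daily_exchange


def digestion_efficiency(produced: float, theoretical: float) -> float:
    """Produced methane as a percentage of the theoretical potential."""
    if theoretical <= 0:
        raise ValueError("theoretical potential must be positive")
    if produced < 0:
        raise ValueError("produced volume must be >= 0")
    return 100.0 * produced / theoretical


def expected_surplus(theoretical_stressor: float, efficiency: float) -> float:
    """Extra methane expected from a stressor's potential at a given efficiency (%)."""
    if not 0 <= efficiency <= 100:
        raise ValueError("efficiency must lie in [0, 100]")
    return theoretical_stressor * efficiency / 100.0


def normalize_gas_volume(m: GasMeasurement) -> float:
    """Ideal-gas correction of a measured volume to 273 K and 1013 hPa."""
    return m.volume * (273.0 / m.temperature) * (m.pressure / 1013.0)


def molar_concentration(load: float, species: ChemicalSpecies) -> float:
    """Convert a mass load (g per L) into millimolar concentration."""
    if load < 0:
        raise ValueError("load must be >= 0")
    return 1000.0 * load / species.molar_mass


@dataclass(frozen=True)
class WeeklyReport:
    """Per-week OLR summary row for the report table."""

    week: int
    olr: float
    olr_2dp: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "olr_2dp", round_half_up(self.olr, 2))


def weekly_loading_rates(
    events: Sequence[FeedingEvent], *, week_length: int = 7
) -> list[WeeklyReport]:
    """Group feeding events into consecutive weeks (day // 7) and compute OLRs."""
    by_week: dict[int, list[FeedingEvent]] = {}
    for e in events:
        by_week.setdefault(e.day // week_length, []).append(e)
    return [WeeklyReport(week=w, olr=organic_loading_rate(evs)) for w, evs in sorted(by_week.items())]


def retention_time_report(config: ReactorConfig) -> dict[str, float]:
    """Retention time at full precision and truncated to 2 dp (printed form)."""
    hrt = hydraulic_retention_time(config)
    return {"days": hrt, "days_2dp": truncate(hrt, 2)}
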