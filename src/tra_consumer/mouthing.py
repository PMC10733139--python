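"""Migration-rate oral exposure from mouthed articles, and its inversion.

Chemical migration from a mouthed article into saliva is characterised
empirically as a rate per 10 cm2 of mouthed surface per minute. Given such
a rate, the dose scales linearly with mouthed area and daily mouthing time;
inverting the relation gives the mouthing time needed to reach a target
dose — a plausibility check on screening-tier oral estimates, which assume
complete ingestion of the mouthed mass.

Observed saliva-migration rates across substance-material combinations span
1.7e-6 to 33 ug/10 cm2/min (the top of the range is a PVC article); both
endpoints ship as named constants. Rates are stored per 10 cm2 exactly as
reported — conversion to per-cm2 happens inside the operations — to avoid a
silent factor-of-ten unit error.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, UnreachableTargetError
from .substances import Population
from .units import MIN_PER_H, UG_PER_MG

__all__ = [
    "MigrationRate",
    "LOWEST_OBSERVED_RATE",
    "HIGHEST_OBSERVED_RATE",
    "migration_oral_dose",
    "mouthing_time_to_reach",
    "implied_uptake_thickness",
    "round_mouthing_hours",
]


@dataclass(frozen=True)
class MigrationRate:
    """Substance migration into saliva, ug per 10 cm2 mouthed area per minute."""

    rate: float
    material_label: str = ""

    def __post_init__(self):
        if self.rate < 0:
            raise DomainError("migration rate must be >= 0")


#: Endpoints of the observed saliva-migration range, ug/10 cm2/min.
LOWEST_OBSERVED_RATE = MigrationRate(1.7e-6, "slowest observed substance-material pair")
HIGHEST_OBSERVED_RATE = MigrationRate(33.0, "fastest observed pair (PVC article)")


def migration_oral_dose(
    rate: MigrationRate,
    mouthed_area: float,
    mouthing_time: float,
    population: Population,
) -> float:
    """Oral dose from mouthing, mg/kg body weight/day.

    dose = r * (area / 10 cm2) * time[min/day] / BW, converted ug -> mg.
    """
    if mouthed_area < 0 or mouthing_time < 0:
        raise DomainError("area and time must be >= 0")
    ug_per_day = rate.rate * (mouthed_area / 10.0) * mouthing_time
    return ug_per_day / UG_PER_MG / population.body_weight


def mouthing_time_to_reach(
    target_dose: float,
    rate: MigrationRate,
    mouthed_area: float,
    population: Population,
) -> float:
    """Daily mouthing time (hours) needed to reach ``target_dose`` mg/kg/day.

    Inverse of :func:`migration_oral_dose`. A zero rate cannot reach any
    positive target.
    """
    if target_dose < 0:
        raise DomainError("target dose must be >= 0")
    if mouthed_area <= 0:
        raise DomainError("mouthed area must be > 0")
    if rate.rate <= 0:
        raise UnreachableTargetError(
            "zero migration rate cannot reach a positive target dose"
        )
    minutes = target_dose * UG_PER_MG * population.body_weight / (
        rate.rate * mouthed_area / 10.0
    )
    return minutes / MIN_PER_H


def implied_uptake_thickness(ingested_volume: float, mouthed_area: float) -> float:
    """Article thickness equivalent to an ingested volume, cm.

    thickness = volume[cm3] / area[cm2]; e.g. ingesting 0.01-0.3 cm3 over a
    10 cm2 mouthed area corresponds to complete uptake from a 0.001-0.03 cm
    surface layer.
    """
    if mouthed_area <= 0:
        raise DomainError("mouthed area must be > 0")
    if ingested_volume < 0:
        raise DomainError("ingested volume must be >= 0")
    return ingested_volume / mouthed_area


def round_mouthing_hours(hours: float) -> float:
    """Report rounding for mouthing times: one decimal below 1 h, nearest
    whole hour otherwise."""
    return round(hours, 1) if hours < 1.0 else float(round(hours))
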