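"""Screening-tier route algorithms.

The four core exposure equations of the screening tool:

* inhalation — instantaneous, well-mixed release of a vapor-pressure-banded
  fraction of the substance into the room, capped at the saturated vapor
  concentration (SVC) for non-aerosols;
* dermal — a uniform thickness layer (TL) of product/article material on the
  contacted skin, all of whose substance content counts as external dose;
* oral — complete ingestion of the substance in the mouthed/ingested mass;
* total — the simple sum of routes, deliberately without mass balance.

Every equation is linear in use amount, weight fraction, contact areas and
event frequency, and inverse-linear in body weight; the only nonlinearity is
the SVC cap.

Vapor-pressure banding: the release fraction is 1 at and above 10 Pa and
drops one order of magnitude per decade of vapor pressure below that, with a
floor of 0.001 below 0.1 Pa::

    [10, inf) -> 1      [1, 10) -> 0.1
    [0.1, 1)  -> 0.01   (0, 0.1) -> 0.001
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

from .errors import CappedResultError, DomainError
from .scenarios import STANDARD_THICKNESS_LAYERS, ExposureScenario
from .substances import Substance
from .units import DEFAULT_TEMPERATURE_K, MG_PER_G, R_GAS

__all__ = [
    "VPBand",
    "VP_BANDS",
    "assign_vp_band",
    "saturated_vapor_concentration",
    "inhalation_event_concentration",
    "inhalation_daily_dose",
    "dermal_daily_dose",
    "oral_daily_dose",
    "total_exposure",
    "rescale_weight_fraction",
    "assess_scenario",
    "ExposureResult",
    "TotalExposure",
]


@dataclass(frozen=True)
class VPBand:
    """One volatility band: [lower_bound, upper_bound) Pa -> release fraction."""

    lower_bound: float  # Pa, inclusive
    upper_bound: float  # Pa, exclusive (inf for the top band)
    release_fraction: float

    def __contains__(self, vapor_pressure: float) -> bool:
        return self.lower_bound <= vapor_pressure < self.upper_bound


#: The four volatility bands, highest first. Bounds are lower-inclusive /
#: upper-exclusive, so exactly 10 Pa gets fraction 1 and exactly 0.1 Pa gets
#: 0.01 (0.1 Pa is the cutoff *for* the lowest band, not in it).
VP_BANDS: tuple[VPBand, ...] = (
    VPBand(10.0, math.inf, 1.0),
    VPBand(1.0, 10.0, 0.1),
    VPBand(0.1, 1.0, 0.01),
    VPBand(0.0, 0.1, 0.001),
)


def assign_vp_band(vapor_pressure: float) -> VPBand:
    """Volatility band containing ``vapor_pressure`` (Pa, must be > 0)."""
    if vapor_pressure <= 0:
        raise DomainError(f"vapor pressure must be > 0 Pa, got {vapor_pressure}")
    for band in VP_BANDS:
        if vapor_pressure in band:
            return band
    raise AssertionError("bands partition (0, inf)")  # pragma: no cover


def saturated_vapor_concentration(
    substance: Substance, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Saturated vapor concentration, mg/m3: SVC = VP * MW / (R * T).

    The ideal-gas ceiling on the airborne concentration of a pure substance;
    used as an upper bound (cap) on non-aerosol inhalation estimates.
    """
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    # Pa * g/mol / (J/mol/K * K) = g/m3; *1000 -> mg/m3
    return (
        substance.vapor_pressure
        * substance.molecular_weight
        / (R_GAS * temperature)
        * MG_PER_G
    )


class ConcentrationResult(NamedTuple):
    """Event-average air concentration with the cap/band bookkeeping."""

    concentration: float  # mg/m3
    caps_applied: tuple[str, ...]
    release_fraction: float


def inhalation_event_concentration(
    scenario: ExposureScenario,
    substance: Substance,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> ConcentrationResult:
    """Event-average air concentration, mg/m3.

    C = A[mg] * WF * f_rel * f_dil / V, with f_rel from the volatility band
    (1 for aerosols: complete instantaneous release). Instantaneous release
    into a closed room makes the event average equal the peak m/V. For
    non-aerosols the result is capped at the SVC and ``"svc_cap"`` is
    recorded when the cap binds.
    """
    if scenario.room_volume <= 0:
        raise DomainError("room volume must be > 0 m3")
    if scenario.is_aerosol:
        f_rel = 1.0
    else:
        f_rel = assign_vp_band(substance.vapor_pressure).release_fraction
    c_raw = (
        scenario.product_amount
        * MG_PER_G
        * scenario.weight_fraction
        * f_rel
        * scenario.dilution_fraction
        / scenario.room_volume
    )
    caps: tuple[str, ...] = ()
    if not scenario.is_aerosol:
        svc = saturated_vapor_concentration(substance, temperature)
        if c_raw > svc:
            c_raw = svc
            caps = ("svc_cap",)
    return ConcentrationResult(c_raw, caps, f_rel)


def inhalation_daily_dose(concentration: float, scenario: ExposureScenario) -> float:
    """Systemic-scale inhalation dose, mg/kg body weight/day.

    dose = C * IR * t * n / BW.
    """
    if concentration < 0:
        raise DomainError("concentration must be >= 0")
    pop = scenario.population
    if pop.body_weight <= 0:
        raise DomainError("body weight must be > 0 kg")
    return (
        concentration
        * pop.inhalation_rate
        * scenario.event_duration
        * scenario.events_per_day
        / pop.body_weight
    )


class DermalResult(NamedTuple):
    daily_dose: float  # mg/kg/day
    areal_load: float  # mg/cm2
    warnings: tuple[str, ...]


def dermal_daily_dose(scenario: ExposureScenario) -> DermalResult:
    """Thickness-layer dermal dose.

    areal_load = TL * rho * WF * TF (mg/cm2); dose = SA * areal_load * n / BW.
    A TL of 0.01 cm at unit density carries 10 mg/cm2 across the contacted
    skin. A thickness layer outside the standard {0.01, 0.001} cm values is
    allowed but recorded as a warning in provenance.
    """
    warnings: tuple[str, ...] = ()
    if scenario.thickness_layer not in STANDARD_THICKNESS_LAYERS:
        warnings = (
            f"nonstandard thickness_layer {scenario.thickness_layer} cm "
            f"(standard values: {STANDARD_THICKNESS_LAYERS})",
        )
    areal_load = (
        scenario.thickness_layer
        * scenario.contact_density
        * scenario.weight_fraction
        * scenario.transfer_factor
        * MG_PER_G
    )
    dose = (
        scenario.skin_contact_area
        * areal_load
        * scenario.events_per_day
        / scenario.population.body_weight
    )
    return DermalResult(dose, areal_load, warnings)


def oral_daily_dose(scenario: ExposureScenario) -> float:
    """Ingestion dose, mg/kg/day: Q[mg] * WF * TF * n / BW.

    Assumes 100% of the substance in the ingested/mouthed mass is taken in.
    """
    return (
        scenario.ingested_amount
        * MG_PER_G
        * scenario.weight_fraction
        * scenario.transfer_factor
        * scenario.events_per_day
        / scenario.population.body_weight
    )


@dataclass(frozen=True)
class ExposureResult:
    """One route estimate with cap/override provenance.

    ``event_route_mass_mg`` is the substance mass the route equation assigns
    to its pathway per event; ``available_mass_mg`` is A x WF. Both feed the
    mass-balance exceedance flag and may be None for results built from bare
    printed doses.
    """

    route: str  # inhalation | dermal | oral
    daily_dose: float  # mg/kg body weight/day
    event_air_concentration: Optional[float] = None  # mg/m3, inhalation only
    areal_load: Optional[float] = None  # mg/cm2, dermal only
    caps_applied: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()
    population_label: str = "adult"
    body_weight: float = 60.0
    category_code: Optional[str] = None
    weight_fraction: Optional[float] = None
    event_route_mass_mg: Optional[float] = None
    available_mass_mg: Optional[float] = None

    def __post_init__(self):
        if self.daily_dose < 0:
            raise DomainError("daily_dose must be >= 0")


class TotalExposure(NamedTuple):
    daily_dose: float  # mg/kg/day, sum over routes
    mass_balance_exceeded: Optional[bool]  # None when route masses unknown


def total_exposure(results: list[ExposureResult]) -> TotalExposure:
    """Sum route doses; flag (never correct) mass-balance exceedance.

    The route equations operate independently, so the emitted + transferred
    + ingested substance mass can exceed the A x WF present in the product;
    this deliberate conservatism is reported via the flag. The flag is None
    when any result lacks mass bookkeeping. All results must share one
    population.
    """
    if not results:
        return TotalExposure(0.0, None)
    pops = {(r.population_label, r.body_weight) for r in results}
    if len(pops) > 1:
        raise DomainError(f"results mix populations: {sorted(pops)}")
    dose = sum(r.daily_dose for r in results)
    flag: Optional[bool]
    if any(r.event_route_mass_mg is None or r.available_mass_mg is None for r in results):
        flag = None
    else:
        implied = sum(r.event_route_mass_mg for r in results)
        available = max(r.available_mass_mg for r in results)
        flag = implied > available
    return TotalExposure(dose, flag)


def rescale_weight_fraction(
    result: ExposureResult, old_wf: float, new_wf: float
) -> ExposureResult:
    """Rescale a route result from one weight fraction to another.

    Exact because every route equation is linear in WF — unless the SVC cap
    bound, in which case linearity is broken and the scenario must be
    recomputed from scratch (raises :class:`CappedResultError`).
    """
    if old_wf <= 0:
        raise DomainError(f"old weight fraction must be > 0, got {old_wf}")
    if not 0 <= new_wf <= 1:
        raise DomainError(f"new weight fraction must be in [0, 1], got {new_wf}")
    if "svc_cap" in result.caps_applied:
        raise CappedResultError(
            "result was capped at the saturated vapor concentration; the cap "
            "breaks linearity in the weight fraction — recompute the scenario "
            "at the new weight fraction instead of rescaling"
        )
    ratio = new_wf / old_wf
    return replace(
        result,
        daily_dose=result.daily_dose * ratio,
        event_air_concentration=(
            None
            if result.event_air_concentration is None
            else result.event_air_concentration * ratio
        ),
        areal_load=None if result.areal_load is None else result.areal_load * ratio,
        event_route_mass_mg=(
            None
            if result.event_route_mass_mg is None
            else result.event_route_mass_mg * ratio
        ),
        available_mass_mg=(
            None
            if result.available_mass_mg is None
            else result.available_mass_mg * ratio
        ),
        weight_fraction=new_wf if result.weight_fraction is not None else None,
        provenance=result.provenance
        + (f"weight_fraction rescaled {old_wf} -> {new_wf}",),
    )


def assess_scenario(
    scenario: ExposureScenario,
    substance: Substance,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> list[ExposureResult]:
    """All applicable route results for one scenario/substance pair.

    Inhalation is emitted when the scenario uses a product amount, dermal
    when skin contact area is set, oral when an ingested amount is set.
    """
    pop = scenario.population
    common = dict(
        population_label=pop.label,
        body_weight=pop.body_weight,
        category_code=scenario.category_code,
        weight_fraction=scenario.weight_fraction,
        # A x WF bounds the mass the routes can draw on; without a product
        # amount (pure mouthing scenarios) the bound is indeterminate.
        available_mass_mg=(
            scenario.available_substance_mass_mg
            if scenario.product_amount > 0
            else None
        ),
        provenance=scenario.applied_overrides,
    )
    results: list[ExposureResult] = []
    if scenario.product_amount > 0:
        conc = inhalation_event_concentration(scenario, substance, temperature)
        emitted = (
            scenario.product_amount
            * MG_PER_G
            * scenario.weight_fraction
            * conc.release_fraction
        )
        results.append(
            ExposureResult(
                route="inhalation",
                daily_dose=inhalation_daily_dose(conc.concentration, scenario),
                event_air_concentration=conc.concentration,
                caps_applied=conc.caps_applied,
                event_route_mass_mg=emitted,
                **{
                    **common,
                    "provenance": common["provenance"]
                    + (f"vp_band_release_fraction={conc.release_fraction}",),
                },
            )
        )
    if scenario.skin_contact_area > 0:
        derm = dermal_daily_dose(scenario)
        results.append(
            ExposureResult(
                route="dermal",
                daily_dose=derm.daily_dose,
                areal_load=derm.areal_load,
                event_route_mass_mg=derm.areal_load * scenario.skin_contact_area,
                **{
                    **common,
                    "provenance": common["provenance"] + derm.warnings,
                },
            )
        )
    if scenario.ingested_amount > 0:
        results.append(
            ExposureResult(
                route="oral",
                daily_dose=oral_daily_dose(scenario),
                event_route_mass_mg=scenario.ingested_amount
                * MG_PER_G
                * scenario.weight_fraction
                * scenario.transfer_factor,
                **common,
            )
        )
    return results
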