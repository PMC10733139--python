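"""Alternative dermal-from-article transfer models.

Four approaches from the consumer-exposure literature, wrapped behind one
interface so their estimates can be compared, unit-safely, against the
thickness-layer estimate of the screening tool:

* diffusion-layer — the substance within the mean diffusion travel distance
  sqrt(4 D t / pi) of the article surface is emitted and transfers to skin
  without resistance (equivalently, the exact perfect-sink surface-flux
  integral 2 C0 sqrt(D t / pi) of a semi-infinite slab);
* mass-balance — the whole substance content of the contacted article slab
  (C0 x L x area) transfers;
* migration-fraction — C x L x (fraction migrating per time) x time, valid
  only while fraction x time << 1;
* transfer-efficiency — areal material weight x weight fraction x daily
  material-to-skin transfer efficiency x skin area.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import DomainError, MigrationValidityError
from .scenarios import ExposureScenario
from .substances import Substance
from .tra import dermal_daily_dose
from .units import MG_PER_G, S_PER_H

__all__ = [
    "ArticleGeometry",
    "ComparatorEstimate",
    "diffusion_travel_distance",
    "diffusion_layer_emission",
    "mass_balance_dermal",
    "tgd_migration",
    "transfer_efficiency_dermal",
    "compare_models",
]

#: The diffusion-layer model is considered inapplicable above this weight
#: fraction: at higher content the substance itself alters matrix diffusivity.
DIFFUSION_MODEL_MAX_WEIGHT_FRACTION = 0.02


class ArticleGeometry(BaseModel):
    """Slab-like article geometry for the comparator models."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    article_thickness: float = Field(gt=0)  # cm (L)
    article_surface_area: float = Field(gt=0)  # cm2
    skin_contact_area: float = Field(gt=0)  # cm2


@dataclass(frozen=True)
class ComparatorEstimate:
    """One comparator-model dermal estimate, dose-compatible with the
    screening-tool results for ratio reporting."""

    model_name: str
    emitted_mass_per_area: Optional[float]  # mg/cm2
    daily_dose: float  # mg/kg body weight/day
    validity_notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.daily_dose < 0:
            raise DomainError("daily_dose must be >= 0")


def diffusion_travel_distance(diffusion_coefficient: float, time_s: float) -> float:
    """Mean absolute displacement of 1-D diffusion, sqrt(4 D t / pi), cm."""
    if diffusion_coefficient < 0 or time_s < 0:
        raise DomainError("D and t must be >= 0")
    return math.sqrt(4.0 * diffusion_coefficient * time_s / math.pi)


def diffusion_layer_emission(
    article_concentration: float,
    diffusion_coefficient: float,
    contact_time: float,
    geometry: ArticleGeometry,
    deplete_cap: bool = False,
) -> float:
    """Diffusion-layer emission per contact area, mg/cm2.

    emission = C0 * d(t) with d(t) = sqrt(4 D t / pi) capped at the article
    thickness L. Identical to the exact semi-infinite perfect-sink surface
    flux integral 2 C0 sqrt(D t / pi) while d(t) < L. All emitted substance
    is assumed to transfer to skin (no material-skin resistance). With
    ``deplete_cap`` the emission also never exceeds the total content C0 * L
    (redundant with the distance cap for a uniform slab; kept as an explicit
    guard for callers that skip it).

    Parameters are C0 in g/cm3, D in cm2/s, t in s.
    """
    if article_concentration < 0:
        raise DomainError("C0 must be >= 0")
    d = diffusion_travel_distance(diffusion_coefficient, contact_time)
    d = min(d, geometry.article_thickness)
    emission = article_concentration * d * MG_PER_G
    if deplete_cap:
        emission = min(
            emission, article_concentration * geometry.article_thickness * MG_PER_G
        )
    return emission


def mass_balance_dermal(
    article_concentration: float,
    geometry: ArticleGeometry,
    area_basis: str = "skin",
) -> float:
    """Whole-slab mass-balance transfer, mg per event.

    mass = C0 * L * area, with the area either the skin contact area or the
    full article surface area.
    """
    if article_concentration < 0:
        raise DomainError("C0 must be >= 0")
    if area_basis == "skin":
        area = geometry.skin_contact_area
    elif area_basis == "article":
        area = geometry.article_surface_area
    else:
        raise DomainError(f"area_basis must be 'skin' or 'article', got {area_basis!r}")
    return article_concentration * geometry.article_thickness * area * MG_PER_G


def tgd_migration(
    concentration: float,
    thickness: float,
    fraction_migrating_per_time: float,
    exposure_time: float,
) -> tuple[float, bool]:
    """Migration-fraction estimate, g/m2 on skin per event.

    result = C[g/m3] x L[m] x (fraction migrating per hour) x t[h].
    Returns ``(estimate, validity_flag)``; the flag is raised when
    fraction x time >= 0.1 (the linearisation degrades) and the call fails
    outright at fraction x time >= 1 (the formula requires it to be much
    less than 1).
    """
    for name, v in (
        ("concentration", concentration),
        ("thickness", thickness),
        ("fraction_migrating_per_time", fraction_migrating_per_time),
        ("exposure_time", exposure_time),
    ):
        if v < 0:
            raise DomainError(f"{name} must be >= 0")
    migrated_fraction = fraction_migrating_per_time * exposure_time
    if migrated_fraction >= 1:
        raise MigrationValidityError(
            f"fraction migrating x exposure time = {migrated_fraction:.3g} >= 1; "
            "the migration formula requires it to be much less than 1"
        )
    flag = migrated_fraction >= 0.1
    return concentration * thickness * migrated_fraction, flag


def transfer_efficiency_dermal(
    material_areal_weight: float,
    weight_fraction: float,
    daily_transfer_efficiency: float,
    skin_area: float,
) -> float:
    """Impregnated-material transfer estimate, mg/day.

    result = areal weight[g/cm2] x WF x daily transfer efficiency x SA[cm2].
    """
    if not 0 <= daily_transfer_efficiency <= 1:
        raise DomainError(
            f"transfer efficiency must be in [0, 1], got {daily_transfer_efficiency}"
        )
    if material_areal_weight < 0 or weight_fraction < 0 or skin_area < 0:
        raise DomainError("inputs must be >= 0")
    return (
        material_areal_weight
        * weight_fraction
        * daily_transfer_efficiency
        * skin_area
        * MG_PER_G
    )


def _as_daily_dose(mass_mg_per_event: float, scenario: ExposureScenario) -> float:
    return mass_mg_per_event * scenario.events_per_day / scenario.population.body_weight


def compare_models(
    scenario: ExposureScenario,
    substance: Substance,
    geometry: ArticleGeometry,
    *,
    travel_time_s: Optional[float] = None,
    fraction_migrating_per_hour: float = 0.01,
    daily_transfer_efficiency: float = 0.08,
    material_areal_weight: Optional[float] = None,
    deplete_cap: bool = False,
) -> pd.DataFrame:
    """Run all comparator models against the thickness-layer estimate.

    Returns one row per model (plus the reference thickness-layer row) with
    the per-area emission, the daily dose through the scenario population,
    the log10 ratio to the reference estimate, and validity notes. The bulk
    article concentration C0 defaults to contact density x weight fraction
    when the substance record does not carry one; the diffusion travel time
    defaults to the scenario event duration.
    """
    tra = dermal_daily_dose(scenario)
    if tra.daily_dose <= 0:
        raise DomainError("reference dermal estimate is zero; comparison undefined")
    c0 = substance.article_concentration
    if c0 is None:
        c0 = scenario.contact_density * scenario.weight_fraction
    if travel_time_s is None:
        travel_time_s = scenario.event_duration * S_PER_H
    if material_areal_weight is None:
        material_areal_weight = scenario.contact_density * geometry.article_thickness

    rows: list[ComparatorEstimate] = [
        ComparatorEstimate(
            model_name="thickness_layer",
            emitted_mass_per_area=tra.areal_load,
            daily_dose=tra.daily_dose,
            validity_notes=tra.warnings,
        )
    ]

    notes: tuple[str, ...] = ()
    if scenario.weight_fraction > DIFFUSION_MODEL_MAX_WEIGHT_FRACTION:
        notes = (
            f"diffusion model outside applicability: weight fraction "
            f"{scenario.weight_fraction} > {DIFFUSION_MODEL_MAX_WEIGHT_FRACTION}",
        )
    if substance.diffusion_coefficient is None:
        rows.append(
            ComparatorEstimate(
                "diffusion_layer",
                None,
                0.0,
                notes + ("no diffusion coefficient; model skipped",),
            )
        )
    else:
        per_area = diffusion_layer_emission(
            c0,
            substance.diffusion_coefficient,
            travel_time_s,
            geometry,
            deplete_cap=deplete_cap,
        )
        rows.append(
            ComparatorEstimate(
                "diffusion_layer",
                per_area,
                _as_daily_dose(per_area * geometry.skin_contact_area, scenario),
                notes,
            )
        )

    mb = mass_balance_dermal(c0, geometry, area_basis="skin")
    rows.append(
        ComparatorEstimate(
            "mass_balance",
            mb / geometry.skin_contact_area,
            _as_daily_dose(mb, scenario),
            ("whole contacted slab transfers (skin-area basis)",),
        )
    )

    # migration formula works in SI: g/m3, m, per-hour fraction
    tgd_g_m2, tgd_flag = tgd_migration(
        c0 * 1e6,
        geometry.article_thickness / 100.0,
        fraction_migrating_per_hour,
        scenario.event_duration,
    )
    tgd_mg_cm2 = tgd_g_m2 * MG_PER_G / 1e4
    rows.append(
        ComparatorEstimate(
            "tgd_migration",
            tgd_mg_cm2,
            _as_daily_dose(tgd_mg_cm2 * geometry.skin_contact_area, scenario),
            ("fraction x time >= 0.1: linearisation degraded",) if tgd_flag else (),
        )
    )

    te = transfer_efficiency_dermal(
        material_areal_weight,
        scenario.weight_fraction,
        daily_transfer_efficiency,
        geometry.skin_contact_area,
    )
    rows.append(
        ComparatorEstimate(
            "transfer_efficiency",
            te / geometry.skin_contact_area,
            te / scenario.population.body_weight,
            (),
        )
    )

    table = pd.DataFrame(
        {
            "model_name": [r.model_name for r in rows],
            "emitted_mass_per_area_mg_cm2": [r.emitted_mass_per_area for r in rows],
            "daily_dose_mg_kg_day": [r.daily_dose for r in rows],
            "validity_notes": ["; ".join(r.validity_notes) for r in rows],
        }
    )
    table["log10_ratio_to_reference"] = [
        math.log10(d / tra.daily_dose) if d > 0 else -math.inf
        for d in table["daily_dose_mg_kg_day"]
    ]
    return table
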