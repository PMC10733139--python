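"""Exposure scenarios, the scenario-defaults registry, and overrides.

A scenario bundles every determinant of the three route equations for one
product (PC) or article (AC) use category: use amount, weight fraction,
room volume, durations, skin contact area, thickness layer, ingested
amount, and the exposed population. Scenario defaults live in a registry
keyed by category code; refined values (SCED-style) are applied through
:class:`OverrideSet` so that every replaced field is recorded and travels
into result provenance.
"""
from __future__ import annotations

import difflib
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import RegistryFormatError, UnknownScenarioError
from .substances import Population

#: Provenance tags for registry entries / fields.
ProvenanceTag = Literal["printed-in-paper", "fixture-nonauthoritative", "user"]

#: Thickness-layer values used without an explicit override: 0.01 cm for
#: liquids (and articles with prolonged/moist contact), 0.001 cm otherwise.
STANDARD_THICKNESS_LAYERS = (0.01, 0.001)


class ExposureScenario(BaseModel):
    """One consumer use scenario (all quantities per event unless noted).

    Attributes
    ----------
    category_code : str
        PC/AC code plus subcategory, e.g. ``"AC13-plastic-flooring"``.
    scenario_class : {"product", "article"}
    is_aerosol : bool
        Aerosol products release 100% of the substance to air regardless of
        volatility, and the saturated-vapor cap does not apply.
    product_amount : float
        Amount of product used per event A, g.
    weight_fraction : float
        Substance weight fraction in the product WF, 0-1.
    room_volume : float
        Room volume V, m3 (default 20).
    dilution_fraction : float
        Multiplicative dilution factor on the air concentration for
        unventilated air flow between rooms, 0-1 (default 1).
    event_duration : float
        Exposure event duration t, h.
    events_per_day : float
        Use events per day n (default 1, daily use).
    skin_contact_area : float
        Exposed skin area SA, cm2.
    thickness_layer : float
        Assumed uniform product/article layer thickness in skin contact
        TL, cm (0.01 liquids, 0.001 most articles).
    contact_density : float
        Density of the layer in skin contact, g/cm3 (default 1; makes a
        0.01 cm layer carry 10 mg/cm2).
    transfer_factor : float
        Fraction of the contact-layer (or mouthed) substance transferred
        TF, 0-1 (default 1).
    ingested_amount : float
        Material ingested per event Q, g.
    mouthed_area : float
        Surface area of the article placed in the mouth, cm2 (default 10).
    population : Population
    applied_overrides : tuple of str
        Provenance records ("field: old -> new [source]") accumulated by
        :func:`apply_overrides`; copied into result provenance.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    category_code: str
    scenario_class: Literal["product", "article"] = "product"
    is_aerosol: bool = False
    product_amount: float = Field(default=0.0, ge=0)  # g/event
    weight_fraction: float = Field(default=1.0, ge=0, le=1)
    room_volume: float = Field(default=20.0, gt=0)  # m3
    dilution_fraction: float = Field(default=1.0, ge=0, le=1)
    event_duration: float = Field(default=1.0, ge=0)  # h
    events_per_day: float = Field(default=1.0, ge=0)
    skin_contact_area: float = Field(default=0.0, ge=0)  # cm2
    thickness_layer: float = Field(default=0.01, gt=0)  # cm
    contact_density: float = Field(default=1.0, gt=0)  # g/cm3
    transfer_factor: float = Field(default=1.0, ge=0, le=1)
    ingested_amount: float = Field(default=0.0, ge=0)  # g/event
    mouthed_area: float = Field(default=10.0, ge=0)  # cm2
    population: Population = Field(default_factory=Population)
    applied_overrides: tuple[str, ...] = Field(default=(), exclude=True)

    @property
    def available_substance_mass_mg(self) -> float:
        """Substance mass in the product used per event, A x WF, mg."""
        return self.product_amount * self.weight_fraction * 1000.0


class OverrideSet(BaseModel):
    """SCED-style field replacements for one scenario code.

    ``replacements`` maps scenario field names to new values; the source
    label identifies where the refined values came from.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    category_code: str
    replacements: dict[str, object] = Field(default_factory=dict)
    source: str = "user"

    @model_validator(mode="after")
    def _known_fields(self) -> "OverrideSet":
        unknown = set(self.replacements) - set(ExposureScenario.model_fields)
        unknown -= {"body_weight", "inhalation_rate"}
        if unknown:
            raise ValueError(f"override names unknown fields: {sorted(unknown)}")
        return self


def apply_overrides(
    scenario: ExposureScenario, overrides: OverrideSet
) -> ExposureScenario:
    """Return a new scenario with the override fields replaced.

    Unmentioned fields are unchanged. Each replacement is recorded in
    ``applied_overrides`` as ``"field: old -> new [source]"``; replacing a
    field with its current value leaves no record, which makes application
    idempotent. Replacement values must satisfy the scenario invariants.
    """
    if overrides.category_code != scenario.category_code:
        raise ValueError(
            f"override targets {overrides.category_code!r}, "
            f"scenario is {scenario.category_code!r}"
        )
    updates: dict[str, object] = {}
    records: list[str] = []
    pop_updates: dict[str, object] = {}
    for field, value in sorted(overrides.replacements.items()):
        if field in ("body_weight", "inhalation_rate"):
            old = getattr(scenario.population, field)
            if old != value:
                pop_updates[field] = value
                records.append(f"{field}: {old} -> {value} [{overrides.source}]")
            continue
        old = getattr(scenario, field)
        if old != value:
            updates[field] = value
            records.append(f"{field}: {old} -> {value} [{overrides.source}]")
    if pop_updates:
        updates["population"] = Population(
            **{**scenario.population.model_dump(), **pop_updates}
        )
    if not records:
        return scenario
    updates["applied_overrides"] = scenario.applied_overrides + tuple(records)
    # model_copy(update=...) skips validation on pydantic v2; rebuild instead
    data = scenario.model_dump()
    data["applied_overrides"] = updates.pop("applied_overrides")
    data.update(updates)
    if "population" not in updates:
        data["population"] = scenario.population
    return ExposureScenario(**data)


class RegistryEntry(BaseModel):
    """A scenario plus provenance: one default tag for the entry and
    optional per-field tags (e.g. a literature-anchored weight fraction inside an
    otherwise synthetic fixture entry)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    scenario: ExposureScenario
    provenance: ProvenanceTag = "user"
    field_provenance: dict[str, ProvenanceTag] = Field(default_factory=dict)

    def tag_for(self, field: str) -> ProvenanceTag:
        return self.field_provenance.get(field, self.provenance)


class ScenarioRegistry(BaseModel):
    """Mapping of category codes to scenario defaults with provenance."""

    model_config = ConfigDict(extra="forbid")

    entries: dict[str, RegistryEntry] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _codes_consistent(self) -> "ScenarioRegistry":
        for code, entry in self.entries.items():
            if entry.scenario.category_code != code:
                raise ValueError(
                    f"registry key {code!r} != scenario code "
                    f"{entry.scenario.category_code!r}"
                )
        return self

    def __len__(self) -> int:
        return len(self.entries)

    def codes(self) -> list[str]:
        return sorted(self.entries)

    def get(self, code: str) -> ExposureScenario:
        """Scenario defaults for ``code``; unknown codes raise with the
        nearest matching codes listed."""
        try:
            return self.entries[code].scenario
        except KeyError:
            suggestions = difflib.get_close_matches(code, self.entries, n=3, cutoff=0.3)
            raise UnknownScenarioError(code, suggestions) from None


# ---------------------------------------------------------------------------
# serialisation

_SCENARIO_CSV_COLUMNS = {
    "category_code": "category_code",
    "scenario_class": "scenario_class",
    "is_aerosol": "is_aerosol",
    "product_amount_g": "product_amount",
    "weight_fraction": "weight_fraction",
    "room_volume_m3": "room_volume",
    "dilution_fraction": "dilution_fraction",
    "event_duration_h": "event_duration",
    "events_per_day": "events_per_day",
    "skin_contact_area_cm2": "skin_contact_area",
    "thickness_layer_cm": "thickness_layer",
    "contact_density_g_cm3": "contact_density",
    "transfer_factor": "transfer_factor",
    "ingested_amount_g": "ingested_amount",
    "mouthed_area_cm2": "mouthed_area",
}
_POP_CSV_COLUMNS = {
    "population_label": "label",
    "body_weight_kg": "body_weight",
    "inhalation_rate_m3_h": "inhalation_rate",
}


def _entry_to_mapping(entry: RegistryEntry) -> dict:
    d = entry.scenario.model_dump()
    d.pop("applied_overrides", None)
    d["provenance"] = entry.provenance
    if entry.field_provenance:
        d["field_provenance"] = dict(entry.field_provenance)
    return d


def _entry_from_mapping(code: str, mapping: dict) -> RegistryEntry:
    data = dict(mapping)
    data.setdefault("category_code", code)
    provenance = data.pop("provenance", "user")
    field_provenance = data.pop("field_provenance", {})
    try:
        scenario = ExposureScenario(**data)
    except Exception as exc:  # pydantic ValidationError carries field names
        raise RegistryFormatError(f"registry entry {code!r} invalid: {exc}") from exc
    return RegistryEntry(
        scenario=scenario, provenance=provenance, field_provenance=field_provenance
    )


def load_registry(path: str | Path, format: str | None = None) -> ScenarioRegistry:
    """Load a scenario registry from CSV, YAML or JSON.

    The format is taken from the extension unless given explicitly. Unknown
    columns/keys are rejected with a message naming them; entries violating
    scenario invariants raise :class:`RegistryFormatError` naming the entry.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryFormatError(f"registry file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("yaml", "yml", "json"):
        try:
            raw = (
                json.loads(path.read_text())
                if fmt == "json"
                else yaml.safe_load(path.read_text())
            )
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise RegistryFormatError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict) or "scenarios" not in raw:
            raise RegistryFormatError(f"{path}: expected a top-level 'scenarios' map")
        entries = {
            code: _entry_from_mapping(code, mapping)
            for code, mapping in raw["scenarios"].items()
        }
        return ScenarioRegistry(entries=entries)
    if fmt == "csv":
        frame = pd.read_csv(path, float_precision="round_trip")
        known = set(_SCENARIO_CSV_COLUMNS) | set(_POP_CSV_COLUMNS) | {"provenance"}
        unknown = set(frame.columns) - known
        if unknown:
            raise RegistryFormatError(
                f"{path}: unknown columns {sorted(unknown)}; expected {sorted(known)}"
            )
        if "category_code" not in frame.columns:
            raise RegistryFormatError(f"{path}: missing required column category_code")
        entries = {}
        for _, row in frame.iterrows():
            data: dict[str, object] = {}
            for col, field in _SCENARIO_CSV_COLUMNS.items():
                if col in frame.columns and pd.notna(row[col]):
                    data[field] = row[col]
            pop = {}
            for col, field in _POP_CSV_COLUMNS.items():
                if col in frame.columns and pd.notna(row[col]):
                    pop[field] = row[col]
            if pop:
                data["population"] = pop
            if "provenance" in frame.columns and pd.notna(row.get("provenance")):
                data["provenance"] = row["provenance"]
            code = str(data["category_code"])
            entries[code] = _entry_from_mapping(code, data)
        return ScenarioRegistry(entries=entries)
    raise RegistryFormatError(f"unsupported registry format {fmt!r}")


def save_registry(
    registry: ScenarioRegistry, path: str | Path, format: str | None = None
) -> None:
    """Write a registry as CSV, YAML or JSON (inverse of :func:`load_registry`).

    CSV flattens the population columns and keeps only the entry-level
    provenance tag; YAML/JSON round-trip per-field provenance as well.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("yaml", "yml", "json"):
        payload = {
            "scenarios": {
                code: _entry_to_mapping(entry)
                for code, entry in sorted(registry.entries.items())
            }
        }
        if fmt == "json":
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return
    if fmt == "csv":
        rows = []
        for code, entry in sorted(registry.entries.items()):
            d = entry.scenario.model_dump()
            row = {col: d[field] for col, field in _SCENARIO_CSV_COLUMNS.items()}
            for col, field in _POP_CSV_COLUMNS.items():
                row[col] = getattr(entry.scenario.population, field)
            row["provenance"] = entry.provenance
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
        return
    raise RegistryFormatError(f"unsupported registry format {fmt!r}")


def default_registry() -> ScenarioRegistry:
    """The bundled scenario-defaults registry.

    Only values printed in the main benchmarking literature are tagged
    ``printed-in-paper``; everything else is a synthetic, clearly
    non-authoritative fixture (tag ``fixture-nonauthoritative``).
    """
    from importlib import resources

    with resources.as_file(
        resources.files("tra_consumer.data") / "scenario_defaults.yaml"
    ) as p:
        return load_registry(p, format="yaml")
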