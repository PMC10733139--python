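"""Run configuration, report tables and report files.

Reports are plain CSV/JSON tables with one row per scenario/substance/route
plus a total row. Reported values are rounded to three significant figures;
everything upstream keeps full precision. The log (stderr) records every
default taken, override applied, cap bound and flag raised, so each number
in a report can be traced back to its inputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import RegistryFormatError
from .scenarios import (
    OverrideSet,
    ScenarioRegistry,
    apply_overrides,
    default_registry,
    load_registry,
)
from .substances import ADULT, CHILD, Substance, load_substances
from .tra import ExposureResult, TotalExposure, assess_scenario, total_exposure
from .units import round_sig

log = logging.getLogger("tra_consumer")

__all__ = ["RunConfig", "run_assessment", "results_frame", "write_report"]


class RunConfig(BaseModel):
    """Configuration for one assessment run."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    scenario_codes: tuple[str, ...]
    substance_file: Path
    registry_file: Optional[Path] = None
    override_files: tuple[Path, ...] = ()
    population: Optional[Literal["adult", "child"]] = None
    out_dir: Path = Path(".")
    output_format: Literal["csv", "json", "both"] = "csv"
    rounding_digits: int = Field(default=3, ge=1)

    def registry(self) -> ScenarioRegistry:
        if self.registry_file is None:
            log.info("using bundled fixture registry (non-authoritative defaults)")
            return default_registry()
        return load_registry(self.registry_file)


def _load_override_sets(paths: tuple[Path, ...]) -> list[OverrideSet]:
    out = []
    for p in paths:
        raw = json.loads(Path(p).read_text())
        records = raw if isinstance(raw, list) else [raw]
        for r in records:
            out.append(OverrideSet(**r))
    return out


def results_frame(
    results: list[ExposureResult], total: Optional[TotalExposure] = None
) -> pd.DataFrame:
    """Tabulate route results (+ optional total row) as a DataFrame."""
    rows = []
    for r in results:
        rows.append(
            {
                "category_code": r.category_code,
                "route": r.route,
                "event_air_concentration_mg_m3": r.event_air_concentration,
                "daily_dose_mg_kg_day": r.daily_dose,
                "caps_applied": ";".join(r.caps_applied),
                "provenance": ";".join(r.provenance),
            }
        )
    if total is not None and results:
        rows.append(
            {
                "category_code": results[0].category_code,
                "route": "total",
                "event_air_concentration_mg_m3": None,
                "daily_dose_mg_kg_day": total.daily_dose,
                "caps_applied": "",
                "provenance": (
                    "mass_balance_exceeded"
                    if total.mass_balance_exceeded
                    else (
                        ""
                        if total.mass_balance_exceeded is None
                        else "mass_balance_ok"
                    )
                ),
            }
        )
    return pd.DataFrame(rows)


def write_report(
    frame: pd.DataFrame,
    out_path: Path,
    output_format: str = "csv",
    rounding_digits: int = 3,
) -> list[Path]:
    """Write a report table as CSV and/or JSON with fixed rounding.

    CSV and JSON carry identical (rounded) values; repeated runs of the same
    inputs are byte-identical.
    """
    frame = frame.copy()
    for col in frame.columns:
        if pd.api.types.is_float_dtype(frame[col]):
            frame[col] = frame[col].map(
                lambda x: round_sig(x, rounding_digits) if pd.notna(x) else None
            )
    written = []
    if output_format in ("csv", "both"):
        p = out_path.with_suffix(".csv")
        frame.to_csv(p, index=False)
        written.append(p)
    if output_format in ("json", "both"):
        p = out_path.with_suffix(".json")
        payload = frame.where(pd.notna(frame), None).to_dict(orient="records")
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)
    for p in written:
        log.info("wrote %s", p)
    return written


def run_assessment(config: RunConfig) -> list[Path]:
    """Run route assessments for every scenario/substance pair in ``config``.

    Writes one report file set per scenario (three route rows where
    applicable plus a total row per substance) into ``config.out_dir`` and
    returns the written paths.
    """
    registry = config.registry()
    substances = load_substances(config.substance_file)
    if not substances:
        raise RegistryFormatError(f"no substances in {config.substance_file}")
    overrides = _load_override_sets(config.override_files)
    config.out_dir.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    for code in config.scenario_codes:
        scenario = registry.get(code)  # raises with suggestions when unknown
        for ov in overrides:
            if ov.category_code == code:
                scenario = apply_overrides(scenario, ov)
                log.info("applied overrides to %s: %s", code, ov.replacements)
        if config.population is not None:
            pop = ADULT if config.population == "adult" else CHILD
            scenario = scenario.model_copy(update={"population": pop})
            log.info("population forced to %s", config.population)
        frames = []
        for substance in substances:
            log.info(
                "assessing %s with %s (VP=%g Pa, MW=%g g/mol)",
                code,
                substance.name,
                substance.vapor_pressure,
                substance.molecular_weight,
            )
            results = assess_scenario(scenario, substance)
            for r in results:
                if r.caps_applied:
                    log.info("%s/%s: caps %s", code, r.route, r.caps_applied)
            total = total_exposure(results)
            if total.mass_balance_exceeded:
                log.info("%s: mass balance exceeded (reported, not corrected)", code)
            frame = results_frame(results, total)
            frame.insert(1, "substance", substance.name)
            frames.append(frame)
        report = pd.concat(frames, ignore_index=True)
        safe = code.replace("/", "_")
        written += write_report(
            report,
            config.out_dir / f"assessment_{safe}",
            config.output_format,
            config.rounding_digits,
        )
    return written
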