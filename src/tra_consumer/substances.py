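"""Substance and population records.

A :class:`Substance` carries the physicochemical properties that drive the
screening algorithms: vapor pressure selects the volatility band and sets the
saturated vapor concentration; molecular weight enters the ideal-gas
conversion; density, diffusion coefficient and bulk article concentration
feed the article comparator models only.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import DomainError, RegistryFormatError


class Substance(BaseModel):
    """Physicochemical record for one substance.

    Parameters
    ----------
    name : str
        Display name.
    molecular_weight : float
        Molar mass, g/mol. Must be positive.
    vapor_pressure : float
        Vapor pressure at ambient temperature, Pa. Non-negative.
    density : float, optional
        Bulk density, g/cm3.
    diffusion_coefficient : float, optional
        Diffusion coefficient in the article matrix, cm2/s
        (comparator models only).
    article_concentration : float, optional
        Substance concentration in the article matrix C0, g/cm3
        (comparator models only).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    molecular_weight: float = Field(gt=0)
    vapor_pressure: float = Field(ge=0)
    density: Optional[float] = Field(default=None, gt=0)
    diffusion_coefficient: Optional[float] = Field(default=None, ge=0)
    article_concentration: Optional[float] = Field(default=None, ge=0)


class Population(BaseModel):
    """Exposed population: body weight and inhalation rate.

    Default body weights are 60 kg (adult) and 10 kg (child). Inhalation
    rates are fixture values (light-activity scale) and are not anchored to
    any authoritative default.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    label: Literal["adult", "child"] = "adult"
    body_weight: float = Field(default=60.0, gt=0)  # kg
    inhalation_rate: float = Field(default=1.0, gt=0)  # m3/h


ADULT = Population(label="adult", body_weight=60.0, inhalation_rate=1.0)
CHILD = Population(label="child", body_weight=10.0, inhalation_rate=0.5)


def generate_fixture_substances(count: int, seed: int) -> list[Substance]:
    """Generate ``count`` synthetic substances for fixtures and sweeps.

    Vapor pressures are drawn log-uniformly over 1e-6 to 1e5 Pa so that all
    four volatility bands are exercised; molecular weights, densities and
    diffusion coefficients span ranges typical of organic product
    ingredients and article additives. Deterministic for a fixed seed.
    """
    if count < 1:
        raise DomainError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    vps = 10.0 ** rng.uniform(-6.0, 5.0, size=count)
    mws = rng.uniform(50.0, 500.0, size=count)
    rhos = rng.uniform(0.8, 1.5, size=count)
    ds = 10.0 ** rng.uniform(-14.0, -6.0, size=count)
    out = []
    for i in range(count):
        out.append(
            Substance(
                name=f"FIX-{i:03d}",
                molecular_weight=float(mws[i]),
                vapor_pressure=float(vps[i]),
                density=float(rhos[i]),
                diffusion_coefficient=float(ds[i]),
                article_concentration=float(rhos[i] * 0.1),
            )
        )
    return out


_CSV_COLUMNS = {
    "name": "name",
    "molecular_weight_g_mol": "molecular_weight",
    "vapor_pressure_pa": "vapor_pressure",
    "density_g_cm3": "density",
    "diffusion_coefficient_cm2_s": "diffusion_coefficient",
    "article_concentration_g_cm3": "article_concentration",
}


def substances_to_frame(substances: list[Substance]) -> pd.DataFrame:
    rows = []
    for s in substances:
        d = s.model_dump()
        rows.append({col: d[field] for col, field in _CSV_COLUMNS.items()})
    return pd.DataFrame(rows)


def write_substances(substances: list[Substance], path: str | Path) -> None:
    """Write substances as CSV (unit-suffixed headers) or JSON by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps([s.model_dump() for s in substances], indent=2) + "\n"
        )
    else:
        # %.17g round-trips doubles exactly through text
        substances_to_frame(substances).to_csv(path, index=False, float_format="%.17g")


def load_substances(path: str | Path) -> list[Substance]:
    """Load substances from CSV (unit-suffixed headers) or JSON."""
    path = Path(path)
    if not path.exists():
        raise RegistryFormatError(f"substance file not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [Substance(**r) for r in records]
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = {"name", "molecular_weight_g_mol", "vapor_pressure_pa"} - set(
        frame.columns
    )
    if missing:
        raise RegistryFormatError(
            f"substance CSV {path} misses required columns: {sorted(missing)}"
        )
    out = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col, field in _CSV_COLUMNS.items():
            if col in frame.columns and pd.notna(row[col]):
                kwargs[field] = row[col]
        out.append(Substance(**kwargs))
    return out
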