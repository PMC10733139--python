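"""Inhalation comparators: ventilated box model and evaporation simulator.

Two mechanistic references against which the banded instantaneous-release
fractions can be benchmarked:

* a one-box, well-mixed room with air exchange, into which the substance is
  released instantaneously — its event-average concentration has the closed
  form m/(V q T) (1 - exp(-q T));
* an evaporation-limited emission simulator — a thin applied film loses mass
  at the Langmuir-type rate k_m A_s (SVC - C) into the ventilated box, and
  the fraction of the film evaporated within the event is the mechanistic
  release fraction.

The sweep harness contrasts the banded fraction with the mechanistic one
over a vapor-pressure grid; with screening-conservative settings the banded
fraction bounds the mechanistic one everywhere, with the log-gap growing as
vapor pressure falls below the lowest-band cutoff.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.integrate import solve_ivp

from .errors import NumericalError
from .substances import Substance
from .tra import assign_vp_band, saturated_vapor_concentration
from .units import DEFAULT_TEMPERATURE_K, M2_PER_CM2

__all__ = [
    "BoxModelSpec",
    "EvaporationSpec",
    "box_event_average",
    "simulate_evaporation",
    "evaporation_release_fraction",
    "vp_sweep",
    "DEFAULT_VP_GRID",
]


class BoxModelSpec(BaseModel):
    """Well-mixed one-box room with air exchange."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    room_volume: float = Field(default=20.0, gt=0)  # m3 (V)
    air_exchange_rate: float = Field(default=0.5, ge=0)  # 1/h (q)
    event_duration: float = Field(default=2.0, gt=0)  # h (T)


class EvaporationSpec(BaseModel):
    """Applied film and mass-transfer settings for the evaporation simulator.

    Defaults sketch a wall-painting-like application (2 m2 of film carrying
    500 g of substance) with an indoor-scale mass-transfer coefficient; they
    are fixture values, not authoritative scenario defaults.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    applied_film_area: float = Field(default=20000.0, gt=0)  # cm2 (A_s)
    film_mass: float = Field(default=5.0e5, gt=0)  # mg of substance
    mass_transfer_coefficient: float = Field(default=1.0, gt=0)  # m/h (k_m)
    temperature: float = Field(default=DEFAULT_TEMPERATURE_K, gt=0)  # K


def box_event_average(released_mass: float, spec: BoxModelSpec) -> float:
    """Event-average concentration after instantaneous release, mg/m3.

    C_avg = m/(V q T) (1 - exp(-q T)); the q -> 0 limit is m/V.
    """
    if released_mass < 0:
        raise ValueError("released mass must be >= 0")
    m, v, q, t = (
        released_mass,
        spec.room_volume,
        spec.air_exchange_rate,
        spec.event_duration,
    )
    qt = q * t
    if qt < 1e-12:
        return m / v
    return m / (v * qt) * -math.expm1(-qt)


def simulate_evaporation(
    substance: Substance,
    spec: EvaporationSpec,
    box: BoxModelSpec,
    rtol: float = 1e-8,
    t_eval: Optional[np.ndarray] = None,
):
    """Integrate the coupled film/room system over the event.

    State (mg): film mass m_f, airborne mass m_a, vented mass m_v, with

        dm_f/dt = -k_m A_s (SVC - C),   C = m_a / V
        dm_a/dt = +k_m A_s (SVC - C) - q m_a
        dm_v/dt = +q m_a

    Evaporation stops (terminal event) when the film is exhausted. The
    airborne concentration approaches SVC from below, so the flux stays
    non-negative. Total mass m_f + m_a + m_v is conserved exactly by
    construction; the integrator preserves it to its tolerance.

    Returns the scipy solution object augmented with ``initial_mass``.
    """
    svc = saturated_vapor_concentration(substance, spec.temperature)
    k_a = spec.mass_transfer_coefficient * spec.applied_film_area * M2_PER_CM2  # m3/h
    v, q = box.room_volume, box.air_exchange_rate
    m0 = spec.film_mass

    def rhs(t, y):
        m_f, m_a, m_v = y
        flux = k_a * (svc - m_a / v)  # mg/h
        if m_f <= 0:
            flux = min(flux, 0.0)
        return (-flux, flux - q * m_a, q * m_a)

    def film_exhausted(t, y):
        return y[0]

    film_exhausted.terminal = True
    film_exhausted.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, box.event_duration),
        (m0, 0.0, 0.0),
        method="LSODA",
        rtol=rtol,
        atol=rtol * m0,
        events=film_exhausted,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        raise NumericalError(f"evaporation integration failed: {sol.message}")
    sol.initial_mass = m0
    return sol


def evaporation_release_fraction(
    substance: Substance,
    spec: EvaporationSpec,
    box: BoxModelSpec,
    rtol: float = 1e-8,
) -> float:
    """Fraction of the applied film evaporated within the event, in [0, 1]."""
    if substance.vapor_pressure == 0:
        return 0.0
    sol = simulate_evaporation(substance, spec, box, rtol=rtol)
    if sol.status == 1:  # film exhausted before the event ended
        return 1.0
    evaporated = sol.initial_mass - sol.y[0, -1]
    return float(min(max(evaporated / sol.initial_mass, 0.0), 1.0))


#: Default sweep grid: 25 log-spaced vapor pressures over 1e-3 to 1e3 Pa.
DEFAULT_VP_GRID = np.logspace(-3, 3, 25)


def vp_sweep(
    substance_template: Substance,
    vp_grid,
    spec: EvaporationSpec,
    box: BoxModelSpec,
) -> pd.DataFrame:
    """Banded vs mechanistic release fractions over a vapor-pressure grid.

    Returns columns ``vp_pa``, ``tra_fraction`` (band release fraction),
    ``mechanistic_fraction`` (evaporation simulator) and ``log10_diff``
    (band minus mechanistic, in orders of magnitude; +inf where the
    mechanistic fraction underflows to zero).
    """
    vp_grid = np.asarray(list(vp_grid), dtype=float)
    if vp_grid.size == 0:
        raise ValueError("vp_grid must be non-empty")
    rows = []
    for vp in vp_grid:
        sub = substance_template.model_copy(update={"vapor_pressure": float(vp)})
        tra_f = assign_vp_band(vp).release_fraction
        mech_f = evaporation_release_fraction(sub, spec, box)
        log_diff = (
            math.log10(tra_f) - math.log10(mech_f) if mech_f > 0 else math.inf
        )
        rows.append(
            {
                "vp_pa": float(vp),
                "tra_fraction": tra_f,
                "mechanistic_fraction": mech_f,
                "log10_diff": log_diff,
            }
        )
    return pd.DataFrame(rows)
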