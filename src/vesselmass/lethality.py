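"""Harness feeding length-derived vessel masses to a strike-lethality model.

Biophysical whale-strike models take an impact area (m²), vessel mass (kg)
and speed (m/s) and return a probability that the collision is lethal.  The
harness reproduces the standard demonstration design — a grid of vessel
types × lengths × transit speeds, with a constant flared-bow impact area —
computing each cell's mass from length overall via the published power laws
and delegating the lethality computation to any callable satisfying the
:class:`LethalityModelContract`.  The external biophysical simulation itself
is deliberately not reimplemented here; a documented toy model is provided
so the plumbing is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolationError
from .published import estimate_mass_published, load_published_bundle
from .units import KNOT_MS
from .vessel_model import VesselType

__all__ = [
    "LethalityScenario",
    "LethalityModelContract",
    "run_scenario",
    "toy_lethality_model",
    "DEFAULT_SCENARIO_TYPES",
]

#: The six demonstration types: two large commercial, two mid-size
#: passenger, two small-craft categories.
DEFAULT_SCENARIO_TYPES = (
    VesselType.CONTAINER_SHIP,
    VesselType.CRUISE,
    VesselType.FERRY,
    VesselType.PLEASURE_CRAFT,
    VesselType.SAILING,
    VesselType.TUG,
)

#: (mass_kg, speed_m_per_s, impact_area_m2, whale_model) -> probability in [0, 1]
LethalityModelContract = Callable[[float, float, float, str], float]


@dataclass(frozen=True)
class LethalityScenario:
    """A types × LOA × speed grid with a constant bow impact area.

    Defaults follow the standard demonstration: six vessel types, LOA of
    10/20/50/100 m, transit speeds of 10 and 20 kn, and a 1.15 m × 1.15 m
    flared-bow impact patch held constant across vessel sizes, evaluated
    against an adult North Atlantic right whale.
    """

    vessel_types: tuple[VesselType, ...] = DEFAULT_SCENARIO_TYPES
    loa_values_m: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0)
    speeds_kn: tuple[float, ...] = (10.0, 20.0)
    impact_width_m: float = 1.15
    impact_height_m: float = 1.15
    whale_model: str = "adult North Atlantic right whale"

    def __post_init__(self):
        if any(v <= 0 for v in self.loa_values_m):
            raise ValueError("LOA values must be positive")
        if any(v <= 0 for v in self.speeds_kn):
            raise ValueError("speeds must be positive")
        if self.impact_width_m <= 0 or self.impact_height_m <= 0:
            raise ValueError("impact dimensions must be positive")

    @property
    def impact_area_m2(self) -> float:
        return self.impact_width_m * self.impact_height_m


def run_scenario(
    scenario: LethalityScenario | None = None,
    model: LethalityModelContract | None = None,
    mass_estimator: Optional[Callable[[VesselType, float], float]] = None,
    model_label: str | None = None,
) -> pd.DataFrame:
    """Evaluate the lethality model over the scenario grid.

    Parameters
    ----------
    scenario : LethalityScenario, optional
        Defaults to the standard demonstration grid (48 cells).
    model : callable
        Satisfies :data:`LethalityModelContract`; defaults to the documented
        :func:`toy_lethality_model` (labelled "toy" in the output).
    mass_estimator : callable (vessel_type, loa_m) -> kg, optional
        Defaults to the published power-law equations.

    Returns
    -------
    DataFrame with one row per (type, LOA, speed) cell: the derived mass,
    the speed in m/s, the impact area and the model's probability.
    """
    scenario = scenario or LethalityScenario()
    if model is None:
        model = toy_lethality_model
        model_label = model_label or "toy"
    model_label = model_label or getattr(model, "__name__", "custom")
    if mass_estimator is None:
        bundle = load_published_bundle()
        mass_estimator = lambda t, loa: estimate_mass_published(t, loa, bundle)

    rows = []
    for vtype in scenario.vessel_types:
        for loa in scenario.loa_values_m:
            mass = mass_estimator(vtype, loa)
            for speed_kn in scenario.speeds_kn:
                speed_ms = speed_kn * KNOT_MS
                p = model(mass, speed_ms, scenario.impact_area_m2, scenario.whale_model)
                if not (0.0 <= p <= 1.0):
                    raise ContractViolationError(
                        f"model {model_label!r} returned {p} outside [0, 1] for "
                        f"cell (type={vtype.value}, loa={loa}, speed={speed_kn} kn)"
                    )
                rows.append(
                    {
                        "vessel_type": vtype.value,
                        "loa_m": loa,
                        "speed_kn": speed_kn,
                        "speed_m_per_s": speed_ms,
                        "mass_kg": mass,
                        "impact_area_m2": scenario.impact_area_m2,
                        "whale_model": scenario.whale_model,
                        "lethality_model": model_label,
                        "probability": p,
                    }
                )
    return pd.DataFrame(rows)


#: toy model shape parameters: logistic in ln(mass) and speed.
_TOY_MASS_COEF = 0.75
_TOY_SPEED_COEF = 0.5
_TOY_OFFSET = -10.0


def toy_lethality_model(
    mass_kg: float, speed_m_per_s: float, impact_area_m2: float, whale_model: str = ""
) -> float:
    """A documented stand-in lethality model for testing the harness.

    Logistic in log-mass and speed::

        p = 1 / (1 + exp(-(0.75 * ln(mass_kg) + 0.5 * v - 10)))

    Deterministic, strictly increasing in mass and speed, upper asymptote 1
    as mass → ∞, and at speed 0 it returns the documented floor
    ``expit(0.75 ln m - 10)``.  The impact area and whale tag are accepted
    for contract compatibility but do not enter the toy formula.  This is
    NOT a biophysical collision model and must never be used for actual
    risk assessment; outputs are labelled "toy" by the harness.
    """
    if mass_kg <= 0 or speed_m_per_s < 0 or impact_area_m2 <= 0:
        raise ValueError("mass and impact area must be > 0, speed >= 0")
    eta = _TOY_MASS_COEF * np.log(mass_kg) + _TOY_SPEED_COEF * speed_m_per_s + _TOY_OFFSET
    return float(1.0 / (1.0 + np.exp(-eta)))
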