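"""Seeded synthetic fleets with the statistical structure of the study data.

The generator emulates a mixed AIS/catalogue vessel sample: per type, LOA is
drawn from a truncated normal parameterised by the observed mean, SD and
range, and mass follows the type's power law with multiplicative log-normal
noise,

    mass = multiplier * LOA^exponent * exp(eps),   eps ~ N(0, sigma_log^2).

Records flagged as AIS-sourced carry a deadweight tonnage (obtained by
inverting the type's DWT → displacement strategy at the noisy mass), because
static AIS reports DWT, not displacement; catalogue-sourced records carry
the displacement directly.  Fleets are fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml
from scipy import optimize, stats

from .displacement import (
    DwtConversionRule,
    MixedStrategy,
    Strategy,
    StrategyTable,
    load_strategy_table,
    strategy_displacement_kg,
)
from .errors import ConfigurationError
from .published import load_published_bundle
from .regression import PowerLawCoefficients
from .units import TONNE_KG
from .vessel_model import VesselRecord, VesselType

__all__ = ["TypeSampling", "FleetConfig", "default_fleet_config", "generate_fleet", "invert_strategy"]

#: relative tolerance for numeric strategy inversion
_INVERT_RTOL = 1e-9


@dataclass(frozen=True)
class TypeSampling:
    """Sampling specification for one vessel type."""

    n_ais: int
    n_online: int
    loa_min_m: float
    loa_max_m: float
    loa_mean_m: float
    loa_sd_m: float

    @property
    def n_total(self) -> int:
        return self.n_ais + self.n_online

    def __post_init__(self):
        if self.n_ais < 0 or self.n_online < 0:
            raise ConfigurationError("sample sizes must be >= 0")
        if not (self.loa_min_m < self.loa_mean_m < self.loa_max_m):
            raise ConfigurationError(
                f"infeasible truncation: need min < mean < max, got "
                f"({self.loa_min_m}, {self.loa_mean_m}, {self.loa_max_m})"
            )
        if self.loa_sd_m <= 0:
            raise ConfigurationError("loa_sd_m must be > 0")


@dataclass(frozen=True)
class FleetConfig:
    """Full fleet specification: composition, generating law, noise, seed."""

    sampling: Mapping[VesselType, TypeSampling]
    coefficients: PowerLawCoefficients
    sigma_log: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.sigma_log < 0:
            raise ConfigurationError("sigma_log must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(s.n_total for s in self.sampling.values())

    def with_(self, **kwargs) -> "FleetConfig":
        return replace(self, **kwargs)


def default_fleet_config(
    sigma_log: float = 0.2,
    seed: int = 0,
    coefficients: Optional[PowerLawCoefficients] = None,
    path: str | Path | None = None,
) -> FleetConfig:
    """The packaged default composition (873 vessels over twelve types).

    The generating power law defaults to the published coefficient bundle.
    """
    if path is None:
        text = (
            resources.files("vesselmass.data")
            .joinpath("fleet_composition.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        sampling = {
            VesselType(label): TypeSampling(**fields)
            for label, fields in raw["types"].items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed fleet composition: {exc}") from exc
    if coefficients is None:
        coefficients = load_published_bundle().power_law()
    return FleetConfig(
        sampling=sampling, coefficients=coefficients, sigma_log=sigma_log, seed=seed
    )


def invert_strategy(strategy: Strategy, mass_kg: float, loa_m: float | None = None) -> float:
    """DWT (tonnes) whose strategy-converted displacement equals ``mass_kg``.

    Ratio strategies invert analytically; linear, power and mixed strategies
    are inverted numerically on the monotone kg-forward function (Brent's
    method, 1e-9 relative).  Raises if the mass is below the strategy's
    minimum attainable displacement (e.g. a linear rule's offset at DWT=0).
    """
    if isinstance(strategy, DwtConversionRule) and strategy.form == "ratio":
        return mass_kg / (strategy.scale * TONNE_KG)

    def f(dwt: float) -> float:
        return strategy_displacement_kg(strategy, dwt, loa_m=loa_m) - mass_kg

    if f(0.0) > 0:
        raise ValueError(
            f"mass {mass_kg} kg below the strategy's minimum displacement"
        )
    hi = max(mass_kg / TONNE_KG, 1.0)
    while f(hi) < 0:
        hi *= 2.0
    dwt = optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=_INVERT_RTOL)
    return float(dwt)


def generate_fleet(config: FleetConfig | None = None, seed: int | None = None) -> list[VesselRecord]:
    """Draw a reproducible synthetic fleet.

    Per type: LOA ~ truncated normal(mean, sd) on [min, max]; mass from the
    generating power law with multiplicative noise exp(N(0, sigma_log^2)).
    The first ``n_ais`` records of each type are AIS-style (DWT only,
    back-derived through the type's conversion strategy); the rest are
    catalogue-style (displacement only).

    Parameters
    ----------
    config : FleetConfig, optional
        Defaults to :func:`default_fleet_config`.
    seed : int, optional
        Overrides ``config.seed`` when given.
    """
    config = config or default_fleet_config()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    table: StrategyTable = load_strategy_table()

    records: list[VesselRecord] = []
    for vtype in sorted(config.sampling, key=lambda t: t.value):
        spec = config.sampling[vtype]
        if spec.n_total == 0:
            continue
        a = (spec.loa_min_m - spec.loa_mean_m) / spec.loa_sd_m
        b = (spec.loa_max_m - spec.loa_mean_m) / spec.loa_sd_m
        loa = stats.truncnorm.rvs(
            a, b, loc=spec.loa_mean_m, scale=spec.loa_sd_m,
            size=spec.n_total, random_state=rng,
        )
        entry = config.coefficients[vtype]
        eps = (
            rng.normal(0.0, config.sigma_log, size=spec.n_total)
            if config.sigma_log > 0
            else np.zeros(spec.n_total)
        )
        mass = entry.multiplier * loa**entry.exponent * np.exp(eps)
        strategy = table.strategies[vtype]
        for i in range(spec.n_total):
            is_ais = i < spec.n_ais
            rid = f"{vtype.value}-{i + 1:04d}"
            if is_ais:
                try:
                    dwt = invert_strategy(strategy, float(mass[i]), loa_m=float(loa[i]))
                except ValueError:
                    # extreme downward noise can push the mass below a linear
                    # strategy's DWT=0 floor; clamp to an empty-hold vessel
                    dwt = 0.0
                records.append(
                    VesselRecord(
                        record_id=rid, vessel_type=vtype, loa_m=float(loa[i]),
                        dwt_tonnes=dwt, source="ais",
                    )
                )
            else:
                records.append(
                    VesselRecord(
                        record_id=rid, vessel_type=vtype, loa_m=float(loa[i]),
                        displacement_kg=float(mass[i]), source="online",
                    )
                )
    return records
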