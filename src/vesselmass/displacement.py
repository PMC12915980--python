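"""Deadweight-tonnage to displacement conversion.

A vessel's displacement (total mass, kg) is rarely reported directly.  This
module converts the fields that *are* available into a displacement:

* maximum deadweight tonnage (DWT), through a per-type strategy — either a
  published DWT regression (power or linear form, sometimes expressed in
  U.S. customary tons) or the deadweight coefficient ``C_D = DWT / Δ``
  characteristic of a vessel class at a given length;
* light-ship (net) weight, corrected by a per-person mass budget;
* a reported displacement, passed through unchanged.

Heterogeneous categories (government/research, "other") average the
estimates of three strategies, after each has been converted to kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Union

import yaml

from .errors import ConfigurationError, EstimationError
from .units import LUGGAGE_KG, PERSON_KG, TONNE_KG, US_TON_KG
from .vessel_model import VesselRecord, VesselType

__all__ = [
    "DeadweightCoefficientSpec",
    "DwtConversionRule",
    "MixedStrategy",
    "StrategyTable",
    "interpolate_cd",
    "apply_dwt_rule",
    "net_weight_to_displacement",
    "strategy_displacement_kg",
    "estimate_displacement",
    "estimate_fleet",
    "load_strategy_table",
]

_UNIT_KG = {"tonnes": TONNE_KG, "us_tons": US_TON_KG}


@dataclass(frozen=True)
class DeadweightCoefficientSpec:
    """An interpolatable deadweight-coefficient range for a vessel class.

    Two (LOA, C_D) endpoints; the coefficient at intermediate lengths is
    obtained by linear interpolation, clamped to the endpoints outside the
    range.
    """

    vessel_class: str
    loa_lo_m: float
    cd_lo: float
    loa_hi_m: float
    cd_hi: float

    def __post_init__(self):
        if not self.loa_lo_m < self.loa_hi_m:
            raise ConfigurationError(
                f"{self.vessel_class}: loa_lo_m must be < loa_hi_m"
            )
        for cd in (self.cd_lo, self.cd_hi):
            if not 0 < cd < 1:
                raise ConfigurationError(
                    f"{self.vessel_class}: C_D endpoints must lie in (0, 1), got {cd}"
                )


@dataclass(frozen=True)
class DwtConversionRule:
    """One DWT → displacement equation with its unit dialect.

    Functional forms: ``ratio`` Δ = scale·DWT; ``linear`` Δ = scale·DWT +
    offset; ``power`` Δ = scale·DWT^exponent.  The result is in
    ``output_unit`` (metric tonnes or U.S. tons) and is converted to kg by
    :func:`apply_dwt_rule`.  Ratio rules may carry the deadweight coefficient
    ``cd`` they invert and the name of the endpoint range it came from.
    """

    form: Literal["ratio", "linear", "power"]
    scale: float
    output_unit: Literal["tonnes", "us_tons"]
    exponent: Optional[float] = None
    offset: Optional[float] = None
    source_label: str = ""
    cd: Optional[float] = None
    cd_spec: Optional[str] = None

    def __post_init__(self):
        if not self.scale > 0:
            raise ConfigurationError(f"rule scale must be > 0, got {self.scale}")
        if self.form == "power" and self.exponent is None:
            raise ConfigurationError("power rule requires an exponent")
        if self.form == "linear" and self.offset is None:
            raise ConfigurationError("linear rule requires an offset")
        if self.output_unit not in _UNIT_KG:
            raise ConfigurationError(f"unknown output unit {self.output_unit!r}")


@dataclass(frozen=True)
class MixedStrategy:
    """Average of several conversion rules, for heterogeneous categories.

    Each component is evaluated and converted to kg first; the unweighted
    arithmetic mean of the kg values is the estimate.
    """

    components: tuple[DwtConversionRule, ...]
    source_label: str = ""

    def __post_init__(self):
        if len(self.components) < 2:
            raise ConfigurationError("mixed strategy needs >= 2 components")


Strategy = Union[DwtConversionRule, MixedStrategy]


@dataclass(frozen=True)
class StrategyTable:
    """Per-type conversion strategies plus the C_D endpoint ranges."""

    version: str
    cd_specs: Mapping[str, DeadweightCoefficientSpec]
    strategies: Mapping[VesselType, Strategy]
    anchors_loa_m: Mapping[VesselType, float] = field(default_factory=dict)


def interpolate_cd(
    spec: DeadweightCoefficientSpec, loa_m: float, decimals: int | None = 3
) -> float:
    """Deadweight coefficient at ``loa_m`` by linear interpolation.

    LOA outside the endpoint range is clamped to the nearer endpoint. The
    result is rounded to ``decimals`` (default 3, the precision at which
    these class ratios are conventionally quoted); pass ``None`` to skip
    rounding.
    """
    if not loa_m > 0:
        raise ValueError(f"loa_m must be > 0, got {loa_m}")
    if loa_m <= spec.loa_lo_m:
        cd = spec.cd_lo
    elif loa_m >= spec.loa_hi_m:
        cd = spec.cd_hi
    else:
        t = (loa_m - spec.loa_lo_m) / (spec.loa_hi_m - spec.loa_lo_m)
        cd = spec.cd_lo + t * (spec.cd_hi - spec.cd_lo)
    return round(cd, decimals) if decimals is not None else cd


def apply_dwt_rule(rule: DwtConversionRule, dwt: float) -> float:
    """Evaluate a conversion rule at ``dwt`` and return mass in kg.

    ``dwt`` is the deadweight tonnage as reported (tonnes); the rule's
    functional form yields a displacement in ``rule.output_unit``, which is
    then converted to kg (×1000 for tonnes, ×1016 for U.S. tons).
    """
    if dwt < 0:
        raise ValueError(f"dwt must be >= 0, got {dwt}")
    if rule.form == "ratio":
        disp = rule.scale * dwt
    elif rule.form == "linear":
        disp = rule.scale * dwt + rule.offset
    else:  # power
        disp = rule.scale * dwt**rule.exponent
    return disp * _UNIT_KG[rule.output_unit]


def net_weight_to_displacement(
    net_weight_kg: float, capacity_persons: int | None = None
) -> float:
    """Maximum displacement from light-ship weight.

    Adds one person (75 kg) plus one luggage (20 kg) per berth up to the
    maximum capacity; when the capacity is unknown, a single person and
    their luggage are added, since there is at least one person onboard.
    """
    if net_weight_kg < 0:
        raise ValueError(f"net_weight_kg must be >= 0, got {net_weight_kg}")
    if capacity_persons is not None and capacity_persons < 0:
        raise ValueError(f"capacity_persons must be >= 0, got {capacity_persons}")
    per_person = PERSON_KG + LUGGAGE_KG
    n = 1 if capacity_persons is None else capacity_persons
    return net_weight_kg + per_person * n


def _resolve_rule(
    rule: DwtConversionRule,
    loa_m: float | None,
    cd_specs: Mapping[str, DeadweightCoefficientSpec],
    per_record_cd: bool,
) -> DwtConversionRule:
    # Opt-in mode: re-derive the ratio from the C_D endpoint range at this
    # record's own LOA instead of the class-average anchor.
    if (
        per_record_cd
        and rule.form == "ratio"
        and rule.cd_spec is not None
        and loa_m is not None
    ):
        cd = interpolate_cd(cd_specs[rule.cd_spec], loa_m)
        return DwtConversionRule(
            form="ratio",
            scale=1.0 / cd,
            output_unit=rule.output_unit,
            source_label=rule.source_label,
            cd=cd,
            cd_spec=rule.cd_spec,
        )
    return rule


def strategy_displacement_kg(
    strategy: Strategy,
    dwt: float,
    loa_m: float | None = None,
    cd_specs: Mapping[str, DeadweightCoefficientSpec] | None = None,
    per_record_cd: bool = False,
) -> float:
    """Displacement in kg from DWT under a (possibly mixed) strategy.

    For a mixed strategy every component is converted to kg before the
    arithmetic mean is taken.
    """
    cd_specs = cd_specs or {}
    if isinstance(strategy, MixedStrategy):
        vals = [
            apply_dwt_rule(_resolve_rule(c, loa_m, cd_specs, per_record_cd), dwt)
            for c in strategy.components
        ]
        return sum(vals) / len(vals)
    return apply_dwt_rule(_resolve_rule(strategy, loa_m, cd_specs, per_record_cd), dwt)


def estimate_displacement(
    record: VesselRecord,
    strategy_table: StrategyTable | None = None,
    per_record_cd: bool = False,
) -> tuple[float, str]:
    """Estimate one vessel's displacement in kg.

    Dispatch order: a reported displacement is passed through; else a net
    weight is corrected for capacity; else the type's DWT strategy is
    applied. Returns ``(mass_kg, method)`` where method is one of
    ``"reported"``, ``"net_weight"``, ``"dwt_ratio"``, ``"dwt_linear"``,
    ``"dwt_power"``, ``"dwt_mixed_mean"``.
    """
    if record.displacement_kg is not None:
        return record.displacement_kg, "reported"
    if record.net_weight_kg is not None:
        return (
            net_weight_to_displacement(record.net_weight_kg, record.capacity_persons),
            "net_weight",
        )
    if record.dwt_tonnes is None:
        raise EstimationError(
            f"record {record.record_id}: no usable mass field "
            "(dwt_tonnes, displacement_kg, net_weight_kg all absent)"
        )
    table = strategy_table or load_strategy_table()
    strategy = table.strategies[record.vessel_type]
    mass = strategy_displacement_kg(
        strategy,
        record.dwt_tonnes,
        loa_m=record.loa_m,
        cd_specs=table.cd_specs,
        per_record_cd=per_record_cd,
    )
    method = (
        "dwt_mixed_mean"
        if isinstance(strategy, MixedStrategy)
        else f"dwt_{strategy.form}"
    )
    return mass, method


def estimate_fleet(
    records: Iterable[VesselRecord],
    strategy_table: StrategyTable | None = None,
    per_record_cd: bool = False,
) -> tuple[list[float], list[str]]:
    """Vectorised convenience wrapper: displacement and method per record."""
    table = strategy_table or load_strategy_table()
    masses, methods = [], []
    for r in records:
        m, meth = estimate_displacement(r, table, per_record_cd)
        masses.append(m)
        methods.append(meth)
    return masses, methods


def _rule_from_dict(d: Mapping, cd_specs) -> DwtConversionRule:
    form = d["form"]
    if form == "ratio" and "scale" not in d:
        # Mixed-strategy components give only the coefficient; the
        # multiplier is its reciprocal at full precision.
        scale = 1.0 / d["cd"]
    else:
        scale = d["scale"]
    rule = DwtConversionRule(
        form=form,
        scale=scale,
        output_unit=d["output_unit"],
        exponent=d.get("exponent"),
        offset=d.get("offset"),
        source_label=d.get("source_label", ""),
        cd=d.get("cd"),
        cd_spec=d.get("cd_spec"),
    )
    if rule.cd_spec is not None and rule.cd_spec not in cd_specs:
        raise ConfigurationError(f"unknown cd_spec {rule.cd_spec!r}")
    return rule


def load_strategy_table(path: str | Path | None = None) -> StrategyTable:
    """Load the per-type strategy table (packaged default or an override).

    The packaged file carries the standard conversion set: power/linear DWT
    regressions for the cargo types and tug, fixed deadweight-coefficient
    ratios for the passenger-like types, and three-way averaged strategies
    for the heterogeneous categories.
    """
    if path is None:
        text = (
            resources.files("vesselmass.data")
            .joinpath("dwt_strategies.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        cd_specs = {
            name: DeadweightCoefficientSpec(vessel_class=name, **fields)
            for name, fields in raw["cd_specs"].items()
        }
        strategies: dict[VesselType, Strategy] = {}
        anchors: dict[VesselType, float] = {}
        for type_label, entry in raw["strategies"].items():
            vtype = VesselType(type_label)
            if "anchor_loa_m" in entry:
                anchors[vtype] = entry["anchor_loa_m"]
            if entry["form"] == "mixed":
                strategies[vtype] = MixedStrategy(
                    components=tuple(
                        _rule_from_dict(c, cd_specs) for c in entry["components"]
                    ),
                    source_label=entry.get("source_label", ""),
                )
            else:
                strategies[vtype] = _rule_from_dict(entry, cd_specs)
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigurationError(f"malformed strategy table: {exc}") from exc
    missing = set(VesselType) - set(strategies)
    if missing:
        raise ConfigurationError(
            f"strategy table missing types: {sorted(t.value for t in missing)}"
        )
    return StrategyTable(
        version=str(raw.get("version", "unversioned")),
        cd_specs=cd_specs,
        strategies=strategies,
        anchors_loa_m=anchors,
    )
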