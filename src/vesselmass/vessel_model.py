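"""Vessel taxonomy, record validation, and tabular I/O.

Vessel records mimic the static half of AIS (Automatic Identification
System) data — identity, type, length overall (LOA), maximum deadweight
tonnage (DWT) — optionally augmented with catalogue-style fields
(displacement, net weight, passenger capacity) as found in online boat
databases and broker listings.
"""

from __future__ import annotations

import enum
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ConfigurationError, RecordValidationError

__all__ = [
    "VesselType",
    "VesselRecord",
    "DEFAULT_COLUMNS",
    "read_vessel_table",
    "write_vessel_table",
    "records_to_frame",
    "dedupe_fleet",
]

#: LOA plausibility window (m); values outside trigger a warning, not an error.
#: Spans the smallest sailing dinghies through the largest container ships.
LOA_PLAUSIBLE_M = (3.0, 450.0)


class VesselType(str, enum.Enum):
    """The twelve vessel categories used by the length–mass model.

    Cruise ships and ferries are split out of the generic AIS "Passenger"
    category upstream; this taxonomy accepts the final labels only.
    """

    BULK_CARRIER = "bulk_carrier"
    CONTAINER_SHIP = "container_ship"
    CRUISE = "cruise"
    FERRY = "ferry"
    FISHING = "fishing"
    GOVERNMENT_RESEARCH = "government_research"
    OTHER = "other"
    PASSENGER = "passenger"
    PLEASURE_CRAFT = "pleasure_craft"
    SAILING = "sailing"
    TANKER = "tanker"
    TUG = "tug"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class VesselRecord(BaseModel):
    """One vessel's static characteristics.

    At least one of ``dwt_tonnes``, ``displacement_kg`` or ``net_weight_kg``
    must be present, otherwise no mass estimate is possible. Gross tonnage,
    being a volume measure, is deliberately not carried as a mass field.

    Parameters
    ----------
    record_id : str
        Opaque identifier (e.g. MMSI, catalogue entry id, row number).
    vessel_type : VesselType
    loa_m : float
        Length overall in metres; must be positive.
    dwt_tonnes : float, optional
        Maximum deadweight tonnage in metric tonnes.
    displacement_kg : float, optional
        Reported total mass (displacement) in kg.
    net_weight_kg : float, optional
        Light-ship weight in kg (empty vessel).
    capacity_persons : int, optional
        Maximum number of persons onboard; used to correct net weight.
    source : {"ais", "online"}
    """

    model_config = ConfigDict(frozen=True)

    record_id: str
    vessel_type: VesselType
    loa_m: float
    dwt_tonnes: Optional[float] = None
    displacement_kg: Optional[float] = None
    net_weight_kg: Optional[float] = None
    capacity_persons: Optional[int] = None
    source: str = "ais"

    @field_validator("loa_m")
    @classmethod
    def _loa_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError(f"loa_m must be > 0, got {v}")
        if not (LOA_PLAUSIBLE_M[0] <= v <= LOA_PLAUSIBLE_M[1]):
            warnings.warn(
                f"LOA {v} m outside plausible range {LOA_PLAUSIBLE_M}",
                stacklevel=2,
            )
        return v

    @field_validator("dwt_tonnes")
    @classmethod
    def _dwt_nonnegative(cls, v):
        if v is not None and v < 0:
            raise ValueError(f"dwt_tonnes must be >= 0, got {v}")
        return v

    @field_validator("displacement_kg")
    @classmethod
    def _displacement_positive(cls, v):
        if v is not None and not v > 0:
            raise ValueError(f"displacement_kg must be > 0, got {v}")
        return v

    @field_validator("net_weight_kg")
    @classmethod
    def _net_weight_nonnegative(cls, v):
        if v is not None and v < 0:
            raise ValueError(f"net_weight_kg must be >= 0, got {v}")
        return v

    @field_validator("capacity_persons")
    @classmethod
    def _capacity_nonnegative(cls, v):
        if v is not None and v < 0:
            raise ValueError(f"capacity_persons must be >= 0, got {v}")
        return v

    @field_validator("source")
    @classmethod
    def _source_known(cls, v: str) -> str:
        if v not in ("ais", "online"):
            raise ValueError(f"source must be 'ais' or 'online', got {v!r}")
        return v

    @model_validator(mode="after")
    def _has_mass_field(self) -> "VesselRecord":
        if (
            self.dwt_tonnes is None
            and self.displacement_kg is None
            and self.net_weight_kg is None
        ):
            raise ValueError(
                "at least one of dwt_tonnes, displacement_kg, net_weight_kg required"
            )
        return self


#: Canonical CSV column names. A dialect maps these canonical names to the
#: column names actually present in a file.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "record_id": "record_id",
    "vessel_type": "vessel_type",
    "loa_m": "loa_m",
    "dwt_tonnes": "dwt_tonnes",
    "displacement_kg": "displacement_kg",
    "net_weight_kg": "net_weight_kg",
    "capacity_persons": "capacity_persons",
    "source": "source",
}

_REQUIRED = ("vessel_type", "loa_m")
_NUMERIC = ("loa_m", "dwt_tonnes", "displacement_kg", "net_weight_kg")


def read_vessel_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[VesselRecord]:
    """Read a CSV of vessel records, validating each row.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    dialect : mapping, optional
        Maps canonical column names (keys of :data:`DEFAULT_COLUMNS`) to the
        names used in the file. Unmapped canonical names fall back to their
        default spelling.
    strict : bool
        If True (default), raise :class:`RecordValidationError` listing every
        failing row. If False, return the valid rows and emit one warning per
        failure — rows are reported either way, never silently dropped.

    Returns
    -------
    list of VesselRecord
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"vessel table not found: {path}")
    colmap = dict(DEFAULT_COLUMNS)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown canonical columns in dialect: {sorted(unknown)}")
        colmap.update(dialect)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canonical in _REQUIRED:
        if colmap[canonical] not in df.columns:
            raise ConfigurationError(
                f"required column {colmap[canonical]!r} (for {canonical!r}) "
                f"missing from {path.name}; present: {list(df.columns)}"
            )

    records: list[VesselRecord] = []
    failures: list[str] = []
    for idx, row in df.iterrows():
        fields: dict = {}
        rid = None
        if colmap["record_id"] in df.columns and row[colmap["record_id"]] != "":
            rid = row[colmap["record_id"]]
        fields["record_id"] = rid if rid is not None else f"row{idx + 1}"
        try:
            fields["vessel_type"] = row[colmap["vessel_type"]].strip()
            for canonical in _NUMERIC:
                col = colmap[canonical]
                if col in df.columns and row[col].strip() != "":
                    try:
                        fields[canonical] = float(row[col])
                    except ValueError:
                        raise ValueError(f"unparseable numeric {canonical}={row[col]!r}")
            cap_col = colmap["capacity_persons"]
            if cap_col in df.columns and row[cap_col].strip() != "":
                try:
                    fields["capacity_persons"] = int(float(row[cap_col]))
                except ValueError:
                    raise ValueError(
                        f"unparseable capacity_persons={row[cap_col]!r}"
                    )
            src_col = colmap["source"]
            if src_col in df.columns and row[src_col].strip() != "":
                fields["source"] = row[src_col].strip()
            records.append(VesselRecord(**fields))
        except (ValueError, TypeError) as exc:
            failures.append(f"record {fields['record_id']}: {exc}")

    if failures:
        if strict:
            raise RecordValidationError(failures)
        for msg in failures:
            warnings.warn(msg, stacklevel=2)
    return records


def records_to_frame(records: Iterable[VesselRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        d = r.model_dump()
        d["vessel_type"] = r.vessel_type.value
        rows.append(d)
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))


def write_vessel_table(
    records: Iterable[VesselRecord],
    path: str | Path,
    extra_columns: Mapping[str, Sequence] | None = None,
) -> None:
    """Write records to CSV in the canonical schema.

    ``extra_columns`` (e.g. ``displacement_est_kg``, ``method``) are appended
    after the canonical columns.
    """
    df = records_to_frame(records)
    if extra_columns:
        for name, values in extra_columns.items():
            df[name] = list(values)
    df.to_csv(path, index=False)


def _dedupe_key(r: VesselRecord):
    # Same-model replicates are identified by (type, LOA, DWT); records
    # lacking DWT fall back to reported displacement as the third key.
    if r.dwt_tonnes is not None:
        return (r.vessel_type, r.loa_m, "dwt", r.dwt_tonnes)
    return (r.vessel_type, r.loa_m, "disp", r.displacement_kg)


def dedupe_fleet(records: Iterable[VesselRecord]) -> list[VesselRecord]:
    """Drop same-model replicates, keeping the first occurrence.

    Two vessels of the same type with identical LOA and DWT are taken to be
    the same model; only one is kept. Records without DWT are instead keyed
    on (type, LOA, displacement). Idempotent.
    """
    seen = set()
    kept: list[VesselRecord] = []
    for r in records:
        key = _dedupe_key(r)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept
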