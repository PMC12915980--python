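"""Published length–mass coefficient sets.

Ships the final per-type power-law coefficients (fitted on a sample of 873
vessels across twelve types) as a versioned data file, so users can estimate
vessel mass from length overall without refitting the regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import DataIntegrityError, LookupError_
from .regression import PowerLawCoefficients, PowerLawEntry, predict_mass
from .vessel_model import VesselType

__all__ = [
    "PublishedCoefficients",
    "CoefficientBundle",
    "load_published_bundle",
    "estimate_mass_published",
]

#: exp(intercept) may differ from the printed multiplier because published
#: intercepts are rounded; they must still agree to this relative tolerance.
_MULTIPLIER_RTOL = 0.01


@dataclass(frozen=True)
class PublishedCoefficients:
    """One type's published row: log-scale coefficients plus power form.

    The standard errors are metadata only — the full coefficient covariance
    is not published, so no prediction intervals are derived from them.
    """

    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    multiplier: float
    exponent: float


@dataclass(frozen=True)
class CoefficientBundle:
    """The twelve published coefficient rows with provenance."""

    entries: Mapping[VesselType, PublishedCoefficients]
    provenance: str
    version: str

    def __getitem__(self, vessel_type) -> PublishedCoefficients:
        try:
            return self.entries[VesselType(vessel_type)]
        except (KeyError, ValueError) as exc:
            raise LookupError_(f"no published row for type {vessel_type!r}") from exc

    def __getattr__(self, name: str) -> PublishedCoefficients:
        try:
            return self.entries[VesselType(name)]
        except ValueError:
            raise AttributeError(name) from None

    def __len__(self) -> int:
        return len(self.entries)

    def power_law(self) -> PowerLawCoefficients:
        """The printed (multiplier, exponent) pairs as a coefficient set."""
        return PowerLawCoefficients(
            entries={
                t: PowerLawEntry(multiplier=c.multiplier, exponent=c.exponent)
                for t, c in self.entries.items()
            }
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "provenance": self.provenance,
            "types": {
                t.value: vars(c).copy() for t, c in self.entries.items()
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _validate(raw: dict) -> CoefficientBundle:
    try:
        entries = {}
        for label, row in raw["types"].items():
            c = PublishedCoefficients(
                intercept=float(row["intercept"]),
                intercept_se=float(row["intercept_se"]),
                slope=float(row["slope"]),
                slope_se=float(row["slope_se"]),
                multiplier=float(row["multiplier"]),
                exponent=float(row["exponent"]),
            )
            entries[VesselType(label)] = c
    except (KeyError, TypeError, ValueError) as exc:
        raise DataIntegrityError(f"malformed coefficient file: {exc}") from exc
    missing = set(VesselType) - set(entries)
    if missing:
        raise DataIntegrityError(
            f"coefficient file missing types: {sorted(t.value for t in missing)}"
        )
    for t, c in entries.items():
        if not (c.multiplier > 0 and c.exponent > 0 and c.intercept_se > 0 and c.slope_se > 0):
            raise DataIntegrityError(f"{t.value}: non-positive coefficient fields")
        rel = abs(math.exp(c.intercept) - c.multiplier) / c.multiplier
        if rel > _MULTIPLIER_RTOL:
            raise DataIntegrityError(
                f"{t.value}: exp(intercept)={math.exp(c.intercept):.4f} disagrees with "
                f"multiplier {c.multiplier} by {rel:.2%}"
            )
    return CoefficientBundle(
        entries=entries,
        provenance=str(raw.get("provenance", "")),
        version=str(raw.get("version", "unversioned")),
    )


def load_published_bundle(path: str | Path | None = None) -> CoefficientBundle:
    """Load the packaged published coefficients (or an override file).

    Raises :class:`DataIntegrityError` if the file is malformed, a type is
    missing, or a printed multiplier disagrees with exp(intercept) by more
    than 1%.
    """
    if path is None:
        text = (
            resources.files("vesselmass.data")
            .joinpath("length_mass_coefficients.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return _validate(yaml.safe_load(text))


def estimate_mass_published(
    vessel_type, loa_m, bundle: CoefficientBundle | None = None
) -> float:
    """Mass in kg from length overall via the published power laws."""
    bundle = bundle or load_published_bundle()
    return predict_mass(bundle.power_law(), vessel_type, loa_m)
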