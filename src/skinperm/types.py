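"""Domain types: chemical records, descriptor blocks, model coefficients.

Missing values are represented as ``None`` (never 0.0) so that an absent
hydrogen-bond descriptor can never silently enter a prediction as zero.
The one sanctioned exception is the pair of Abraham ionic descriptors
J+/J-, which are identically zero for neutral species.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import UnitError

#: recognised permeability units (log10 scale is implicit everywhere)
UNIT_CM_S = "cm/s"
UNIT_CM_H = "cm/h"
KNOWN_UNITS = (UNIT_CM_S, UNIT_CM_H)

#: provenance vocabulary for descriptor values
PROVENANCE_EXPERIMENTAL = "experimental"
PROVENANCE_ASM = "ASM"
PROVENANCE_EPISUITE = "EPI-Suite"
PROVENANCE_OTHER = "other"
PROVENANCE_THEORETICAL = "theoretical"
PROVENANCE_INSTRUMENT = "instrument"

DESCRIPTOR_PROVENANCES = (
    PROVENANCE_EXPERIMENTAL,
    PROVENANCE_ASM,
    PROVENANCE_EPISUITE,
    PROVENANCE_OTHER,
)


def check_unit(unit: str) -> str:
    if unit not in KNOWN_UNITS:
        raise UnitError(
            f"unknown permeability unit '{unit}'; expected one of {KNOWN_UNITS}"
        )
    return unit


@dataclass(frozen=True)
class ProvenancedValue:
    """A numeric descriptor value together with where it came from."""

    value: float
    provenance: str = PROVENANCE_OTHER

    def __float__(self) -> float:
        return float(self.value)


def _value_of(x) -> float | None:
    """Unwrap a ProvenancedValue or pass a plain float through."""
    if x is None:
        return None
    if isinstance(x, ProvenancedValue):
        return float(x.value)
    return float(x)


def _provenance_of(x) -> str | None:
    if isinstance(x, ProvenancedValue):
        return x.provenance
    return None


@dataclass
class SoluteDescriptors:
    """Abraham solute descriptors.

    E: excess molar refraction; S: dipolarity/polarizability;
    A: hydrogen-bond acidity; B: hydrogen-bond basicity;
    V: McGowan characteristic volume ((cm^3/mol)/100);
    L: log gas-hexadecane partition coefficient (used only by gas-phase
    solvation equations that declare an ``l`` coefficient);
    Jplus/Jminus: ionic descriptors, zero for neutral species.
    """

    E: float | None = None
    S: float | None = None
    A: float | None = None
    B: float | None = None
    V: float | None = None
    L: float | None = None
    Jplus: float | None = None
    Jminus: float | None = None

    def __post_init__(self) -> None:
        if self.V is not None and self.V <= 0:
            raise ValueError(f"McGowan volume V must be positive, got {self.V}")


@dataclass
class PartitionDescriptors:
    """Partition-coefficient descriptors, each value carrying a provenance tag.

    Fields accept either a plain float (tagged 'other') or a
    :class:`ProvenancedValue`.
    """

    log_kow: ProvenancedValue | float | None = None
    log_kaw: ProvenancedValue | float | None = None
    mw: ProvenancedValue | float | None = None
    log_kocw: ProvenancedValue | float | None = None
    log_bcf: ProvenancedValue | float | None = None
    log_dw: ProvenancedValue | float | None = None
    log_dethanol: ProvenancedValue | float | None = None

    def __post_init__(self) -> None:
        mw = _value_of(self.mw)
        if mw is not None and mw <= 0:
            raise ValueError(f"molecular weight must be positive, got {mw}")

    def value(self, name: str) -> float | None:
        return _value_of(getattr(self, name))

    def provenance(self, name: str) -> str | None:
        return _provenance_of(getattr(self, name))


@dataclass
class RetentionParameters:
    """GC x GC solute parameters u1, u2 (first/second retention dimension)."""

    u1: float
    u2: float
    provenance: str = PROVENANCE_THEORETICAL

    def __post_init__(self) -> None:
        if self.u1 is None or self.u2 is None:
            raise ValueError("u1 and u2 must both be present")


@dataclass
class ChemicalRecord:
    """One chemical: identifiers, descriptor blocks, optional measured log Kp.

    ``candidates`` holds alternative values of the same descriptor from
    different sources (e.g. experimental and estimated log Kow side by
    side); provenance-based resolution picks among them.
    """

    id: str
    name: str = ""
    cas: str | None = None
    solute: SoluteDescriptors | None = None
    partition: PartitionDescriptors | None = None
    retention: RetentionParameters | None = None
    log_kp_exp: float | None = None
    log_kp_unit: str | None = None
    candidates: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.log_kp_exp is not None:
            if self.log_kp_unit is None:
                raise ValueError(
                    f"record '{self.id}': log_kp_unit is mandatory when "
                    "log_kp_exp is present"
                )
            check_unit(self.log_kp_unit)


@dataclass
class LFERCoefficients:
    """A named linear free energy relationship: intercept + per-descriptor slopes.

    ``coefficients`` is an ordered mapping descriptor-name -> slope;
    ``standard_errors`` (optional) uses the same keys plus ``intercept``.
    """

    model_name: str
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float] | None = None
    output_unit: str = UNIT_CM_S
    n_train: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        check_unit(self.output_unit)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "standard_errors": (
                dict(self.standard_errors) if self.standard_errors else None
            ),
            "output_unit": self.output_unit,
            "n_train": self.n_train,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LFERCoefficients":
        return cls(
            model_name=d["model_name"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            standard_errors=(
                {k: float(v) for k, v in d["standard_errors"].items()}
                if d.get("standard_errors")
                else None
            ),
            output_unit=d.get("output_unit", UNIT_CM_S),
            n_train=d.get("n_train"),
            notes=d.get("notes", ""),
        )
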