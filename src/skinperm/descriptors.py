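"""Descriptor estimation and provenance handling.

Covers three jobs upstream of model calibration:

1. Abraham solvation model (ASM) estimation of partition coefficients
   (log Kow, log Kaw, gas-stationary-phase log K) from solute descriptors:
   ``log K = c + eE + sS + aA + bB + vV (+ lL)``.
2. Provenance-ranked resolution of a descriptor when several candidate
   values coexist (experimental, ASM-estimated, EPI-Suite-estimated):
   experimental values are preferred over ASM estimates, which are
   preferred over EPI-Suite estimates.
3. The interface for GC x GC solute parameters u1/u2: they are normally
   supplied directly as input columns; when only gas-stationary-phase
   partition coefficients are available, a user-configured affine
   transform maps (log K1, log K2) to (u1, u2).

Two ASM equation files for log Kow and log Kaw ship with the package; they
are externally sourced literature parameterizations and should be verified
against the cited solvation-chemistry literature before production use.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError, MissingDescriptorError
from .types import (
    PROVENANCE_ASM,
    PROVENANCE_INSTRUMENT,
    PROVENANCE_THEORETICAL,
    ChemicalRecord,
    ProvenancedValue,
    RetentionParameters,
    SoluteDescriptors,
)

TARGET_PROPERTIES = ("log_kow", "log_kaw", "log_k_gas_stationary")


@dataclass(frozen=True)
class ASMEquation:
    """One Abraham solvation model equation for a target log K."""

    target_property: str
    c: float
    e: float
    s: float
    a: float
    b: float
    v: float
    l: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.target_property not in TARGET_PROPERTIES:
            raise ConfigurationError(
                f"unknown target property '{self.target_property}'; "
                f"expected one of {TARGET_PROPERTIES}"
            )
        vals = [self.c, self.e, self.s, self.a, self.b, self.v]
        if self.l is not None:
            vals.append(self.l)
        if not all(np.isfinite(vals)):
            raise ConfigurationError("ASM equation coefficients must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "ASMEquation":
        return cls(
            target_property=d["target_property"],
            c=float(d["c"]),
            e=float(d["e"]),
            s=float(d["s"]),
            a=float(d["a"]),
            b=float(d["b"]),
            v=float(d["v"]),
            l=float(d["l"]) if d.get("l") is not None else None,
            source=d.get("source", ""),
        )


def load_asm_equation(path) -> ASMEquation:
    with open(path) as fh:
        return ASMEquation.from_dict(json.load(fh))


def shipped_asm_equation(target_property: str) -> ASMEquation:
    """Load one of the packaged ASM equations (log_kow or log_kaw)."""
    pkg = resources.files(__package__) / "asm"
    path = pkg / f"{target_property}.json"
    try:
        with path.open() as fh:
            return ASMEquation.from_dict(json.load(fh))
    except FileNotFoundError:
        raise ConfigurationError(
            f"no shipped ASM equation for '{target_property}'"
        ) from None


def asm_estimate(eq: ASMEquation, d: SoluteDescriptors) -> ProvenancedValue:
    """Evaluate an ASM equation on a solute's descriptors.

    Returns the estimated log K tagged with provenance 'ASM'. The L
    descriptor is consumed only when the equation declares an ``l``
    coefficient.
    """
    needed = {"E": eq.e, "S": eq.s, "A": eq.a, "B": eq.b, "V": eq.v}
    total = eq.c
    for name in ("E", "S", "A", "B", "V"):
        val = getattr(d, name)
        if val is None:
            raise MissingDescriptorError(name)
        total += needed[name] * float(val)
    if eq.l is not None:
        if d.L is None:
            raise MissingDescriptorError("L")
        total += eq.l * float(d.L)
    return ProvenancedValue(total, PROVENANCE_ASM)


@dataclass(frozen=True)
class DescriptorProvenancePolicy:
    """Ordered preference over descriptor provenance tags (best first)."""

    order: tuple[str, ...] = ("experimental", "ASM", "EPI-Suite")

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ConfigurationError("provenance policy contains duplicates")

    def rank(self, provenance: str) -> int:
        try:
            return self.order.index(provenance)
        except ValueError:
            return len(self.order)  # unknown tags rank last


DEFAULT_POLICY = DescriptorProvenancePolicy()


def resolve_descriptor(
    record: ChemicalRecord,
    name: str,
    policy: DescriptorProvenancePolicy = DEFAULT_POLICY,
) -> ProvenancedValue:
    """Pick the best-provenance value of a descriptor for a record.

    Candidates come from ``record.candidates[name]`` plus the singly
    tagged value stored in the partition-descriptor block. The stored
    record is never mutated; only the returned selection depends on the
    policy. Ties in rank break deterministically on the provenance tag.
    """
    candidates: dict[str, float] = dict(record.candidates.get(name, {}))
    if record.partition is not None and hasattr(record.partition, name):
        stored = record.partition.value(name)
        if stored is not None:
            tag = record.partition.provenance(name) or "other"
            candidates.setdefault(tag, stored)
    if not candidates:
        raise MissingDescriptorError(name, record.id)
    best = min(sorted(candidates), key=policy.rank)
    return ProvenancedValue(candidates[best], best)


@dataclass(frozen=True)
class UTransform:
    """Affine map from gas-stationary-phase (log K1, log K2) to (u1, u2).

    The published orthogonalization lives in the GC x GC retention
    literature and is supplied here as configuration: u = M @ logk + b.
    """

    matrix: tuple[tuple[float, float], tuple[float, float]]
    offset: tuple[float, float] = (0.0, 0.0)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.asarray(self.matrix, dtype=float)
        b = np.asarray(self.offset, dtype=float)
        if m.shape != (2, 2) or b.shape != (2,):
            raise ConfigurationError("u-transform must be a 2x2 matrix and length-2 offset")
        return m, b

    def inverse(self) -> "UTransform":
        m, b = self.as_arrays()
        if abs(np.linalg.det(m)) < 1e-12:
            raise ConfigurationError("u-transform matrix is singular")
        minv = np.linalg.inv(m)
        binv = -minv @ b
        return UTransform(
            matrix=tuple(map(tuple, minv)), offset=tuple(binv)
        )


def derive_u_parameters(
    log_k_gc1: float,
    log_k_gc2: float,
    transform: UTransform | None,
    inputs_from_instrument: bool = False,
) -> RetentionParameters:
    """Map a pair of gas-stationary-phase log K values to (u1, u2).

    Provenance is 'theoretical' when the log K inputs were ASM-estimated
    and 'instrument' when they came from measured retention times.
    """
    if transform is None:
        raise ConfigurationError(
            "no u-parameter transform configured; supply the published "
            "affine transform (2x2 matrix + offset) from the GC x GC "
            "retention calibration literature"
        )
    if not (np.isfinite(log_k_gc1) and np.isfinite(log_k_gc2)):
        raise ConfigurationError("gas-stationary-phase log K values must be finite")
    m, b = transform.as_arrays()
    u = m @ np.array([log_k_gc1, log_k_gc2], dtype=float) + b
    prov = PROVENANCE_INSTRUMENT if inputs_from_instrument else PROVENANCE_THEORETICAL
    return RetentionParameters(u1=float(u[0]), u2=float(u[1]), provenance=prov)
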