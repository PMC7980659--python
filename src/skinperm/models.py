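"""Published LFER predictors for the skin permeability coefficient.

Four fixed, literature-calibrated linear models are shipped as JSON
coefficient files and evaluated through a single generic linear
predictor, so the convenience wrappers (``predict_dermwin`` etc.) are
bit-for-bit identical to registry evaluation by construction:

* DERMWIN (US-EPA):      log Kp = -2.80 + 0.66 log Kow - 0.0056 MW   [log10 cm/h]
* Zhang Abraham LFER:    log Kp = -5.328 + 0.137 E - 0.604 S - 0.338 A
                                  - 2.428 B + 1.797 V - 1.485 J+ + 2.471 J-  [log10 cm/s]
* PPM (two-parameter):   log Kp = -5.41 + 0.46 log Kow + 0.14 log Kaw
* GC x GC model:         log Kp = -5.35 + 0.58 u1 - 3.51 u2

The PPM and GC x GC predictors were trained against the same neutral-chemical
log Kp compilation as the Zhang model, so their outputs are tagged with that
compilation's unit (log10 cm/s); comparison against DERMWIN requires an
explicit unit conversion — nothing converts silently.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .errors import DescriptorMismatchError, MissingDescriptorError
from .types import (
    UNIT_CM_H,
    UNIT_CM_S,
    LFERCoefficients,
    PartitionDescriptors,
    RetentionParameters,
    SoluteDescriptors,
    check_unit,
)

LOG10_SECONDS_PER_HOUR = math.log10(3600.0)


@dataclass(frozen=True)
class Prediction:
    """A predicted log10 Kp with unit and input-provenance metadata."""

    value: float
    unit: str
    model_name: str
    provenance: dict[str, str] = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)

    def in_unit(self, unit: str) -> "Prediction":
        return Prediction(
            value=convert_logkp_unit(self.value, self.unit, unit),
            unit=unit,
            model_name=self.model_name,
            provenance=dict(self.provenance),
        )


def convert_logkp_unit(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a log10 permeability coefficient between cm/s and cm/h.

    cm/s -> cm/h adds log10(3600); the inverse subtracts it.
    """
    check_unit(from_unit)
    check_unit(to_unit)
    if from_unit == to_unit:
        return value
    if from_unit == UNIT_CM_S and to_unit == UNIT_CM_H:
        return value + LOG10_SECONDS_PER_HOUR
    return value - LOG10_SECONDS_PER_HOUR


def predict_linear(model: LFERCoefficients, values: Mapping[str, float]) -> float:
    """Evaluate intercept + sum(coefficient * descriptor value).

    Every coefficient key in the model must have a (non-None) value;
    otherwise a descriptor-mismatch error lists what is missing.
    """
    missing = [k for k in model.coefficients if values.get(k) is None]
    if missing:
        raise DescriptorMismatchError(missing, model.model_name)
    total = model.intercept
    for name, coef in model.coefficients.items():
        total += coef * float(values[name])
    return total


# ---------------------------------------------------------------------------
# registry of published coefficient sets
# ---------------------------------------------------------------------------

_REGISTRY_FILES = (
    "dermwin_eq1",
    "zhang_eq2",
    "ppm_eq5",
    "ppm_eq6",
    "gcgc_eq7",
    "gcgc_eq8",
)

_registry_cache: dict[str, LFERCoefficients] | None = None


def load_registry() -> dict[str, LFERCoefficients]:
    """Load the shipped model coefficient files (cached)."""
    global _registry_cache
    if _registry_cache is None:
        reg: dict[str, LFERCoefficients] = {}
        pkg = resources.files(__package__) / "registry"
        for name in _REGISTRY_FILES:
            with (pkg / f"{name}.json").open() as fh:
                reg[name] = LFERCoefficients.from_dict(json.load(fh))
        _registry_cache = reg
    return dict(_registry_cache)


def get_model(name: str) -> LFERCoefficients:
    reg = load_registry()
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown model '{name}'; shipped models: {', '.join(sorted(reg))}"
        ) from None


def load_model_file(path) -> LFERCoefficients:
    """Load a user-supplied model coefficient JSON file."""
    with open(path) as fh:
        return LFERCoefficients.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# dedicated predictors (thin wrappers over the registry entries)
# ---------------------------------------------------------------------------


def _require(d, names: list[str], record_id: str | None = None) -> dict[str, float]:
    out: dict[str, float] = {}
    for name in names:
        v = d.value(name) if isinstance(d, PartitionDescriptors) else getattr(d, name)
        if v is None:
            raise MissingDescriptorError(name, record_id)
        out[name] = float(v)
    return out


def predict_dermwin(
    d: PartitionDescriptors, record_id: str | None = None
) -> Prediction:
    """DERMWIN estimate of log Kp (log10 cm/h) from log Kow and MW."""
    model = get_model("dermwin_eq1")
    x = _require(d, ["log_kow", "mw"], record_id)
    prov = {
        k: p for k in x if (p := d.provenance(k)) is not None
    }
    return Prediction(predict_linear(model, x), model.output_unit, model.model_name, prov)


def predict_zhang(d: SoluteDescriptors, record_id: str | None = None) -> Prediction:
    """Zhang Abraham-descriptor estimate of log Kp (log10 cm/s).

    J+/J- default to zero when absent: they vanish for neutral species.
    """
    model = get_model("zhang_eq2")
    x = _require(d, ["E", "S", "A", "B", "V"], record_id)
    x["Jplus"] = float(d.Jplus) if d.Jplus is not None else 0.0
    x["Jminus"] = float(d.Jminus) if d.Jminus is not None else 0.0
    return Prediction(predict_linear(model, x), model.output_unit, model.model_name)


def predict_ppm(d: PartitionDescriptors, record_id: str | None = None) -> Prediction:
    """Two-parameter partitioning model estimate of log Kp.

    Input provenance tags (experimental / ASM / EPI-Suite) propagate into
    the prediction's metadata so downstream comparisons can stratify by
    input quality.
    """
    model = get_model("ppm_eq5")
    x = _require(d, ["log_kow", "log_kaw"], record_id)
    prov = {k: p for k in x if (p := d.provenance(k)) is not None}
    return Prediction(predict_linear(model, x), model.output_unit, model.model_name, prov)


def predict_gcgc(r: RetentionParameters, record_id: str | None = None) -> Prediction:
    """GC x GC retention-parameter estimate of log Kp from u1, u2."""
    model = get_model("gcgc_eq7")
    if r is None:
        raise MissingDescriptorError("u1", record_id)
    x = {"u1": float(r.u1), "u2": float(r.u2)}
    return Prediction(
        predict_linear(model, x),
        model.output_unit,
        model.model_name,
        {"u1": r.provenance, "u2": r.provenance},
    )
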