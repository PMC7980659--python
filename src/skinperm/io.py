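"""Reading and writing chemical descriptor tables.

Tables are comma-separated (TSV by flag), UTF-8, header row required,
"." decimal. Headers are matched case-insensitively against a
controlled vocabulary; nonstandard headers can be renamed through a
user-supplied column map. Unparseable numeric cells become missing
values with a logged warning count — they are never silently zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DuplicateIdError, TableFormatError
from .types import (
    ChemicalRecord,
    PartitionDescriptors,
    ProvenancedValue,
    RetentionParameters,
    SoluteDescriptors,
)

logger = logging.getLogger(__name__)

#: canonical column names (lowercase key -> canonical spelling)
COLUMN_VOCAB = {
    "id": "id",
    "name": "name",
    "cas": "cas",
    "e": "E",
    "s": "S",
    "a": "A",
    "b": "B",
    "v": "V",
    "l": "L",
    "jplus": "Jplus",
    "jminus": "Jminus",
    "log_kow": "log_kow",
    "log_kaw": "log_kaw",
    "mw": "mw",
    "log_kocw": "log_kocw",
    "log_bcf": "log_bcf",
    "log_dw": "log_dw",
    "log_dethanol": "log_dethanol",
    "u1": "u1",
    "u2": "u2",
    "log_kp": "log_kp",
    "log_kp_exp": "log_kp_exp",
    "log_kp_unit": "log_kp_unit",
}

_TEXT_COLUMNS = {"id", "name", "cas", "log_kp_unit"}

#: suffix conventions for multi-provenance candidate columns,
#: e.g. log_kow_exp / log_kow_asm / log_kow_episuite
_CANDIDATE_SUFFIXES = {
    "_exp": "experimental",
    "_experimental": "experimental",
    "_asm": "ASM",
    "_episuite": "EPI-Suite",
    "_epi": "EPI-Suite",
}


@dataclass
class ChemicalTable:
    """An ordered table of chemical records plus column metadata."""

    frame: pd.DataFrame
    column_provenance: dict[str, str] = field(default_factory=dict)
    log_kp_unit: str | None = None
    n_cell_warnings: int = 0
    candidate_columns: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    def __len__(self) -> int:
        return len(self.frame)

    def to_records(self) -> list[ChemicalRecord]:
        records = []
        cols = set(self.frame.columns)

        def get(row, name):
            if name not in cols:
                return None
            v = row[name]
            if isinstance(v, float) and np.isnan(v):
                return None
            return v

        for _, row in self.frame.iterrows():
            solute = None
            if cols & {"E", "S", "A", "B", "V", "L", "Jplus", "Jminus"}:
                solute = SoluteDescriptors(
                    E=get(row, "E"), S=get(row, "S"), A=get(row, "A"),
                    B=get(row, "B"), V=get(row, "V"), L=get(row, "L"),
                    Jplus=get(row, "Jplus"), Jminus=get(row, "Jminus"),
                )
            partition = None
            part_fields = (
                "log_kow", "log_kaw", "mw", "log_kocw",
                "log_bcf", "log_dw", "log_dethanol",
            )
            if cols & set(part_fields):
                kwargs = {}
                for f in part_fields:
                    v = get(row, f)
                    if v is not None:
                        tag = self.column_provenance.get(f, "other")
                        kwargs[f] = ProvenancedValue(float(v), tag)
                partition = PartitionDescriptors(**kwargs)
            retention = None
            u1, u2 = get(row, "u1"), get(row, "u2")
            if u1 is not None and u2 is not None:
                retention = RetentionParameters(float(u1), float(u2))
            log_kp = get(row, "log_kp_exp")
            if log_kp is None:
                log_kp = get(row, "log_kp")
            unit = get(row, "log_kp_unit") or self.log_kp_unit
            candidates: dict[str, dict[str, float]] = {}
            for base, bytag in self.candidate_columns.items():
                cand = {}
                for tag, colname in bytag.items():
                    v = get(row, colname)
                    if v is not None:
                        cand[tag] = float(v)
                if cand:
                    candidates[base] = cand
            records.append(
                ChemicalRecord(
                    id=str(row["id"]),
                    name=str(get(row, "name") or ""),
                    cas=get(row, "cas"),
                    solute=solute,
                    partition=partition,
                    retention=retention,
                    log_kp_exp=float(log_kp) if log_kp is not None else None,
                    log_kp_unit=unit if log_kp is not None else None,
                    candidates=candidates,
                )
            )
        return records


def _canonicalize(col: str, column_map: dict[str, str] | None) -> str:
    if column_map:
        lowered = {k.lower(): v for k, v in column_map.items()}
        if col.lower() in lowered:
            col = lowered[col.lower()]
    return COLUMN_VOCAB.get(col.lower(), col)


def read_chemical_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
    column_provenance: dict[str, str] | None = None,
    log_kp_unit: str | None = None,
) -> ChemicalTable:
    """Read a chemical descriptor table from CSV/TSV.

    Headers are canonicalized case-insensitively; ``column_map`` renames
    nonstandard headers first. Numeric cells that fail to parse become
    missing with one logged warning each. Duplicate ids and a missing id
    column are hard errors. Columns named like ``log_kow_exp`` /
    ``log_kow_asm`` / ``log_kow_episuite`` are collected as provenance
    candidates for the base descriptor.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [_canonicalize(c, column_map) for c in raw.columns]
    if "id" not in raw.columns:
        raise TableFormatError(f"{path}: no 'id' column after header mapping")

    candidate_columns: dict[str, dict[str, str]] = {}
    for col in raw.columns:
        for suffix, tag in _CANDIDATE_SUFFIXES.items():
            if col.lower().endswith(suffix):
                base = _canonicalize(col[: -len(suffix)], column_map)
                if base in COLUMN_VOCAB.values():
                    candidate_columns.setdefault(base, {})[tag] = col
                break

    n_warnings = 0
    frame = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        if col in _TEXT_COLUMNS:
            frame[col] = raw[col].replace("", np.nan)
            continue
        text = raw[col].str.strip()
        numeric = pd.to_numeric(text.replace("", np.nan), errors="coerce")
        bad = numeric.isna() & (text != "")
        for i in frame.index[bad]:
            n_warnings += 1
            logger.warning(
                "%s: unparseable value %r in column %s, row %d -> missing",
                path, raw.at[i, col], col, i,
            )
        frame[col] = numeric

    ids = frame["id"].astype(str)
    if ids.isna().any() or (ids == "nan").any():
        raise TableFormatError(f"{path}: empty id cells")
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise DuplicateIdError(dup)
    frame["id"] = ids

    return ChemicalTable(
        frame=frame.reset_index(drop=True),
        column_provenance=dict(column_provenance or {}),
        log_kp_unit=log_kp_unit,
        n_cell_warnings=n_warnings,
        candidate_columns=candidate_columns,
    )


def write_table(frame: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a frame to CSV with full-precision floats (repr round-trip)."""
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_predictions(
    table: ChemicalTable | pd.DataFrame,
    predictions: pd.Series,
    path,
    model_name: str,
    unit: str,
    provenance: pd.Series | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Write per-chemical predictions aligned to a table's ids.

    Output columns: id, name (when available), predicted log Kp, model
    name, output unit and input-provenance tags. Prediction ids must
    match the table ids exactly; an empty prediction set yields a
    header-only file.
    """
    frame = table.frame if isinstance(table, ChemicalTable) else table
    ids = list(frame["id"].astype(str))
    pred_ids = [str(i) for i in predictions.index]
    if len(predictions) and pred_ids != ids:
        raise AlignmentError(
            "prediction ids do not align with table ids "
            f"(first mismatch near {next((a for a, b in zip(pred_ids, ids) if a != b), '?')})"
        )
    out = pd.DataFrame({"id": ids if len(predictions) else []})
    if "name" in frame.columns and len(predictions):
        out["name"] = list(frame["name"])
    elif "name" in frame.columns:
        out["name"] = []
    out["log_kp_pred"] = list(predictions.values) if len(predictions) else []
    out["model"] = model_name if len(predictions) else []
    out["unit"] = unit if len(predictions) else []
    if provenance is not None:
        out["input_provenance"] = list(provenance.values) if len(predictions) else []
    if not len(predictions):
        out = out.iloc[0:0]
    write_table(out, path, sep=sep)
    return out
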