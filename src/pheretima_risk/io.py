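"""Readers and writers for the delimiter-separated table formats.

Concentration files have a ``sample_id`` column, an optional ``origin`` column
and one column per measured metal. Censored cells are encoded either as the
tokens ``<LOD`` / ``<LOQ`` in the value column, or through a companion
``<metal>_status`` column holding one of ``detected`` / ``below_LOD`` /
``between_LOD_LOQ``; both encodings are accepted and may be mixed. Detected
values round-trip bit-identically through write/read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .datamodel import (
    BELOW_LOD,
    BETWEEN_LOD_LOQ,
    CENSOR_STATUSES,
    DETECTED,
    MEASURED_METALS,
    ConcentrationTable,
    ConsumptionRecords,
    DetectionLimits,
    censor_value,
)
from .errors import SchemaError, ValidationError

_LOD_TOKEN = "<LOD"
_LOQ_TOKEN = "<LOQ"


def read_concentration_table(
    path: Union[str, Path],
    limits: Optional[DetectionLimits] = None,
    sep: str = ",",
) -> ConcentrationTable:
    """Read and validate a concentration table, applying censoring substitution.

    Raises :class:`SchemaError` for unknown columns and :class:`ValidationError`
    for negative values or duplicate sample ids. Row order is preserved.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in raw.columns:
        raise SchemaError(f"{path}: missing required column 'sample_id'")
    known = {"sample_id", "origin"}
    status_cols = {f"{m}_status": m for m in MEASURED_METALS}
    for col in raw.columns:
        if col in known or col in status_cols or col in MEASURED_METALS:
            continue
        raise SchemaError(f"{path}: unknown column {col!r}")
    missing = [m for m in MEASURED_METALS if m not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing metal columns: {', '.join(missing)}")

    values = {}
    statuses = {}
    for metal in MEASURED_METALS:
        col_values = []
        col_status = []
        explicit = raw.get(f"{metal}_status")
        for i, cell in enumerate(raw[metal]):
            if not isinstance(cell, str) or not cell.strip():
                raise ValidationError(f"{path}: missing {metal} value in row {i}")
            status, numeric = _parse_cell(cell.strip(), path, metal)
            if explicit is not None and isinstance(explicit.iloc[i], str):
                declared = explicit.iloc[i].strip()
                if declared not in CENSOR_STATUSES:
                    raise SchemaError(
                        f"{path}: invalid status {declared!r} for {metal} row {i}"
                    )
                if status == DETECTED:
                    status = declared
            col_values.append(censor_value(status, numeric, limits, metal))
            col_status.append(status)
        values[metal] = col_values
        statuses[metal] = col_status

    index = pd.Index(raw["sample_id"], name="sample_id")
    origin = None
    if "origin" in raw.columns:
        origin = pd.Series(raw["origin"].to_numpy(), index=index, name="origin")
    return ConcentrationTable(
        values=pd.DataFrame(values, index=index, dtype=float),
        censor_status=pd.DataFrame(statuses, index=index),
        origin=origin,
    )


def _parse_cell(cell: str, path, metal: str):
    upper = cell.upper()
    if upper == _LOD_TOKEN.upper():
        return BELOW_LOD, None
    if upper == _LOQ_TOKEN.upper():
        return BETWEEN_LOD_LOQ, None
    try:
        value = float(cell)
    except ValueError:
        raise SchemaError(f"{path}: cannot parse {metal} value {cell!r}") from None
    if value < 0:
        raise ValidationError(f"{path}: negative {metal} concentration {value}")
    return DETECTED, value


def write_concentration_table(
    table: ConcentrationTable, path: Union[str, Path], sep: str = ","
) -> None:
    """Write a table back to disk, re-encoding censored cells as tokens."""
    out = pd.DataFrame(index=table.values.index)
    if table.origin is not None:
        out["origin"] = table.origin
    for metal in table.values.columns:
        col = []
        for sample in table.values.index:
            status = table.censor_status.loc[sample, metal]
            if status == BELOW_LOD:
                col.append(_LOD_TOKEN)
            elif status == BETWEEN_LOD_LOQ:
                col.append(_LOQ_TOKEN)
            else:
                col.append(repr(float(table.values.loc[sample, metal])))
        out[metal] = col
    out.to_csv(path, sep=sep, index=True)


def read_consumption_records(path: Union[str, Path], sep: str = ",") -> ConsumptionRecords:
    """Read and validate per-individual consumption records."""
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in ConsumptionRecords.COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")
    return ConsumptionRecords(frame=frame)


def write_consumption_records(
    records: ConsumptionRecords, path: Union[str, Path], sep: str = ","
) -> None:
    records.frame.to_csv(path, sep=sep, index=False)
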