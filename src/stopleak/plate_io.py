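"""Readers, writers and schema validation for plate-screen tables.

All tables are tidy (one row per well / colony plate / gel lane) CSV files
and are held in memory as :class:`pandas.DataFrame` objects with a fixed
column order:

* measurements: ``plate_id,well,role,od750,venus,chl``
* layout (sample annotations): ``plate_id,well,construct,strain,replicate``
* colony counts: ``replicate,construct,selection,colonies,cells_plated``
* band intensities: ``lane_id,construct,intensity``

Well labels are case-insensitive and normalized to an upper-case row label
followed by an unpadded column number (``"a01"`` -> ``"A1"``).  Missing
numeric cells are rejected rather than imputed.
"""

from __future__ import annotations

import re
from os import PathLike
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import SchemaError

PathType = Union[str, PathLike]

MEASUREMENT_COLUMNS = ["plate_id", "well", "role", "od750", "venus", "chl"]
LAYOUT_COLUMNS = ["plate_id", "well", "construct", "strain", "replicate"]
COLONY_COLUMNS = ["replicate", "construct", "selection", "colonies", "cells_plated"]
BAND_COLUMNS = ["lane_id", "construct", "intensity"]

ROLES = frozenset({"blank", "sample"})
SELECTIONS = frozenset({"photoautotrophy", "antibiotic"})

_WELL_RE = re.compile(r"^([A-Za-z]+)0*([0-9]+)$")


def normalize_well_label(label: str) -> str:
    """Normalize a well label: upper-case row letters, unpadded column.

    >>> normalize_well_label("a01")
    'A1'
    """
    m = _WELL_RE.match(str(label).strip())
    if m is None:
        raise SchemaError(f"malformed well label {label!r}")
    return m.group(1).upper() + str(int(m.group(2)))


def _read_csv(path: PathType, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df.loc[:, columns]


def _numeric(df: pd.DataFrame, cols: Iterable[str], path: PathType) -> pd.DataFrame:
    """Convert columns to float, rejecting missing or non-finite cells."""
    df = df.copy()
    for col in cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, plus header line
            raise SchemaError(
                f"{path}: column {col!r} has a missing or non-numeric value "
                f"at line {row}"
            )
        df[col] = values.astype(float)
    return df


def _check_unique_wells(df: pd.DataFrame, path: PathType) -> None:
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        plate, well = df.loc[df.index[dup][0], ["plate_id", "well"]]
        raise SchemaError(f"{path}: duplicate well {well!r} on plate {plate!r}")


def read_measurements(path: PathType) -> pd.DataFrame:
    """Read a plate-reader measurement table.

    Returns a DataFrame with one row per well, roles validated against
    {blank, sample}, well labels normalized, readings finite floats.
    Row order of the file is preserved.
    """
    df = _read_csv(path, MEASUREMENT_COLUMNS)
    df["well"] = df["well"].map(normalize_well_label)
    unknown = ~df["role"].isin(ROLES)
    if unknown.any():
        bad = df.loc[df.index[unknown][0]]
        raise SchemaError(
            f"{path}: unknown role {bad['role']!r} for well {bad['well']!r} "
            f"on plate {bad['plate_id']!r}"
        )
    df = _numeric(df, ["od750", "venus", "chl"], path)
    _check_unique_wells(df, path)
    return df.reset_index(drop=True)


def read_layout(path: PathType) -> pd.DataFrame:
    """Read a plate layout (sample annotation) table."""
    df = _read_csv(path, LAYOUT_COLUMNS)
    df["well"] = df["well"].map(normalize_well_label)
    _check_unique_wells(df, path)
    return df.reset_index(drop=True)


def read_plate_table(
    path: PathType, layout_path: PathType
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read measurements together with their layout and cross-validate.

    Every sample well must carry exactly one annotation; blank wells carry
    none; annotations may not reference absent wells.
    """
    measurements = read_measurements(path)
    layout = read_layout(layout_path)

    meas_keys = set(zip(measurements["plate_id"], measurements["well"]))
    roles = dict(
        zip(zip(measurements["plate_id"], measurements["well"]), measurements["role"])
    )
    for plate, well in zip(layout["plate_id"], layout["well"]):
        if (plate, well) not in meas_keys:
            raise SchemaError(
                f"layout references absent well {well!r} on plate {plate!r}"
            )
        if roles[(plate, well)] != "sample":
            raise SchemaError(
                f"layout annotates blank well {well!r} on plate {plate!r}"
            )
    layout_keys = set(zip(layout["plate_id"], layout["well"]))
    samples = measurements.loc[measurements["role"] == "sample"]
    for plate, well in zip(samples["plate_id"], samples["well"]):
        if (plate, well) not in layout_keys:
            raise SchemaError(
                f"sample well {well!r} on plate {plate!r} has no annotation"
            )
    return measurements, layout


def read_colony_counts(path: PathType) -> pd.DataFrame:
    """Read a colony-count table for transformation-efficiency analysis."""
    df = _read_csv(path, COLONY_COLUMNS)
    unknown = ~df["selection"].isin(SELECTIONS)
    if unknown.any():
        bad = df.loc[df.index[unknown][0], "selection"]
        raise SchemaError(f"{path}: unknown selection {bad!r}")
    df = _numeric(df, ["colonies", "cells_plated"], path)
    if (df["colonies"] < 0).any():
        raise SchemaError(f"{path}: negative colony count")
    if (df["cells_plated"] <= 0).any():
        raise SchemaError(f"{path}: cells_plated must be positive")
    return df.reset_index(drop=True)


def read_band_intensities(path: PathType) -> pd.DataFrame:
    """Read an immunoblot band-intensity (densitometry) table."""
    df = _read_csv(path, BAND_COLUMNS)
    df = _numeric(df, ["intensity"], path)
    if (df["intensity"] < 0).any():
        raise SchemaError(f"{path}: negative band intensity")
    return df.reset_index(drop=True)


def write_summary(
    records: pd.DataFrame, path: PathType, allow_empty: bool = False
) -> None:
    """Write a result table to CSV with full float precision.

    The written file round-trips: reading it back reproduces identifiers
    bit-exactly and numbers to full precision (shortest-repr floats).
    Non-finite numbers are rejected; NaN is permitted as the undefined-value
    marker for statistics such as the sd of a single observation.
    """
    if len(records) == 0 and not allow_empty:
        raise SchemaError("refusing to write an empty table (pass allow_empty=True)")
    numeric = records.select_dtypes(include=[np.number])
    if np.isinf(numeric.to_numpy(dtype=float, na_value=np.nan)).any():
        raise SchemaError("non-finite value in output table")
    records.to_csv(path, index=False)
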