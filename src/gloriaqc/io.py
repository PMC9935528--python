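"""Reading and writing the GLORIA multi-file CSV layout.

The distribution stores each radiometric quantity in its own CSV file
(``GLORIA_Rrs.csv``, ``GLORIA_Es.csv``, ...): the first column is the
GLORIA sample ID and the remaining columns are ``<prefix>_<nm>`` at 1 nm
over (a sub-range of) 350-900 nm.  Metadata, laboratory water-quality
values, QC flags and QC ancillary metrics live in sibling CSV files keyed
by the same ID.

Dialect: comma-separated, UTF-8, "." decimal, empty cell = missing.
Numeric output uses up to 10 significant digits so write -> read round
trips are lossless at float32-source precision.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .metrics import QCAncillary
from .qc import FLAG_COLUMNS, QCResult
from .spectra import Quantity, Spectrum

_FLOAT_FMT = "%.10g"

SPECTRAL_FILENAMES = {
    Quantity.RRS: "GLORIA_Rrs.csv",
    Quantity.ES: "GLORIA_Es.csv",
    Quantity.LW: "GLORIA_Lw.csv",
    Quantity.LT: "GLORIA_Lt.csv",
    Quantity.LSKY: "GLORIA_Lsky.csv",
    Quantity.LU: "GLORIA_Lu.csv",
}
META_FILENAME = "GLORIA_meta_and_lab.csv"
FLAGS_FILENAME = "GLORIA_qc_flags.csv"
ANCILLARY_FILENAME = "GLORIA_qc_ancillary.csv"

ID_COLUMN = "GLORIA_ID"


class SchemaError(ValueError):
    """A file does not conform to the expected column layout."""


class ValidationError(ValueError):
    """File contents violate an invariant (duplicate ids, out-of-range values)."""


# ---------------------------------------------------------------------------
# spectral tables
# ---------------------------------------------------------------------------


@dataclass
class SpectralTable:
    """All spectra of one quantity for many samples (one GLORIA CSV file)."""

    quantity: Quantity
    ids: list[str]
    grid: np.ndarray  # integer wavelengths, nm, strictly increasing
    values: np.ndarray  # shape (n_ids, n_wavelengths), NaN = missing

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        expected = (len(self.ids), self.grid.size)
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != (n_ids, n_wavelengths) {expected}"
            )

    def __len__(self) -> int:
        return len(self.ids)

    def spectrum(self, gloria_id: str) -> Spectrum:
        i = self.ids.index(gloria_id)
        return Spectrum(self.grid.astype(float), self.values[i].copy(), self.quantity)

    def iter_spectra(self):
        for i, gid in enumerate(self.ids):
            yield gid, Spectrum(
                self.grid.astype(float), self.values[i].copy(), self.quantity
            )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{self.quantity.value}_{int(w)}" for w in self.grid]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, ID_COLUMN, self.ids)
        return df


def read_spectral_table(path: str | Path, quantity: Quantity) -> SpectralTable:
    """Read one spectral CSV file (first column id, then ``<prefix>_<nm>``).

    The wavelength grid is parsed from the suffix after the last underscore
    of each column name; files may span a legitimate sub-range of
    350-900 nm.  Empty cells become NaN; id order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 1:
        raise SchemaError(f"{path.name}: no columns")
    header = list(df.columns)
    grid = []
    pattern = re.compile(rf"^{re.escape(quantity.value)}_(\d+)$")
    for col in header[1:]:
        m = pattern.match(col)
        if not m:
            raise SchemaError(
                f"{path.name}: column {col!r} does not match "
                f"'{quantity.value}_<nm>'"
            )
        grid.append(int(m.group(1)))
    grid_arr = np.asarray(grid, dtype=int)
    if grid_arr.size > 1 and not np.all(np.diff(grid_arr) > 0):
        raise SchemaError(f"{path.name}: wavelength columns not strictly increasing")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path.name}: duplicate ids: {dupes[:5]}")
    values = df.iloc[:, 1:].to_numpy(dtype=float).reshape(len(ids), grid_arr.size)
    return SpectralTable(quantity=quantity, ids=ids, grid=grid_arr, values=values)


def write_spectral_table(table: SpectralTable, path: str | Path) -> None:
    """Write one spectral table back to the distribution layout."""
    table.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

WATER_TYPES = (
    "TSS-dominated",
    "Chla-dominated",
    "CDOM-dominated",
    "Chla+CDOM-dominated",
    "Moderately turbid coastal",
    "Clear",
)

#: metadata CSV column -> SampleRecord attribute
_META_FIELD_MAP = {
    "Water_type": "water_type",
    "Water_body_type": "water_body_type",
    "Chla": "chla",
    "Chl_plus_phaeo": "chl_plus_phaeo",
    "Phaeophytin_correction": "phaeophytin_correction",
    "TSS": "tss",
    "aCDOM_440": "acdom440",
    "Secchi_depth": "secchi",
    "Latitude": "latitude",
    "Longitude": "longitude",
    "Date_Time": "datetime",
    "Measurement_method": "measurement_method",
    "Skyglint_removal": "skyglint_removal",
    "Spectral_resolution_nm": "spectral_resolution_nm",
}
_NUMERIC_FIELDS = {
    "chla",
    "chl_plus_phaeo",
    "tss",
    "acdom440",
    "secchi",
    "latitude",
    "longitude",
    "spectral_resolution_nm",
}
_NONNEGATIVE_FIELDS = {"chla", "chl_plus_phaeo", "tss", "acdom440", "secchi"}


@dataclass
class SampleRecord:
    """Metadata and water-quality values for one GLORIA_ID.

    Viewing-geometry fields, when present in the source file, are carried in
    ``extras`` as metadata only; R_rs is defined at nadir so they never
    enter any computation.  Unknown columns are likewise retained opaquely.
    """

    gloria_id: str
    water_type: str | None = None
    water_body_type: str | None = None
    chla: float | None = None  # mg m^-3
    chl_plus_phaeo: float | None = None  # mg m^-3
    phaeophytin_correction: int | None = None
    tss: float | None = None  # g m^-3
    acdom440: float | None = None  # m^-1
    secchi: float | None = None  # m
    latitude: float | None = None  # degrees
    longitude: float | None = None  # degrees
    datetime: str | None = None
    measurement_method: int | None = None
    skyglint_removal: str | None = None
    spectral_resolution_nm: float | None = None
    extras: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"{self.gloria_id}: latitude {self.latitude} outside [-90, 90]"
            )
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"{self.gloria_id}: longitude {self.longitude} outside [-180, 180]"
            )
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.gloria_id}: {name} = {v} is negative")
        if self.phaeophytin_correction not in (None, 0, 1):
            raise ValidationError(
                f"{self.gloria_id}: Phaeophytin_correction must be 0 or 1"
            )


def _cell(value: Any) -> Any:
    """Missing CSV cells (NaN / empty) -> None."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read GLORIA_meta_and_lab.csv into one SampleRecord per row."""
    path = Path(path)
    df = pd.read_csv(path)
    if ID_COLUMN not in df.columns:
        raise SchemaError(f"{path.name}: missing required column {ID_COLUMN!r}")
    records: list[SampleRecord] = []
    known = set(_META_FIELD_MAP) | {ID_COLUMN}
    for row in df.to_dict(orient="records"):
        kwargs: dict[str, Any] = {"gloria_id": str(row[ID_COLUMN])}
        for col, attr in _META_FIELD_MAP.items():
            v = _cell(row.get(col))
            if v is None:
                continue
            if attr in _NUMERIC_FIELDS:
                v = float(v)
            elif attr in ("phaeophytin_correction", "measurement_method"):
                v = int(v)
            else:
                v = str(v)
            kwargs[attr] = v
        kwargs["extras"] = {
            k: _cell(v) for k, v in row.items() if k not in known
        }
        records.append(SampleRecord(**kwargs))
    return records


def write_metadata(records: list[SampleRecord], path: str | Path) -> None:
    """Write SampleRecords back to the metadata layout (known columns + extras)."""
    rows = []
    extra_cols: list[str] = []
    for r in records:
        row: dict[str, Any] = {ID_COLUMN: r.gloria_id}
        for col, attr in _META_FIELD_MAP.items():
            row[col] = getattr(r, attr)
        for k, v in r.extras.items():
            if k not in extra_cols:
                extra_cols.append(k)
            row[k] = v
        rows.append(row)
    cols = [ID_COLUMN, *_META_FIELD_MAP.keys(), *extra_cols]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# QC outputs
# ---------------------------------------------------------------------------

_FLAG_ATTRS = [
    "noisy_red",
    "noisy_blue",
    "baseline_shift",
    "oxygen_signal",
    "negative_uv_slope",
    "qwip_fail",
    "suspect",
    "flagged",
]


def write_flags(results: list[QCResult], path: str | Path) -> None:
    """Write GLORIA_qc_flags.csv: one tri-state column per flag.

    NA flags become empty cells ("the flag could not be determined").
    """
    if not results:
        raise ValueError("no QC results to write")
    rows = []
    for r in results:
        row = {ID_COLUMN: r.gloria_id}
        for col, attr in zip(FLAG_COLUMNS, _FLAG_ATTRS):
            row[col] = getattr(r, attr)
        rows.append(row)
    df = pd.DataFrame(rows, columns=[ID_COLUMN, *FLAG_COLUMNS])
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


def read_flags(path: str | Path) -> pd.DataFrame:
    """Read a flags file; tri-state columns come back as nullable Int64."""
    path = Path(path)
    df = pd.read_csv(path, dtype={ID_COLUMN: str})
    if ID_COLUMN not in df.columns:
        raise SchemaError(f"{path.name}: missing required column {ID_COLUMN!r}")
    for col in df.columns:
        if col != ID_COLUMN:
            df[col] = df[col].astype("Int64")
    return df


def read_suspects(path: str | Path) -> dict[str, int | None]:
    """Extract the expert-elicited Suspect column from an existing flags file."""
    df = read_flags(path)
    if "Suspect" not in df.columns:
        raise SchemaError(f"{Path(path).name}: missing 'Suspect' column")
    out: dict[str, int | None] = {}
    for gid, v in zip(df[ID_COLUMN], df["Suspect"]):
        out[str(gid)] = None if pd.isna(v) else int(v)
    return out


def write_ancillary(rows: list[QCAncillary], path: str | Path) -> None:
    """Write GLORIA_qc_ancillary.csv (oxygen peak height, AVW, QWIP score)."""
    df = pd.DataFrame(
        {
            ID_COLUMN: [r.gloria_id for r in rows],
            "Oxygen_peak_height": [r.oxygen_peak_height for r in rows],
            "Apparent_visible_wavelength": [r.avw for r in rows],
            "QWIP_score": [r.qwip_score for r in rows],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
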