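"""Reading and writing of breath-by-breath tables, cohort tables and matrices.

Canonical breath-table format: comma-separated UTF-8 text, ``#``-prefixed
``key=value`` metadata lines before a single header row.  Canonical units are
fixed (VO2/VCO2 in mL·min⁻¹, VE in L·min⁻¹, tidal volume in L, times in
seconds from recording start); vendor exports in other units are mapped at the
boundary through a dialect registry.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

#: canonical per-breath channels, in on-disk column order
CHANNELS = [
    "t", "vo2", "vco2", "ve", "hr", "rf", "vt_tidal", "iv",
    "peto2", "petco2", "ti", "te", "power",
]
OPTIONAL_CHANNELS = ["sv", "vd_vt"]
REQUIRED_CHANNELS = ["t", "vo2", "vco2", "ve"]


@dataclass
class SeriesMeta:
    """Recording-level metadata carried alongside a breath table."""

    athlete_id: str = "unknown"
    sex: str = ""
    age: float = float("nan")
    mass_kg: float = float("nan")
    height_cm: float = float("nan")
    rest_onset_s: float = 0.0
    warmup_onset_s: float = float("nan")
    ramp_onset_s: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BreathSeries:
    """Time-ordered per-breath gas-exchange measurements plus workload.

    ``df`` holds one row per breath with the canonical channels; ``meta``
    carries athlete identity and the phase-onset markers (rest, warm-up, ramp)
    that downstream windowing anchors on.
    """

    df: pd.DataFrame
    meta: SeriesMeta = field(default_factory=SeriesMeta)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in REQUIRED_CHANNELS:
            if col not in self.df.columns:
                raise SchemaError(f"breath table missing required column {col!r}")
        t = self.df["t"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise DataError(f"time not strictly increasing at row {bad}")
        # positivity only matters once exercise has begun; rest rows may hold
        # device zeros on optional channels
        t0 = self.meta.ramp_onset_s
        ex = self.df if np.isnan(t0) else self.df[self.df["t"] >= t0]
        for col in ("vo2", "vco2", "ve"):
            vals = ex[col].to_numpy(float)
            if len(vals) and np.any(vals <= 0):
                bad = int(np.flatnonzero(vals <= 0)[0])
                raise DataError(f"non-positive {col} within exercise phase (row {bad})")

    @property
    def n_breaths(self) -> int:
        return len(self.df)

    def exercise(self) -> pd.DataFrame:
        """Rows at or after ramp onset (the phase event detection consumes)."""
        t0 = self.meta.ramp_onset_s
        if np.isnan(t0):
            return self.df
        return self.df[self.df["t"] >= t0].reset_index(drop=True)


# --------------------------------------------------------------------------
# dialect registry

@dataclass(frozen=True)
class Dialect:
    """Mapping from a vendor export header to canonical columns and units."""

    name: str
    column_map: Mapping[str, str]          # file header -> canonical name
    unit_scale: Mapping[str, float]        # canonical name -> multiplier

    def normalize(self, df: pd.DataFrame) -> pd.DataFrame:
        df = df.rename(columns=dict(self.column_map))
        for col, k in self.unit_scale.items():
            if col in df.columns:
                df[col] = df[col] * k
        return df


_DIALECTS: dict[str, Dialect] = {}


def register_dialect(dialect: Dialect) -> None:
    _DIALECTS[dialect.name] = dialect


def get_dialect(name: str) -> Dialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise SchemaError(f"unknown breath-table dialect {name!r}") from None


register_dialect(Dialect("canonical", {}, {}))
# common cart export: gas volumes in L·min⁻¹, capitalised headers
register_dialect(
    Dialect(
        "liters",
        {
            "Time": "t", "VO2": "vo2", "VCO2": "vco2", "VE": "ve",
            "HR": "hr", "Rf": "rf", "VT": "vt_tidal", "IV": "iv",
            "PetO2": "peto2", "PetCO2": "petco2", "Ti": "ti", "Te": "te",
            "Power": "power",
        },
        {"vo2": 1000.0, "vco2": 1000.0},
    )
)


# --------------------------------------------------------------------------
# breath tables

_META_FLOAT_KEYS = {
    "age", "mass_kg", "height_cm", "rest_onset_s", "warmup_onset_s", "ramp_onset_s",
}


def read_breath_table(path: str | Path, dialect: str = "canonical") -> BreathSeries:
    """Read a delimited breath table, normalising headers/units per dialect.

    Raises :class:`SchemaError` for missing required columns and
    :class:`DataError` for non-monotone time.
    """
    path = Path(path)
    meta = SeriesMeta()
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, val = body.partition("=")
        key, val = key.strip(), val.strip()
        if key in _META_FLOAT_KEYS:
            setattr(meta, key, float(val))
        elif key in ("athlete_id", "sex"):
            setattr(meta, key, val)
    df = pd.read_csv(_io.StringIO(text), comment="#", float_precision="round_trip")
    df = get_dialect(dialect).normalize(df)
    missing = [c for c in REQUIRED_CHANNELS if c not in df.columns]
    if missing:
        raise SchemaError(f"breath table missing required column(s): {', '.join(missing)}")
    return BreathSeries(df=df.reset_index(drop=True), meta=meta)


def write_breath_table(series: BreathSeries, path: str | Path) -> None:
    """Write a breath table in the canonical dialect (lossless round trip)."""
    path = Path(path)
    cols = [c for c in CHANNELS + OPTIONAL_CHANNELS if c in series.df.columns]
    extra = [c for c in series.df.columns if c not in cols]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in series.meta.to_dict().items():
            fh.write(f"# {key}={val}\n")
        series.df[cols + extra].to_csv(fh, index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# cohort tables

@dataclass
class CohortTable:
    """One row per athlete; numeric variable panel plus a sex label column."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            dup = self.df.columns[self.df.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate cohort column(s): {dup}")

    def numeric(self) -> pd.DataFrame:
        return self.df.select_dtypes(include=[np.number])

    def validate_complete(self, columns: list[str] | None = None) -> None:
        """Reject missing entries in the columns destined for multivariate analysis."""
        sub = self.df[columns] if columns else self.numeric()
        if sub.isna().any().any():
            cells = [
                f"(row {idx!r}, column {col!r})"
                for col in sub.columns
                for idx in sub.index[sub[col].isna()]
            ]
            raise DataError("missing cohort entries: " + "; ".join(cells))


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")
    return CohortTable(df=df)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.df.to_csv(path, index=True, lineterminator="\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix (correlations, loadings, scores) as CSV."""
    matrix.to_csv(path, index=True, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, float_precision="round_trip")
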