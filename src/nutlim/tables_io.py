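"""Shared domain schemas, CSV readers/writers, configuration, and stage logging.

All pipeline stages exchange pandas DataFrames validated against the table
schemas declared here; no downstream stage reads raw files directly. The
canonical concentration unit is mg L^-1; readers accept an optional ``units``
column (mg/L, ug/L, µg/L) and convert on ingest. Dates are calendar dates
(time of day discarded, matching daily discharge resolution).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger("nutlim")

ANALYTES = ("TN", "TP", "NO3N", "DRP")

#: micrograms-per-litre spellings accepted by readers; values are divided by 1000
_UG_UNITS = {"ug/L", "µg/L", "ug/l", "µg/l"}
_MG_UNITS = {"mg/L", "mg/l"}


class SchemaError(ValueError):
    """A file's header or structure does not match the declared schema."""


class RowError(ValueError):
    """A row violates a type invariant; carries 1-based data row numbers."""

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows {self.rows[:10]})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Schema registry
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    date_columns: tuple[str, ...] = ()
    optional: tuple[str, ...] = ()
    validator: Callable[[pd.DataFrame], None] | None = None
    # columns beyond the declared set are allowed (predictor columns)
    open_columns: bool = False


def _validate_samples(df: pd.DataFrame) -> None:
    bad = ~df["analyte"].isin(ANALYTES)
    if bad.any():
        raise RowError("unknown analyte", _rows(bad))
    uncensored_neg = (~df["censored"]) & (df["value"] < 0)
    if uncensored_neg.any():
        raise RowError("negative concentration on uncensored sample", _rows(uncensored_neg))
    bad_dl = df["detection_limit"].notna() & (df["detection_limit"] <= 0)
    if bad_dl.any():
        raise RowError("detection_limit must be > 0", _rows(bad_dl))
    # censoring convention: the value field holds the detection limit
    cens = df["censored"]
    mismatch = cens & df["detection_limit"].notna() & (
        ~np.isclose(df["value"], df["detection_limit"], rtol=1e-9, atol=0.0)
    )
    if mismatch.any():
        raise RowError("censored rows must carry the detection limit in 'value'", _rows(mismatch))


def _validate_sites(df: pd.DataFrame) -> None:
    bad = (df["latitude"] < -90) | (df["latitude"] > 90) | df["latitude"].isna()
    if bad.any():
        raise RowError("latitude outside [-90, 90]", _rows(bad))


def _validate_discharge(df: pd.DataFrame) -> None:
    bad = df["flow_m3s"].notna() & (df["flow_m3s"] < 0)
    if bad.any():
        raise RowError("negative flow", _rows(bad))


def _validate_links(df: pd.DataFrame) -> None:
    bad = df["downstream_km"].notna() & (df["downstream_km"] < 0)
    if bad.any():
        raise RowError("negative downstream distance", _rows(bad))


LANDUSE_COLUMNS = (
    "landuse_agriculture_km2",
    "landuse_forest_km2",
    "landuse_other_km2",
)


def _validate_catchments(df: pd.DataFrame) -> None:
    if (df["area_km2"] <= 0).any():
        raise RowError("area_km2 must be positive", _rows(df["area_km2"] <= 0))
    if (df["population"] < 0).any():
        raise RowError("population must be non-negative", _rows(df["population"] < 0))
    lu = df[list(LANDUSE_COLUMNS)].sum(axis=1)
    bad = lu > df["area_km2"] * (1 + 1e-6)
    if bad.any():
        raise RowError("land-use areas exceed catchment area", _rows(bad))
    for col in df.columns:
        if col.startswith("x_") and not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"continuous predictor column {col!r} is not numeric")


def _validate_thresholds(df: pd.DataFrame) -> None:
    if (df["threshold_mgL"] <= 0).any():
        raise RowError("threshold must be > 0", _rows(df["threshold_mgL"] <= 0))
    bad = ~df["analyte"].isin(ANALYTES)
    if bad.any():
        raise RowError("unknown analyte", _rows(bad))


def _rows(mask: pd.Series) -> list[int]:
    return [int(i) + 1 for i in np.flatnonzero(np.asarray(mask))]


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in [
        TableSchema(
            "samples",
            ("site_id", "date", "analyte", "value", "detection_limit",
             "censored", "method_code", "filter_pore_um"),
            date_columns=("date",),
            optional=("filter_pore_um",),
            validator=_validate_samples,
        ),
        TableSchema(
            "sites",
            ("site_id", "latitude", "catchment_id"),
            validator=_validate_sites,
        ),
        TableSchema(
            "discharge",
            ("gauge_id", "date", "flow_m3s"),
            date_columns=("date",),
            validator=_validate_discharge,
        ),
        TableSchema(
            "site_gauge_links",
            ("site_id", "gauge_id", "downstream_km"),
            validator=_validate_links,
        ),
        TableSchema(
            "catchments",
            ("catchment_id", "continent", "area_km2", "population") + LANDUSE_COLUMNS,
            validator=_validate_catchments,
            open_columns=True,
        ),
        TableSchema(
            "thresholds",
            ("study_id", "analyte", "threshold_mgL", "biome", "region"),
            validator=_validate_thresholds,
        ),
        TableSchema(
            "site_medians",
            ("site_id", "catchment_id", "analyte", "median_mgL", "n_samples",
             "window_start", "window_end"),
            date_columns=("window_start", "window_end"),
        ),
        TableSchema(
            "catchment_medians",
            ("catchment_id", "analyte", "median_mgL", "n_sites"),
        ),
        TableSchema(
            "catchment_types",
            ("catchment_id", "tn_median", "tp_median", "np_ratio",
             "limitation", "growth", "type_code"),
        ),
    ]
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "True": True, "False": False}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named table schema.

    Raises :class:`SchemaError` for missing columns and :class:`RowError`
    (with 1-based data row numbers) for invariant violations. A ``units``
    column on the samples schema is converted to mg L^-1 and dropped.
    """
    sch = _get_schema(schema)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"site_id": str, "gauge_id": str,
                                  "catchment_id": str, "study_id": str})
    missing = [c for c in sch.columns if c not in df.columns and c not in sch.optional]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing} for schema {schema!r}")
    for c in sch.optional:
        if c not in df.columns:
            df[c] = np.nan
    if schema == "samples" and "units" in df.columns:
        df = _convert_units(df)
    if "censored" in df.columns:
        if df["censored"].dtype == object:
            df["censored"] = df["censored"].map(lambda v: _BOOL_MAP.get(str(v).strip(), v))
        df["censored"] = df["censored"].astype(bool)
    for c in sch.date_columns:
        df[c] = pd.to_datetime(df[c], format="ISO8601").dt.normalize()
    if not sch.open_columns:
        extra = [c for c in df.columns if c not in sch.columns]
        df = df.drop(columns=extra)
        df = df[list(sch.columns)]
    if sch.validator is not None and not df.empty:
        sch.validator(df)
    logger.info("read_table: %s rows of schema %s from %s", len(df), schema, path.name)
    return df


def _convert_units(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    units = df["units"].astype(str).str.strip()
    known = units.isin(_UG_UNITS | _MG_UNITS)
    if not known.all():
        raise RowError("unrecognised units (accepted: mg/L, ug/L, µg/L)", _rows(~known))
    scale = np.where(units.isin(_UG_UNITS), 1e-3, 1.0)
    df["value"] = df["value"] * scale
    df["detection_limit"] = df["detection_limit"] * scale
    return df.drop(columns=["units"])


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a validated table to CSV so that ``read_table`` round-trips it."""
    sch = _get_schema(schema)
    missing = [c for c in sch.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write schema {schema!r}: missing column(s) {missing}")
    out = df.copy()
    for c in sch.date_columns:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    if not sch.open_columns:
        out = out[list(sch.columns)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def _get_schema(schema: str) -> TableSchema:
    try:
        return SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}") from None


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """All stage tunables, loadable from a flat TOML file.

    Units: concentrations mg L^-1, distances km, gaps/intervals days.
    """

    seed: int = 42
    # harmonisation
    unit_anomaly_factor: float = 100.0
    substitution_fraction: float = 0.5
    max_censored_fraction: float = 0.10
    # baseflow separation
    alpha: float = 0.925
    passes: int = 3
    reflect_days: int = 30
    min_segment_days: int = 10
    min_baseflow_fraction: float = 0.75
    max_gauge_km: float = 50.0
    # date / season / eligibility filters
    year_min: int = 1990
    year_max: int = 2016
    window_years: int = 7
    tropics_abs_lat: float = 23.43695
    min_samples: int = 37
    max_interval_days: float = 61.0
    # regression
    max_exhaustive: int = 20
    selection_rule: str = "min_cp"  # or "cp_le_p"
    # classification
    ratio_boundary: float = 7.0
    tn_threshold: float = 0.800
    tp_threshold: float = 0.046
    equality_is_undesirable: bool = False
    # aggregation
    excluded_regions: tuple[str, ...] = ("Antarctica", "Greenland")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.passes < 1 or self.passes % 2 == 0:
            raise ValueError("passes must be odd and >= 1")
        if not 0 < self.max_censored_fraction < 1:
            raise ValueError("max_censored_fraction must be in (0, 1)")
        if not 0 < self.substitution_fraction < 1:
            raise ValueError("substitution_fraction must be in (0, 1)")
        if self.selection_rule not in ("min_cp", "cp_le_p"):
            raise ValueError("selection_rule must be 'min_cp' or 'cp_le_p'")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a TOML config file; unknown keys are rejected, missing keys default."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    data.update(overrides)
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "excluded_regions" in data:
        data["excluded_regions"] = tuple(data["excluded_regions"])
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# Stage provenance logging
# ---------------------------------------------------------------------------

class StageLog:
    """Counts rows in/out of a filter stage, with per-reason exclusion tallies.

    Filter accounting must balance: in = out + sum(excluded by reason).
    """

    def __init__(self, stage: str):
        self.stage = stage
        self.n_in = 0
        self.n_out = 0
        self.excluded: dict[str, int] = {}

    def record(self, n_in: int, n_out: int, reasons: dict[str, int] | None = None) -> None:
        self.n_in += int(n_in)
        self.n_out += int(n_out)
        for reason, count in (reasons or {}).items():
            self.excluded[reason] = self.excluded.get(reason, 0) + int(count)

    def check_balance(self) -> bool:
        return self.n_in == self.n_out + sum(self.excluded.values())

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "in": self.n_in,
            "out": self.n_out,
            "excluded": dict(self.excluded),
            "balanced": self.check_balance(),
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))
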