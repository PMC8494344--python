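"""Standardization and anomaly flagging of raw export tables.

The processing stage never edits raw columns: every standardized value goes
into a parallel ``*_proc`` column and every anomaly into a boolean ``flag_*``
column, so raw collection and isolation data are preserved verbatim for
review. Temperature unit mistakes are the most common field error — probes
and phones are often left in Fahrenheit — so readings above a configurable
threshold (default 40, implausibly hot for a Celsius field reading) are
auto-converted to Celsius and flagged for review. A second temperature check
flags *stuck-probe runs*: identical readings across several sequential
collections, which suggests the probe was not actually re-read.

Repairs (reverting a conversion judged wrong, or removing an erroneous
value) are programmatic and audited; nothing is ever silently changed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ProcessingConfig
from .errors import LookupError_, ParseError
from .project_io import RawBundle

_TEMP_FIELDS = {
    "ambient": "ambient_temperature_c",
    "substrate": "substrate_temperature",
}


def convert_temperature(
    value: float | None, threshold: float = 40.0
) -> tuple[float | None, bool]:
    """Convert a raw reading from Fahrenheit to Celsius if above ``threshold``.

    Values strictly greater than the threshold are converted via
    ``(value - 32) * 5/9``; values at or below pass through unchanged.
    Missing values pass through as missing.

    Returns ``(value_celsius, converted)``.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return value, False
    if not isinstance(value, (int, float, np.integer, np.floating)):
        raise ParseError(f"non-numeric temperature value: {value!r}")
    value = float(value)
    if value > threshold:
        return (value - 32.0) * 5.0 / 9.0, True
    return value, False


@dataclass
class ProcessedBundle:
    """Raw tables plus standardized columns, flags, and a repair audit trail."""

    field_sampling: pd.DataFrame
    field_sampling_sample_photo: pd.DataFrame
    isolation: pd.DataFrame
    isolation_s_labeled_plates: pd.DataFrame
    isolation_photos: pd.DataFrame
    prefix: str
    isolation_present: bool
    config: ProcessingConfig
    audit: list[dict] = field(default_factory=list)

    def copy(self) -> "ProcessedBundle":
        return ProcessedBundle(
            field_sampling=self.field_sampling.copy(),
            field_sampling_sample_photo=self.field_sampling_sample_photo.copy(),
            isolation=self.isolation.copy(),
            isolation_s_labeled_plates=self.isolation_s_labeled_plates.copy(),
            isolation_photos=self.isolation_photos.copy(),
            prefix=self.prefix,
            isolation_present=self.isolation_present,
            config=self.config,
            audit=list(self.audit),
        )


@dataclass
class TemperatureReport:
    """Review table of auto-converted values and stuck-probe runs."""

    conversions: pd.DataFrame  # record id, field, raw value, converted value
    runs: pd.DataFrame  # field, run index, record id, value, run length

    @property
    def empty(self) -> bool:
        return self.conversions.empty and self.runs.empty

    def to_text(self) -> str:
        lines = ["Temperature review", "=" * 18, "", "Converted values:"]
        if self.conversions.empty:
            lines.append("  (none)")
        else:
            lines.append(self.conversions.to_string(index=False))
        lines += ["", f"Stuck-probe runs:"]
        if self.runs.empty:
            lines.append("  (none)")
        else:
            lines.append(self.runs.to_string(index=False))
        return "\n".join(lines) + "\n"


def _coerce_numeric(series: pd.Series, table: str, col: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        idx = series.index[bad][0]
        raise ParseError(
            f"non-numeric value {series[idx]!r} in {table}.{col} (row {idx})"
        )
    return out.astype(float)


def _norm_labels(raw: pd.Series, pattern: str) -> tuple[pd.Series, pd.Series, pd.Series]:
    norm = raw.astype("string").str.strip().str.upper()
    norm = norm.replace("", pd.NA)
    missing = norm.isna()
    rx = re.compile(pattern)
    misformatted = norm.notna() & ~norm.fillna("").str.match(rx)
    return norm.astype(object), missing.astype(bool), misformatted.astype(bool)


def _parse_dates(df: pd.DataFrame) -> None:
    """Add ISO-8601 ``date_proc`` / 24-h ``time_proc`` columns plus a flag."""
    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    times = pd.to_datetime(df["time"], errors="coerce", format="mixed")
    df["date_proc"] = dates.dt.strftime("%Y-%m-%d")
    df["time_proc"] = times.dt.strftime("%H:%M:%S")
    df["flag_datetime_unparseable"] = (
        (dates.isna() & df["date"].notna()) | (times.isna() & df["time"].notna())
    ).astype(bool)


def _order_by_collection_time(fs: pd.DataFrame) -> pd.Index:
    """Collection order: date+time, ties broken by record id."""
    key = pd.DataFrame(
        {
            "d": fs["date_proc"].fillna("9999-12-31"),
            "t": fs["time_proc"].fillna("99:99:99"),
            "i": fs["fulcrum_id"].astype(str),
        },
        index=fs.index,
    )
    return key.sort_values(["d", "t", "i"], kind="stable").index


def _find_runs(values: pd.Series, order: pd.Index, min_len: int) -> list[list]:
    """Maximal runs of >= min_len identical consecutive non-missing values.

    Returns a list of runs, each a list of row indices in collection order.
    """
    runs: list[list] = []
    current: list = []
    prev = None
    for idx in order:
        v = values.loc[idx]
        if pd.notna(v) and prev is not None and v == prev:
            current.append(idx)
        else:
            if len(current) >= min_len:
                runs.append(current)
            current = [idx] if pd.notna(v) else []
        prev = v if pd.notna(v) else None
    if len(current) >= min_len:
        runs.append(current)
    return runs


def _refresh_run_flags(fs: pd.DataFrame, config: ProcessingConfig) -> None:
    order = _order_by_collection_time(fs)
    for fld in _TEMP_FIELDS:
        col = f"{_TEMP_FIELDS[fld]}_proc"
        flag = f"flag_{fld}_temperature_run"
        fs[flag] = False
        for run in _find_runs(fs[col], order, config.run_length_min):
            fs.loc[run, flag] = True


def proc_fulcrum(
    bundle: RawBundle, config: ProcessingConfig | None = None
) -> ProcessedBundle:
    """Standardize temperatures, dates/times, labels, and GPS fields.

    Adds ``*_proc`` columns and ``flag_*`` columns alongside the untouched
    raw columns; row counts are never changed. Out-of-range coordinates are
    flagged and blanked in the processed copy, never fatal.
    """
    config = config or ProcessingConfig()

    fs = bundle.field_sampling.copy()
    _parse_dates(fs)
    for fld, col in _TEMP_FIELDS.items():
        raw = _coerce_numeric(fs[col], "field_sampling", col)
        converted = raw > config.fahrenheit_threshold
        proc = raw.where(~converted, (raw - 32.0) * 5.0 / 9.0)
        fs[f"{col}_proc"] = proc
        fs[f"flag_{fld}_temperature_converted"] = converted.fillna(False).astype(bool)
    fs["ambient_humidity_proc"] = _coerce_numeric(
        fs["ambient_humidity"], "field_sampling", "ambient_humidity"
    )
    if "gps_altitude" in fs.columns:
        fs["altitude_proc"] = _coerce_numeric(
            fs["gps_altitude"], "field_sampling", "gps_altitude"
        )
    else:
        fs["altitude_proc"] = np.nan

    lat = _coerce_numeric(fs["latitude"], "field_sampling", "latitude")
    lon = _coerce_numeric(fs["longitude"], "field_sampling", "longitude")
    bad_gps = (lat.abs() > 90) | (lon.abs() > 180)
    fs["flag_gps_invalid"] = (bad_gps & lat.notna() & lon.notna()).astype(bool)
    fs["latitude_proc"] = lat.where(~bad_gps)
    fs["longitude_proc"] = lon.where(~bad_gps)

    norm, missing, misf = _norm_labels(fs["c_label"], config.c_label_pattern)
    fs["c_label_proc"] = norm
    fs["flag_c_label_missing"] = missing
    fs["flag_c_label_misformatted"] = misf
    _refresh_run_flags(fs, config)

    photos = bundle.field_sampling_sample_photo.copy()
    for col in ("exif_gps_latitude", "exif_gps_longitude", "exif_gps_dop"):
        photos[f"{col}_proc"] = _coerce_numeric(photos[col], "sample_photo", col)
    plat, plon = photos["exif_gps_latitude_proc"], photos["exif_gps_longitude_proc"]
    bad = (plat.abs() > 90) | (plon.abs() > 180)
    photos["exif_gps_latitude_proc"] = plat.where(~bad)
    photos["exif_gps_longitude_proc"] = plon.where(~bad)

    iso = bundle.isolation.copy()
    if len(iso):
        _parse_dates(iso)
    else:
        iso["date_proc"] = pd.Series(dtype=object)
        iso["time_proc"] = pd.Series(dtype=object)
        iso["flag_datetime_unparseable"] = pd.Series(dtype=bool)

    plates = bundle.isolation_s_labeled_plates.copy()
    norm, missing, misf = _norm_labels(
        plates["s_label"] if len(plates) else pd.Series(dtype=object),
        config.s_label_pattern,
    )
    plates["s_label_proc"] = norm
    plates["flag_s_label_missing"] = missing
    plates["flag_s_label_misformatted"] = misf

    return ProcessedBundle(
        field_sampling=fs,
        field_sampling_sample_photo=photos,
        isolation=iso,
        isolation_s_labeled_plates=plates,
        isolation_photos=bundle.isolation_photos.copy(),
        prefix=bundle.prefix,
        isolation_present=bundle.isolation_present,
        config=config,
    )


def check_temperatures(
    processed: ProcessedBundle, config: ProcessingConfig | None = None
) -> TemperatureReport:
    """Tabulate flagged conversions and stuck-probe runs for review."""
    config = config or processed.config
    fs = processed.field_sampling

    conv_rows = []
    for fld, col in _TEMP_FIELDS.items():
        flagged = fs[fs[f"flag_{fld}_temperature_converted"]]
        for _, row in flagged.iterrows():
            conv_rows.append(
                {
                    "fulcrum_id": row["fulcrum_id"],
                    "c_label": row.get("c_label_proc"),
                    "field": fld,
                    "raw_value": float(row[col]),
                    "converted_value": float(row[f"{col}_proc"]),
                }
            )
    conversions = pd.DataFrame(
        conv_rows,
        columns=["fulcrum_id", "c_label", "field", "raw_value", "converted_value"],
    )

    run_rows = []
    order = _order_by_collection_time(fs)
    for fld, col in _TEMP_FIELDS.items():
        for k, run in enumerate(
            _find_runs(fs[f"{col}_proc"], order, config.run_length_min)
        ):
            for idx in run:
                run_rows.append(
                    {
                        "field": fld,
                        "run": k,
                        "fulcrum_id": fs.loc[idx, "fulcrum_id"],
                        "value": float(fs.loc[idx, f"{col}_proc"]),
                        "run_length": len(run),
                    }
                )
    runs = pd.DataFrame(
        run_rows, columns=["field", "run", "fulcrum_id", "value", "run_length"]
    )
    return TemperatureReport(conversions=conversions, runs=runs)


def fix_temperatures(
    processed: ProcessedBundle,
    revert_ids: list[tuple[str, str]] | None = None,
    remove_ids: list[tuple[str, str]] | None = None,
) -> ProcessedBundle:
    """Revert mis-converted temperatures and remove erroneous ones.

    ``revert_ids`` / ``remove_ids`` are lists of ``(record id, field)``
    pairs where field is ``"ambient"`` or ``"substrate"``. Reverts restore
    the raw value and clear the converted flag; removals blank the processed
    value. Every action (including a no-op revert of a non-converted field)
    is appended to the bundle's audit trail. Returns a new bundle.
    """
    out = processed.copy()
    fs = out.field_sampling

    def _locate(rec_id: str, fld: str) -> int:
        if fld not in _TEMP_FIELDS:
            raise LookupError_(f"unknown temperature field {fld!r}")
        hits = fs.index[fs["fulcrum_id"] == rec_id]
        if len(hits) == 0:
            raise LookupError_(f"record id {rec_id!r} not found in field_sampling")
        return hits[0]

    for rec_id, fld in revert_ids or []:
        idx = _locate(rec_id, fld)
        col = _TEMP_FIELDS[fld]
        flag = f"flag_{fld}_temperature_converted"
        if not bool(fs.loc[idx, flag]):
            out.audit.append(
                {
                    "action": "revert",
                    "fulcrum_id": rec_id,
                    "field": fld,
                    "note": "no-op: field was not converted",
                }
            )
            continue
        old = float(fs.loc[idx, f"{col}_proc"])
        new = float(fs.loc[idx, col])
        fs.loc[idx, f"{col}_proc"] = new
        fs.loc[idx, flag] = False
        out.audit.append(
            {
                "action": "revert",
                "fulcrum_id": rec_id,
                "field": fld,
                "old": old,
                "new": new,
                "note": "conversion reverted after review",
            }
        )

    for rec_id, fld in remove_ids or []:
        idx = _locate(rec_id, fld)
        col = _TEMP_FIELDS[fld]
        old = fs.loc[idx, f"{col}_proc"]
        fs.loc[idx, f"{col}_proc"] = np.nan
        out.audit.append(
            {
                "action": "remove",
                "fulcrum_id": rec_id,
                "field": fld,
                "old": None if pd.isna(old) else float(old),
                "new": None,
                "note": "erroneous value removed after review",
            }
        )

    _refresh_run_flags(fs, out.config)
    return out
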