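"""Project directory layout, export-prefix discovery, and raw-CSV ingestion.

A sampling project lives in a fixed directory tree: raw app exports under
``data/raw/fulcrum`` (photos in a ``photos`` subfolder, spatial annotation
files under ``data/raw/annotate``), processed outputs under
``data/processed``, and reports/scripts at the top level. The mobile app
exports five CSV files per project, named ``<prefix>_field_sampling.csv``,
``<prefix>_field_sampling_sample_photo.csv``, ``<prefix>_isolation.csv``,
``<prefix>_isolation_s_labeled_plates.csv``, and
``<prefix>_isolation_photos.csv``; the three isolation files are absent when
no laboratory isolations were performed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import (
    AmbiguousPrefixError,
    InvalidPathError,
    MissingExportError,
    ParseError,
    SchemaError,
)

#: roles of the five raw export tables, in the canonical file order
TABLE_ROLES = (
    "field_sampling",
    "field_sampling_sample_photo",
    "isolation",
    "isolation_s_labeled_plates",
    "isolation_photos",
)

#: minimum column contract per table. The field-sampling and isolation app
#: field data-names, plus the record identifiers every export carries and
#: the GPS columns the downstream location logic requires.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "field_sampling": (
        "fulcrum_id",
        "c_label",
        "date",
        "time",
        "sample_photo",
        "gridsect",
        "substrate_temperature",
        "ambient_temperature_c",
        "ambient_humidity",
        "latitude",
        "longitude",
    ),
    "field_sampling_sample_photo": (
        "fulcrum_id",
        "fulcrum_parent_id",
        "exif_gps_latitude",
        "exif_gps_longitude",
        "exif_gps_dop",
    ),
    "isolation": (
        "fulcrum_id",
        "c_label",
        "date",
        "time",
        "worms_on_sample",
    ),
    "isolation_s_labeled_plates": (
        "fulcrum_id",
        "fulcrum_parent_id",
        "s_label",
    ),
    "isolation_photos": (
        "fulcrum_id",
        "fulcrum_parent_id",
    ),
}

_ISOLATION_ROLES = ("isolation", "isolation_s_labeled_plates", "isolation_photos")


@dataclass(frozen=True)
class ProjectLayout:
    """The fixed directory tree of one sampling project."""

    root: Path

    @property
    def raw_fulcrum_dir(self) -> Path:
        return self.root / "data" / "raw" / "fulcrum"

    @property
    def raw_photos_dir(self) -> Path:
        return self.raw_fulcrum_dir / "photos"

    @property
    def raw_annotate_dir(self) -> Path:
        return self.root / "data" / "raw" / "annotate"

    @property
    def processed_fulcrum_dir(self) -> Path:
        return self.root / "data" / "processed" / "fulcrum"

    @property
    def processed_photos_dir(self) -> Path:
        return self.processed_fulcrum_dir / "photos"

    @property
    def thumbnails_dir(self) -> Path:
        return self.processed_photos_dir / "thumbnails"

    @property
    def processed_genotypes_dir(self) -> Path:
        return self.root / "data" / "processed" / "genotypes"

    @property
    def reports_dir(self) -> Path:
        return self.root / "reports"

    @property
    def scripts_dir(self) -> Path:
        return self.root / "scripts"

    def directories(self) -> tuple[Path, ...]:
        return (
            self.raw_fulcrum_dir,
            self.raw_photos_dir,
            self.raw_annotate_dir,
            self.processed_fulcrum_dir,
            self.processed_photos_dir,
            self.thumbnails_dir,
            self.processed_genotypes_dir,
            self.reports_dir,
            self.scripts_dir,
        )


@dataclass
class RawBundle:
    """The five raw export tables of one project, read verbatim.

    ``isolation_present`` is False when the project has no laboratory
    isolation data, in which case the three isolation tables are empty
    frames with their contractual columns.
    """

    field_sampling: pd.DataFrame
    field_sampling_sample_photo: pd.DataFrame
    isolation: pd.DataFrame
    isolation_s_labeled_plates: pd.DataFrame
    isolation_photos: pd.DataFrame
    prefix: str
    isolation_present: bool

    def table(self, role: str) -> pd.DataFrame:
        if role not in TABLE_ROLES:
            raise KeyError(role)
        return getattr(self, role)


def make_directory_structure(root: Path | str) -> ProjectLayout:
    """Create (or complete) the project directory tree at ``root``.

    Idempotent: existing directories and files are left untouched; only
    missing directories are created.
    """
    root = Path(root)
    if root.exists() and not root.is_dir():
        raise InvalidPathError(f"{root} exists and is not a directory")
    layout = ProjectLayout(root=root)
    try:
        for d in layout.directories():
            d.mkdir(parents=True, exist_ok=True)
    except PermissionError:
        raise
    return layout


def detect_prefix(raw_fulcrum_dir: Path | str) -> str:
    """Discover the export-file prefix from ``<prefix>_field_sampling.csv``."""
    raw_fulcrum_dir = Path(raw_fulcrum_dir)
    suffix = "_field_sampling.csv"
    prefixes = sorted(
        p.name[: -len(suffix)]
        for p in raw_fulcrum_dir.glob(f"*{suffix}")
        if p.name.endswith(suffix) and len(p.name) > len(suffix)
    )
    if not prefixes:
        raise MissingExportError(
            f"no '<prefix>_field_sampling.csv' export found in {raw_fulcrum_dir}"
        )
    if len(prefixes) > 1:
        raise AmbiguousPrefixError(prefixes)
    return prefixes[0]


def _read_csv(path: Path, role: str) -> pd.DataFrame:
    """Read one export CSV: UTF-8, comma, RFC-4180 quoting, header row.

    Empty strings become missing values; all cells are kept as strings so
    the raw data round-trips verbatim (typed copies are added later by the
    processing stage).
    """
    try:
        df = pd.read_csv(
            path,
            dtype=str,
            encoding="utf-8",
            keep_default_na=False,
            quoting=csv.QUOTE_MINIMAL,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed CSV in {path.name}: {exc}") from exc
    df = df.mask(df == "")
    missing = [c for c in REQUIRED_COLUMNS[role] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name} is missing required column(s): {', '.join(missing)}"
        )
    return df


def _empty_table(role: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in REQUIRED_COLUMNS[role]})


def read_fulcrum(layout: ProjectLayout, prefix: str | None = None) -> RawBundle:
    """Read the raw export CSVs of a project into a :class:`RawBundle`.

    The two field-sampling tables are mandatory. The three isolation tables
    are optional as a trio: all present or all absent; a partial trio is a
    schema error (silently dropping specimen labels would be worse).
    """
    raw_dir = layout.raw_fulcrum_dir
    if prefix is None:
        prefix = detect_prefix(raw_dir)

    paths = {role: raw_dir / f"{prefix}_{role}.csv" for role in TABLE_ROLES}
    for role in ("field_sampling", "field_sampling_sample_photo"):
        if not paths[role].exists():
            raise MissingExportError(f"required export {paths[role].name} not found")

    present = [role for role in _ISOLATION_ROLES if paths[role].exists()]
    if present and len(present) < len(_ISOLATION_ROLES):
        absent = sorted(set(_ISOLATION_ROLES) - set(present))
        raise SchemaError(
            f"partial isolation export: present={present}, missing={absent}; "
            "the three isolation files must be exported together"
        )
    isolation_present = bool(present)

    tables = {}
    for role in TABLE_ROLES:
        if role in _ISOLATION_ROLES and not isolation_present:
            tables[role] = _empty_table(role)
        else:
            tables[role] = _read_csv(paths[role], role)

    return RawBundle(prefix=prefix, isolation_present=isolation_present, **tables)
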