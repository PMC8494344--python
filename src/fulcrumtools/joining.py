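"""Joining field collections, isolations, specimen labels, and photo GPS.

The unified long table has one row per isolated specimen (S-label), or a
single row for a collection without isolations, so no field collection is
ever lost by the join. Each collection gets a *best photo* — the one whose
GPS dilution-of-precision estimate (``exif_gps_dop``, meters; smaller is
more precise) is smallest — and its final location prefers the best-photo
GPS over the location recorded when the collection record was created,
because photos are typically taken at the sample itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ProcessingConfig
from .errors import IntegrityError
from .qc import ProcessedBundle

#: mapping of the isolation app's worms-on-sample answers to categories
WORMS_CATEGORIES = {
    "yes": "present",
    "no": "absent",
    "tracks": "tracks_only",
    "?": "unknown",
}

#: which raw export file is responsible for each flag type
FLAG_SOURCE_FILES = {
    "flag_ambient_temperature_converted": "field_sampling",
    "flag_substrate_temperature_converted": "field_sampling",
    "flag_ambient_temperature_run": "field_sampling",
    "flag_substrate_temperature_run": "field_sampling",
    "flag_ambient_temperature_extreme": "field_sampling",
    "flag_substrate_temperature_extreme": "field_sampling",
    "flag_altitude_extreme": "field_sampling",
    "flag_gps_invalid": "field_sampling",
    "flag_datetime_unparseable": "field_sampling",
    "flag_c_label_missing": "field_sampling",
    "flag_c_label_misformatted": "field_sampling",
    "flag_c_label_duplicated": "field_sampling",
    "flag_s_label_missing": "isolation_s_labeled_plates",
    "flag_s_label_misformatted": "isolation_s_labeled_plates",
    "flag_s_label_duplicated": "isolation_s_labeled_plates",
    "flag_photo_missing": "field_sampling_sample_photo",
    "flag_orphan_isolation": "isolation",
}


def select_best_photo(photos: pd.DataFrame) -> pd.Series | None:
    """Pick the photo with the most precise GPS fix among one collection's photos.

    Minimal ``exif_gps_dop`` wins (missing treated as +inf); ties are broken
    by lexicographic photo record id so reruns are deterministic. Returns the
    photo row, or ``None`` for an empty set.
    """
    if photos is None or len(photos) == 0:
        return None
    dop_col = (
        "exif_gps_dop_proc" if "exif_gps_dop_proc" in photos.columns else "exif_gps_dop"
    )
    dop = pd.to_numeric(photos[dop_col], errors="coerce").fillna(np.inf)
    key = pd.DataFrame(
        {"dop": dop.to_numpy(), "pid": photos["fulcrum_id"].astype(str).to_numpy()}
    )
    best_pos = key.sort_values(["dop", "pid"], kind="stable").index[0]
    return photos.iloc[int(best_pos)]


def _fill_false(s: pd.Series) -> pd.Series:
    s = s.astype(object)
    return s.where(s.notna(), False).astype(bool)


def _mark_duplicates(labels: pd.Series) -> pd.Series:
    """True for every member of a group sharing a non-missing label."""
    counts = labels.dropna().value_counts()
    dup = set(counts[counts > 1].index)
    return labels.map(lambda v: v in dup if pd.notna(v) else False).astype(bool)


def _worms_category(raw) -> str:
    if pd.isna(raw):
        return "unknown"
    return WORMS_CATEGORIES.get(str(raw).strip().lower(), "unknown")


def join_fulcrum(
    processed: ProcessedBundle, config: ProcessingConfig | None = None
) -> pd.DataFrame:
    """Build the unified long table from a processed bundle.

    Steps, in order: attach the best photo (and its GPS) to each collection;
    resolve the final location (photo GPS preferred, record GPS as fallback);
    join isolations onto collections by collection record id; expand
    specimen S-labels; compute project-wide flags (extreme values, duplicate
    or missing labels, missing photos, orphan isolations).

    Duplicate collection record ids are a fatal integrity error. Isolations
    referencing an unknown collection record are retained and flagged.
    """
    config = config or processed.config
    fs = processed.field_sampling
    photos = processed.field_sampling_sample_photo

    if fs["fulcrum_id"].duplicated().any():
        dups = fs.loc[fs["fulcrum_id"].duplicated(), "fulcrum_id"].tolist()
        raise IntegrityError(f"duplicate collection record ids: {dups}")
    if processed.isolation_present and processed.isolation["fulcrum_id"].duplicated().any():
        raise IntegrityError("duplicate isolation record ids")

    # --- best photo per collection ---------------------------------------
    best_rows = {}
    if len(photos):
        for parent, grp in photos.groupby("fulcrum_parent_id"):
            best = select_best_photo(grp)
            if best is not None:
                best_rows[parent] = best

    base = pd.DataFrame(
        {
            "c_label": fs["c_label_proc"],
            "collection_fulcrum_id": fs["fulcrum_id"],
            "collection_date": fs["date_proc"],
            "collection_time": fs["time_proc"],
            "collection_by": fs.get("created_by", pd.Series(index=fs.index, dtype=object)),
            "record_latitude": fs["latitude_proc"],
            "record_longitude": fs["longitude_proc"],
            "ambient_temperature_c": fs["ambient_temperature_c_proc"],
            "substrate_temperature_c": fs["substrate_temperature_proc"],
            "ambient_humidity": fs["ambient_humidity_proc"],
            "altitude": fs["altitude_proc"],
            "gridsect": fs["gridsect"],
            "substrate": fs.get("substrate", pd.Series(index=fs.index, dtype=object)),
        }
    )
    for flag in (
        "flag_ambient_temperature_converted",
        "flag_substrate_temperature_converted",
        "flag_ambient_temperature_run",
        "flag_substrate_temperature_run",
        "flag_gps_invalid",
        "flag_datetime_unparseable",
        "flag_c_label_missing",
        "flag_c_label_misformatted",
    ):
        base[flag] = fs[flag].astype(bool)

    ids = fs["fulcrum_id"]
    base["best_photo_id"] = ids.map(
        lambda i: best_rows[i]["fulcrum_id"] if i in best_rows else np.nan
    )
    base["best_photo_filename"] = base["best_photo_id"].map(
        lambda p: f"{p}.jpg" if pd.notna(p) else np.nan
    )
    base["photo_latitude"] = ids.map(
        lambda i: best_rows[i]["exif_gps_latitude_proc"] if i in best_rows else np.nan
    ).astype(float)
    base["photo_longitude"] = ids.map(
        lambda i: best_rows[i]["exif_gps_longitude_proc"] if i in best_rows else np.nan
    ).astype(float)
    base["flag_photo_missing"] = base["best_photo_id"].isna()

    # --- final location: photo GPS preferred over record GPS -------------
    has_photo_gps = base["photo_latitude"].notna() & base["photo_longitude"].notna()
    has_record_gps = base["record_latitude"].notna() & base["record_longitude"].notna()
    base["location_source"] = np.where(
        has_photo_gps, "photo", np.where(has_record_gps, "record", "none")
    )
    base["latitude"] = np.where(
        has_photo_gps, base["photo_latitude"], base["record_latitude"]
    )
    base["longitude"] = np.where(
        has_photo_gps, base["photo_longitude"], base["record_longitude"]
    )

    # --- project-wide flags ----------------------------------------------
    base["flag_c_label_duplicated"] = _mark_duplicates(base["c_label"])
    lo, hi = config.ambient_temp_range
    base["flag_ambient_temperature_extreme"] = (
        (base["ambient_temperature_c"] < lo) | (base["ambient_temperature_c"] > hi)
    ).fillna(False).astype(bool)
    lo, hi = config.substrate_temp_range
    base["flag_substrate_temperature_extreme"] = (
        (base["substrate_temperature_c"] < lo) | (base["substrate_temperature_c"] > hi)
    ).fillna(False).astype(bool)
    lo, hi = config.altitude_range
    base["flag_altitude_extreme"] = (
        (base["altitude"] < lo) | (base["altitude"] > hi)
    ).fillna(False).astype(bool)

    # --- join isolations and expand S-labels ------------------------------
    iso = processed.isolation
    plates = processed.isolation_s_labeled_plates
    iso_cols = pd.DataFrame(
        {
            "isolation_fulcrum_id": iso["fulcrum_id"],
            "collection_fulcrum_id": iso["c_label"],
            "isolation_date": iso["date_proc"],
            "isolation_time": iso["time_proc"],
            "isolation_by": iso.get("created_by", pd.Series(index=iso.index, dtype=object)),
            "worms_on_sample": iso["worms_on_sample"].map(_worms_category)
            if len(iso)
            else pd.Series(dtype=object),
        }
    )

    if processed.isolation_present and len(iso_cols):
        joined = base.merge(iso_cols, on="collection_fulcrum_id", how="left")
        orphans = iso_cols[
            ~iso_cols["collection_fulcrum_id"].isin(base["collection_fulcrum_id"])
        ]
        if len(orphans):
            orphan_rows = orphans.copy()
            orphan_rows["flag_orphan_isolation"] = True
            joined = pd.concat([joined, orphan_rows], ignore_index=True)
        joined["flag_orphan_isolation"] = (
            joined.get("flag_orphan_isolation", False)
        )
        joined["flag_orphan_isolation"] = _fill_false(joined["flag_orphan_isolation"])

        plate_cols = pd.DataFrame(
            {
                "isolation_fulcrum_id": plates["fulcrum_parent_id"],
                "s_label": plates["s_label_proc"],
                "flag_s_label_missing": plates["flag_s_label_missing"],
                "flag_s_label_misformatted": plates["flag_s_label_misformatted"],
            }
        )
        plate_cols["flag_s_label_duplicated"] = _mark_duplicates(plate_cols["s_label"])
        joined = joined.merge(plate_cols, on="isolation_fulcrum_id", how="left")
    else:
        joined = base.copy()
        joined["isolation_fulcrum_id"] = np.nan
        joined["isolation_date"] = np.nan
        joined["isolation_time"] = np.nan
        joined["isolation_by"] = np.nan
        joined["worms_on_sample"] = "unknown"
        joined["flag_orphan_isolation"] = False
        joined["s_label"] = np.nan
        joined["flag_s_label_missing"] = False
        joined["flag_s_label_misformatted"] = False
        joined["flag_s_label_duplicated"] = False

    joined["worms_on_sample"] = joined["worms_on_sample"].fillna("unknown")
    for col in (
        "flag_s_label_missing",
        "flag_s_label_misformatted",
        "flag_s_label_duplicated",
    ):
        joined[col] = _fill_false(joined[col])
    for col in joined.columns:
        if col.startswith("flag_"):
            joined[col] = _fill_false(joined[col])

    return joined.reset_index(drop=True)


@dataclass
class JoinReport:
    """Per-flag summary of the joined table, naming the responsible file."""

    entries: pd.DataFrame  # flag, source_file, count, labels

    @property
    def empty(self) -> bool:
        return self.entries.empty

    def to_text(self) -> str:
        if self.entries.empty:
            return "Join review: no flags raised.\n"
        return "Join review\n===========\n" + self.entries.to_string(index=False) + "\n"


def check_join(joined: pd.DataFrame) -> JoinReport:
    """Group raised flags by type, listing affected labels and source files."""
    rows = []
    for flag in sorted(c for c in joined.columns if c.startswith("flag_")):
        hit = joined[joined[flag]]
        if hit.empty:
            continue
        labels = sorted(
            set(hit["c_label"].dropna().astype(str))
            | set(hit.get("s_label", pd.Series(dtype=object)).dropna().astype(str))
        )
        rows.append(
            {
                "flag": flag,
                "source_file": FLAG_SOURCE_FILES.get(flag, "field_sampling"),
                "count": int(len(hit)),
                "labels": ";".join(labels),
            }
        )
    return JoinReport(
        entries=pd.DataFrame(rows, columns=["flag", "source_file", "count", "labels"])
    )
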