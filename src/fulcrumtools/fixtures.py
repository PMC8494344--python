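"""Seeded synthetic sampling projects for testing the whole workflow.

Generates everything a real project export would contain — the five raw
CSV files, stub JPEG photos named by record id, a genotyping sheet, and a
GeoJSON feature file — plus a ground-truth *anomaly manifest* listing every
defect injected (Fahrenheit readings, stuck-probe runs, duplicated/missing/
misformatted labels, missing photo files, genotyping-sheet mistakes), so
downstream flag recovery can be scored exactly.

A single integer seed determines every byte of output. Clean data are drawn
so that no flag can fire by accident: temperatures are continuous draws
(identical consecutive values have probability zero) well below the
Fahrenheit threshold, labels follow their grammars, and every photo file is
written. Injected Fahrenheit values are drawn from [60, 110], unambiguously
above the default threshold of 40.
"""

from __future__ import annotations

import datetime
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FixtureSpecError
from .project_io import ProjectLayout

SPECIES_POOL = (
    "Caenorhabditis briggsae",
    "Caenorhabditis elegans",
    "Caenorhabditis tropicalis",
    "Oscheius tipulae",
)

SUBSTRATE_POOL = ("rotting fruit", "leaf litter", "rotting stem", "compost", "soil")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic project.

    Rates are per-record probabilities; ``s_labels_per_isolation`` maps a
    specimen count to its probability. ``stuck_run_lengths`` gives the
    length of each injected stuck-probe run (substrate series).
    ``bounding_region`` is (lon_min, lat_min, lon_max, lat_max) in WGS84.
    """

    prefix: str = "nematode"
    n_collections: int = 30
    isolation_rate: float = 0.8
    s_labels_per_isolation: dict[int, float] = field(
        default_factory=lambda: {0: 0.25, 1: 0.30, 2: 0.25, 3: 0.15, 4: 0.05}
    )
    fahrenheit_rate: float = 0.0
    stuck_run_lengths: tuple[int, ...] = ()
    duplicate_c_label_rate: float = 0.0
    missing_c_label_rate: float = 0.0
    misformat_rate: float = 0.0
    missing_photo_rate: float = 0.0
    duplicate_s_label_rate: float = 0.0
    missing_s_label_rate: float = 0.0
    sheet_anomaly_rates: dict[str, float] = field(default_factory=dict)
    genotype_rate: float = 0.9
    bounding_region: tuple[float, float, float, float] = (-159.8, 21.85, -159.3, 22.25)
    dop_range: tuple[float, float] = (2.0, 15.0)
    photos_per_collection: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "isolation_rate": self.isolation_rate,
            "fahrenheit_rate": self.fahrenheit_rate,
            "duplicate_c_label_rate": self.duplicate_c_label_rate,
            "missing_c_label_rate": self.missing_c_label_rate,
            "misformat_rate": self.misformat_rate,
            "missing_photo_rate": self.missing_photo_rate,
            "duplicate_s_label_rate": self.duplicate_s_label_rate,
            "missing_s_label_rate": self.missing_s_label_rate,
            "genotype_rate": self.genotype_rate,
            **{f"sheet:{k}": v for k, v in self.sheet_anomaly_rates.items()},
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"rate {name}={v} outside [0, 1]")
        if abs(sum(self.s_labels_per_isolation.values()) - 1.0) > 1e-9:
            raise FixtureSpecError("s_labels_per_isolation probabilities must sum to 1")
        if any(l < 2 for l in self.stuck_run_lengths):
            raise FixtureSpecError("stuck-run lengths must be >= 2")


@dataclass
class AnomalyManifest:
    """Ground truth of every injected defect, plus expected flag counts."""

    entries: list[dict] = field(default_factory=list)
    expected_flag_counts: dict[str, int] = field(default_factory=dict)

    def add(self, anomaly: str, file: str, record_id: str, fld: str, injected, true) -> None:
        self.entries.append(
            {
                "anomaly": anomaly,
                "file": file,
                "record_id": record_id,
                "field": fld,
                "injected": injected,
                "true": true,
            }
        )

    def count(self, anomaly: str) -> int:
        return sum(1 for e in self.entries if e["anomaly"] == anomaly)

    def to_json(self) -> str:
        return json.dumps(
            {"entries": self.entries, "expected_flag_counts": self.expected_flag_counts},
            indent=1,
            default=str,
        )


def _record_id(rng: np.random.Generator, i: int) -> str:
    tail = "".join(rng.choice(list("0123456789abcdef"), size=12))
    return f"{i:04d}{tail}"


def _stub_jpeg(rng: np.random.Generator) -> bytes:
    rgb = tuple(int(v) for v in rng.integers(0, 256, size=3))
    im = Image.new("RGB", (16, 12), rgb)
    buf = io.BytesIO()
    im.save(buf, format="JPEG", quality=85)
    return buf.getvalue()


def _pick_disjoint(rng: np.random.Generator, n: int, rates: dict[str, float]) -> dict[str, list[int]]:
    """Binomially sized, mutually disjoint index sets — one anomaly per record."""
    order = rng.permutation(n).tolist()
    out: dict[str, list[int]] = {}
    cursor = 0
    for name, rate in rates.items():
        k = int(rng.binomial(n, rate))
        k = min(k, len(order) - cursor)
        out[name] = sorted(order[cursor : cursor + k])
        cursor += k
    return out


def generate_project(spec: FixtureSpec, layout: ProjectLayout) -> AnomalyManifest:
    """Write a full synthetic project under ``layout`` and return its manifest."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    manifest = AnomalyManifest()
    lon0, lat0, lon1, lat1 = spec.bounding_region
    n = spec.n_collections

    start = datetime.datetime(2021, 3, 1, 8, 0, 0)

    # --- clean collections, in strict time order ---------------------------
    coll_ids = [_record_id(rng, i) for i in range(n)]
    rows = []
    for i, cid in enumerate(coll_ids):
        dt = start + datetime.timedelta(minutes=7 * i)
        rows.append(
            {
                "fulcrum_id": cid,
                "created_by": "sampler1",
                "date": dt.strftime("%Y-%m-%d"),
                "time": dt.strftime("%H:%M:%S"),
                "c_label": f"C-{1000 + i}",
                "gridsect": str(int(rng.integers(1, 10))),
                "substrate": str(rng.choice(SUBSTRATE_POOL)),
                "substrate_temperature": round(float(rng.uniform(10, 35)), 3),
                "ambient_temperature_c": round(float(rng.uniform(12, 32)), 3),
                "ambient_humidity": round(float(rng.uniform(30, 100)), 1),
                "gps_altitude": round(float(rng.uniform(0, 900)), 1),
                "latitude": round(float(rng.uniform(lat0, lat1)), 6),
                "longitude": round(float(rng.uniform(lon0, lon1)), 6),
            }
        )
    fs = pd.DataFrame(rows)

    # --- stuck-probe runs (substrate), then Fahrenheit injections ----------
    run_members: set[int] = set()
    pos = 0
    for run_len in spec.stuck_run_lengths:
        if pos + run_len + 1 > n:
            raise FixtureSpecError("stuck runs do not fit in n_collections")
        value = round(float(rng.uniform(10, 35)), 3)
        idxs = list(range(pos, pos + run_len))
        for idx in idxs:
            manifest.add(
                "stuck_run",
                "field_sampling",
                coll_ids[idx],
                "substrate",
                value,
                float(fs.loc[idx, "substrate_temperature"]),
            )
            fs.loc[idx, "substrate_temperature"] = value
        run_members.update(idxs)
        pos += run_len + 1  # leave a gap so runs stay maximal and separate

    for fld, col in (("ambient", "ambient_temperature_c"), ("substrate", "substrate_temperature")):
        for idx in range(n):
            if fld == "substrate" and idx in run_members:
                continue
            if rng.random() < spec.fahrenheit_rate:
                injected = round(float(rng.uniform(60, 110)), 2)
                manifest.add(
                    "fahrenheit", "field_sampling", coll_ids[idx], fld,
                    injected, float(fs.loc[idx, col]),
                )
                fs.loc[idx, col] = injected

    # --- C-label anomalies (disjoint) --------------------------------------
    picks = _pick_disjoint(
        rng,
        n,
        {
            "duplicate": spec.duplicate_c_label_rate,
            "missing": spec.missing_c_label_rate,
            "misformat": spec.misformat_rate,
        },
    )
    usable_sources = [
        i for i in range(n)
        if i not in set(picks["duplicate"]) | set(picks["missing"]) | set(picks["misformat"])
    ]
    dup_targets = picks["duplicate"][: len(usable_sources)]
    for idx, src in zip(dup_targets, usable_sources):
        injected = fs.loc[src, "c_label"]
        manifest.add(
            "duplicate_c_label", "field_sampling", coll_ids[idx], "c_label",
            injected, fs.loc[idx, "c_label"],
        )
        fs.loc[idx, "c_label"] = injected
    for idx in picks["missing"]:
        manifest.add(
            "missing_c_label", "field_sampling", coll_ids[idx], "c_label",
            None, fs.loc[idx, "c_label"],
        )
        fs.loc[idx, "c_label"] = ""
    for idx in picks["misformat"]:
        injected = fs.loc[idx, "c_label"].replace("-", "")  # e.g. C1005
        manifest.add(
            "misformat_c_label", "field_sampling", coll_ids[idx], "c_label",
            injected, fs.loc[idx, "c_label"],
        )
        fs.loc[idx, "c_label"] = injected

    # --- sample photos ------------------------------------------------------
    missing_photo_idx = sorted(
        int(i) for i in range(n) if rng.random() < spec.missing_photo_rate
    )
    photo_rows = []
    photo_files: dict[str, bytes] = {}
    sample_photo_col = []
    for i, cid in enumerate(coll_ids):
        lo, hi = spec.photos_per_collection
        n_photos = 1 if i in missing_photo_idx else int(rng.integers(lo, hi + 1))
        pids = []
        for j in range(n_photos):
            pid = _record_id(rng, 1000 + i * 10 + j)
            pids.append(pid)
            photo_rows.append(
                {
                    "fulcrum_id": pid,
                    "fulcrum_parent_id": cid,
                    "created_by": "sampler1",
                    "captured_at": f"{fs.loc[i, 'date']} {fs.loc[i, 'time']}",
                    "exif_gps_latitude": round(
                        float(fs.loc[i, "latitude"]) + float(rng.uniform(-1e-4, 1e-4)), 6
                    ),
                    "exif_gps_longitude": round(
                        float(fs.loc[i, "longitude"]) + float(rng.uniform(-1e-4, 1e-4)), 6
                    ),
                    "exif_gps_altitude": fs.loc[i, "gps_altitude"],
                    "exif_gps_dop": round(float(rng.uniform(*spec.dop_range)), 2),
                }
            )
            if i in missing_photo_idx:
                manifest.add(
                    "missing_photo_file", "photos", pid, "file", None, f"{pid}.jpg"
                )
            else:
                photo_files[f"{pid}.jpg"] = _stub_jpeg(rng)
        sample_photo_col.append(",".join(pids))
    fs["sample_photo"] = sample_photo_col
    photos = pd.DataFrame(photo_rows)

    # --- isolations and S-labeled plates ------------------------------------
    counts = sorted(spec.s_labels_per_isolation)
    probs = [spec.s_labels_per_isolation[k] for k in counts]
    iso_rows, plate_rows, iso_photo_rows = [], [], []
    s_serial = 0
    for i, cid in enumerate(coll_ids):
        if rng.random() >= spec.isolation_rate:
            continue
        iid = _record_id(rng, 5000 + i)
        n_s = int(rng.choice(counts, p=probs))
        worms = "Yes" if n_s > 0 else ("Tracks" if rng.random() < 0.5 else "No")
        iso_dt = start + datetime.timedelta(days=1, minutes=5 * i)
        plate_ids = []
        for _ in range(n_s):
            plid = _record_id(rng, 9000 + s_serial)
            plate_ids.append(plid)
            plate_rows.append(
                {
                    "fulcrum_id": plid,
                    "fulcrum_parent_id": iid,
                    "s_label": f"S-{2000 + s_serial}",
                }
            )
            s_serial += 1
        ipid = _record_id(rng, 7000 + i)
        iso_photo_rows.append(
            {
                "fulcrum_id": ipid,
                "fulcrum_parent_id": iid,
                "captured_at": iso_dt.strftime("%Y-%m-%d %H:%M:%S"),
            }
        )
        photo_files[f"{ipid}.jpg"] = _stub_jpeg(rng)
        iso_rows.append(
            {
                "fulcrum_id": iid,
                "created_by": "isolator1",
                "c_label": cid,
                "date": iso_dt.strftime("%Y-%m-%d"),
                "time": iso_dt.strftime("%H:%M:%S"),
                "worms_on_sample": worms,
                "approximate_number_of_worms": str(n_s * 3),
                "photos": ipid,
                "s_labeled_plates": ",".join(plate_ids),
            }
        )
    iso = pd.DataFrame(iso_rows)
    plates = pd.DataFrame(plate_rows)
    iso_photos = pd.DataFrame(iso_photo_rows)

    # --- S-label anomalies (disjoint, on plate rows) -------------------------
    np_ = len(plates)
    if np_:
        s_picks = _pick_disjoint(
            rng,
            np_,
            {
                "duplicate": spec.duplicate_s_label_rate,
                "missing": spec.missing_s_label_rate,
                "misformat": spec.misformat_rate,
            },
        )
        taken = set(s_picks["duplicate"]) | set(s_picks["missing"]) | set(s_picks["misformat"])
        s_sources = [i for i in range(np_) if i not in taken]
        for idx, src in zip(s_picks["duplicate"][: len(s_sources)], s_sources):
            injected = plates.loc[src, "s_label"]
            manifest.add(
                "duplicate_s_label", "isolation_s_labeled_plates",
                plates.loc[idx, "fulcrum_id"], "s_label",
                injected, plates.loc[idx, "s_label"],
            )
            plates.loc[idx, "s_label"] = injected
        for idx in s_picks["missing"]:
            manifest.add(
                "missing_s_label", "isolation_s_labeled_plates",
                plates.loc[idx, "fulcrum_id"], "s_label",
                None, plates.loc[idx, "s_label"],
            )
            plates.loc[idx, "s_label"] = ""
        for idx in s_picks["misformat"]:
            injected = plates.loc[idx, "s_label"].replace("-", "")
            manifest.add(
                "misformat_s_label", "isolation_s_labeled_plates",
                plates.loc[idx, "fulcrum_id"], "s_label",
                injected, plates.loc[idx, "s_label"],
            )
            plates.loc[idx, "s_label"] = injected

    # --- genotyping sheet -----------------------------------------------------
    clean_s = [
        s for s in plates["s_label"].tolist() if s and s.startswith("S-")
    ] if np_ else []
    # drop duplicates introduced above so the clean sheet starts valid
    seen: set[str] = set()
    clean_s = [s for s in clean_s if not (s in seen or seen.add(s))]
    sheet_rows = []
    for k, s in enumerate(clean_s):
        if rng.random() >= spec.genotype_rate:
            continue
        sheet_rows.append(
            {
                "project_id": spec.prefix,
                "s_label": s,
                "species_id": str(rng.choice(SPECIES_POOL)),
                "possible_new_sp": "1" if rng.random() < 0.05 else "",
                "strain_name": f"NIC{3000 + k}",
            }
        )
    sheet = pd.DataFrame(
        sheet_rows,
        columns=["project_id", "s_label", "species_id", "possible_new_sp", "strain_name"],
    )
    rates = spec.sheet_anomaly_rates
    if len(sheet):
        g_picks = _pick_disjoint(
            rng,
            len(sheet),
            {
                "duplicate": rates.get("duplicate", 0.0),
                "missing_species": rates.get("missing_species", 0.0),
                "misformat": rates.get("misformat", 0.0),
            },
        )
        dup_frames = []
        for idx in g_picks["duplicate"]:
            manifest.add(
                "sheet_duplicate_s_label", "genotyping_sheet",
                sheet.loc[idx, "s_label"], "s_label",
                sheet.loc[idx, "s_label"], None,
            )
            dup_frames.append(sheet.loc[[idx]])
        for idx in g_picks["missing_species"]:
            manifest.add(
                "sheet_missing_species", "genotyping_sheet",
                sheet.loc[idx, "s_label"], "species_id",
                None, sheet.loc[idx, "species_id"],
            )
            sheet.loc[idx, "species_id"] = ""
        for idx in g_picks["misformat"]:
            injected = sheet.loc[idx, "s_label"].replace("-", "")
            manifest.add(
                "sheet_misformat_s_label", "genotyping_sheet",
                sheet.loc[idx, "s_label"], "s_label",
                injected, sheet.loc[idx, "s_label"],
            )
            sheet.loc[idx, "s_label"] = injected
        if dup_frames:
            sheet = pd.concat([sheet] + dup_frames, ignore_index=True)

    # --- geographic features ---------------------------------------------------
    mid_lon = (lon0 + lon1) / 2.0
    geojson = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": "West Sector"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [
                            [lon0, lat0], [mid_lon, lat0], [mid_lon, lat1],
                            [lon0, lat1], [lon0, lat0],
                        ]
                    ],
                },
            },
            {
                "type": "Feature",
                "properties": {"name": "East Sector"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [
                            [mid_lon, lat0], [lon1, lat0], [lon1, lat1],
                            [mid_lon, lat1], [mid_lon, lat0],
                        ]
                    ],
                },
            },
        ],
    }

    # --- write everything -------------------------------------------------------
    raw = layout.raw_fulcrum_dir
    raw.mkdir(parents=True, exist_ok=True)
    layout.raw_photos_dir.mkdir(parents=True, exist_ok=True)
    layout.raw_annotate_dir.mkdir(parents=True, exist_ok=True)
    fs.to_csv(raw / f"{spec.prefix}_field_sampling.csv", index=False)
    photos.to_csv(raw / f"{spec.prefix}_field_sampling_sample_photo.csv", index=False)
    iso_cols = [
        "fulcrum_id", "created_by", "c_label", "date", "time",
        "worms_on_sample", "approximate_number_of_worms", "photos", "s_labeled_plates",
    ]
    (iso if len(iso) else pd.DataFrame(columns=iso_cols)).to_csv(
        raw / f"{spec.prefix}_isolation.csv", index=False
    )
    plate_cols = ["fulcrum_id", "fulcrum_parent_id", "s_label"]
    (plates if len(plates) else pd.DataFrame(columns=plate_cols)).to_csv(
        raw / f"{spec.prefix}_isolation_s_labeled_plates.csv", index=False
    )
    ip_cols = ["fulcrum_id", "fulcrum_parent_id", "captured_at"]
    (iso_photos if len(iso_photos) else pd.DataFrame(columns=ip_cols)).to_csv(
        raw / f"{spec.prefix}_isolation_photos.csv", index=False
    )
    for fname, blob in sorted(photo_files.items()):
        (layout.raw_photos_dir / fname).write_bytes(blob)
    sheet.to_csv(raw.parent.parent.parent / "genotyping_sheet.csv", index=False)
    (layout.raw_annotate_dir / "features.geojson").write_text(
        json.dumps(geojson, indent=1), encoding="utf-8"
    )

    # --- expected flag counts ---------------------------------------------------
    manifest.expected_flag_counts = {
        "flag_ambient_temperature_converted": sum(
            1 for e in manifest.entries
            if e["anomaly"] == "fahrenheit" and e["field"] == "ambient"
        ),
        "flag_substrate_temperature_converted": sum(
            1 for e in manifest.entries
            if e["anomaly"] == "fahrenheit" and e["field"] == "substrate"
        ),
        "flag_substrate_temperature_run": manifest.count("stuck_run"),
        "flag_c_label_duplicated": 2 * manifest.count("duplicate_c_label"),
        "flag_c_label_missing": manifest.count("missing_c_label"),
        "flag_c_label_misformatted": manifest.count("misformat_c_label"),
        "flag_s_label_duplicated": 2 * manifest.count("duplicate_s_label"),
        "flag_s_label_missing": manifest.count("missing_s_label"),
        "flag_s_label_misformatted": manifest.count("misformat_s_label"),
        "missing_photo_collections": len(missing_photo_idx),
    }
    (layout.root / "fixture_manifest.json").write_text(
        manifest.to_json(), encoding="utf-8"
    )
    return manifest
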