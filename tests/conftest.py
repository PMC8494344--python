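import numpy as np
import pandas as pd
import pytest

from fulcrumtools import (
    FixtureSpec,
    ProcessingConfig,
    generate_project,
    join_fulcrum,
    make_directory_structure,
    proc_fulcrum,
    read_fulcrum,
)
from fulcrumtools.project_io import RawBundle


ANOMALY_SPEC_KWARGS = dict(
    n_collections=50,
    seed=11,
    fahrenheit_rate=0.1,
    stuck_run_lengths=(3, 4),
    duplicate_c_label_rate=0.05,
    missing_c_label_rate=0.05,
    misformat_rate=0.05,
    missing_photo_rate=0.1,
    duplicate_s_label_rate=0.05,
    missing_s_label_rate=0.05,
    sheet_anomaly_rates={"duplicate": 0.05, "missing_species": 0.1, "misformat": 0.05},
)


@pytest.fixture
def clean_project(tmp_path):
    """A generated project with every anomaly rate at zero."""
    layout = make_directory_structure(tmp_path / "proj")
    spec = FixtureSpec(n_collections=20, seed=7)
    manifest = generate_project(spec, layout)
    return layout, spec, manifest


@pytest.fixture
def anomaly_project(tmp_path):
    """A generated project seeded with one of every anomaly type."""
    layout = make_directory_structure(tmp_path / "proj")
    spec = FixtureSpec(**ANOMALY_SPEC_KWARGS)
    manifest = generate_project(spec, layout)
    return layout, spec, manifest


@pytest.fixture
def clean_pipeline(clean_project):
    layout, spec, manifest = clean_project
    bundle = read_fulcrum(layout)
    processed = proc_fulcrum(bundle)
    joined = join_fulcrum(processed)
    return layout, manifest, processed, joined


def make_bundle(
    collections,
    photos=None,
    isolations=None,
    plates=None,
    isolation_present=None,
):
    """Build a RawBundle from plain dict-rows, for surgical join tests."""
    fs_defaults = dict(
        created_by="sampler1",
        date="2021-03-01",
        time="08:00:00",
        gridsect="1",
        substrate="leaf litter",
        substrate_temperature="20.0",
        ambient_temperature_c="21.0",
        ambient_humidity="60.0",
        gps_altitude="100.0",
        latitude="22.0",
        longitude="-159.5",
        sample_photo="",
    )
    fs_rows = [{**fs_defaults, **c} for c in collections]
    fs = pd.DataFrame(fs_rows)

    photo_cols = [
        "fulcrum_id", "fulcrum_parent_id", "exif_gps_latitude",
        "exif_gps_longitude", "exif_gps_dop",
    ]
    ph = pd.DataFrame(photos or [], columns=photo_cols).astype(object)

    iso_defaults = dict(date="2021-03-02", time="10:00:00", worms_on_sample="Yes")
    iso_rows = [{**iso_defaults, **i} for i in (isolations or [])]
    iso_cols = ["fulcrum_id", "c_label", "date", "time", "worms_on_sample"]
    iso = pd.DataFrame(iso_rows, columns=iso_cols).astype(object)

    plate_cols = ["fulcrum_id", "fulcrum_parent_id", "s_label"]
    pl = pd.DataFrame(plates or [], columns=plate_cols).astype(object)

    ip = pd.DataFrame([], columns=["fulcrum_id", "fulcrum_parent_id"]).astype(object)
    if isolation_present is None:
        isolation_present = bool(len(iso) or len(pl))
    return RawBundle(
        field_sampling=fs,
        field_sampling_sample_photo=ph,
        isolation=iso,
        isolation_s_labeled_plates=pl,
        isolation_photos=ip,
        prefix="test",
        isolation_present=isolation_present,
    )
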