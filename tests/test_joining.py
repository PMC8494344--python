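import itertools

import numpy as np
import pandas as pd
import pytest

from fulcrumtools import (
    check_join,
    join_fulcrum,
    proc_fulcrum,
    read_fulcrum,
    select_best_photo,
)
from fulcrumtools.errors import IntegrityError
from conftest import make_bundle


def _photo(pid, parent, dop, lat="22.01", lon="-159.51"):
    return {
        "fulcrum_id": pid,
        "fulcrum_parent_id": parent,
        "exif_gps_latitude": lat,
        "exif_gps_longitude": lon,
        "exif_gps_dop": dop,
    }


class TestSelectBestPhoto:
    def test_smallest_dop_wins(self):
        photos = pd.DataFrame([_photo("p1", "r1", "5.0"), _photo("p2", "r1", "3.0")])
        assert select_best_photo(photos)["fulcrum_id"] == "p2"

    def test_singleton_with_missing_dop(self):
        photos = pd.DataFrame([_photo("p1", "r1", None)])
        assert select_best_photo(photos)["fulcrum_id"] == "p1"

    def test_missing_dop_is_worst(self):
        photos = pd.DataFrame([_photo("p1", "r1", None), _photo("p2", "r1", "9.9")])
        assert select_best_photo(photos)["fulcrum_id"] == "p2"

    def test_empty_returns_none(self):
        assert select_best_photo(pd.DataFrame(columns=["fulcrum_id", "exif_gps_dop"])) is None

    def test_tie_break_exhaustive_pairs(self):
        # for every ordering of equal-dop photos the lexicographically
        # smallest id must win
        for ids in itertools.permutations(["b-photo", "a-photo", "c-photo"]):
            photos = pd.DataFrame([_photo(i, "r1", "2.0") for i in ids])
            assert select_best_photo(photos)["fulcrum_id"] == "a-photo"

    def test_winner_dop_is_minimal(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(1, 6))
            dops = [None if rng.random() < 0.3 else str(round(rng.uniform(1, 20), 2)) for _ in range(n)]
            photos = pd.DataFrame([_photo(f"p{i}", "r1", d) for i, d in enumerate(dops)])
            best = select_best_photo(photos)
            best_dop = float(best["exif_gps_dop"]) if best["exif_gps_dop"] else np.inf
            numeric = [np.inf if d is None else float(d) for d in dops]
            assert best_dop == min(numeric) or (best_dop is np.inf and min(numeric) is np.inf)


def _three_collection_bundle():
    """3 collections: one with 2 S-labels, one without isolation, one with 1."""
    return make_bundle(
        collections=[
            {"fulcrum_id": "r1", "c_label": "C-1"},
            {"fulcrum_id": "r2", "c_label": "C-2"},
            {"fulcrum_id": "r3", "c_label": "C-3"},
        ],
        photos=[_photo("p1", "r1", "3.0"), _photo("p2", "r1", "5.0")],
        isolations=[
            {"fulcrum_id": "i1", "c_label": "r1"},
            {"fulcrum_id": "i3", "c_label": "r3"},
        ],
        plates=[
            {"fulcrum_id": "sp1", "fulcrum_parent_id": "i1", "s_label": "S-1"},
            {"fulcrum_id": "sp2", "fulcrum_parent_id": "i1", "s_label": "S-2"},
            {"fulcrum_id": "sp3", "fulcrum_parent_id": "i3", "s_label": "S-3"},
        ],
    )


class TestJoinFulcrum:
    def test_cardinality_sum_of_max(self):
        joined = join_fulcrum(proc_fulcrum(_three_collection_bundle()))
        # sum over collections of max(1, n S-labels) = 2 + 1 + 1
        assert len(joined) == 4

    def test_photo_location_preferred(self):
        joined = join_fulcrum(proc_fulcrum(_three_collection_bundle()))
        r1 = joined[joined["collection_fulcrum_id"] == "r1"].iloc[0]
        assert r1["location_source"] == "photo"
        assert r1["latitude"] == pytest.approx(22.01)
        assert r1["best_photo_id"] == "p1"  # dop 3.0 < 5.0
        r2 = joined[joined["collection_fulcrum_id"] == "r2"].iloc[0]
        assert r2["location_source"] == "record"
        assert r2["latitude"] == pytest.approx(22.0)

    def test_location_source_none_iff_no_gps(self):
        bundle = make_bundle(
            [{"fulcrum_id": "r1", "c_label": "C-1", "latitude": None, "longitude": None}]
        )
        joined = join_fulcrum(proc_fulcrum(bundle))
        assert joined.iloc[0]["location_source"] == "none"
        assert pd.isna(joined.iloc[0]["latitude"])

    def test_duplicate_c_labels_both_flagged(self):
        bundle = make_bundle(
            [
                {"fulcrum_id": "r1", "c_label": "C-0001"},
                {"fulcrum_id": "r2", "c_label": "C-0001"},
                {"fulcrum_id": "r3", "c_label": "C-0002"},
            ]
        )
        joined = join_fulcrum(proc_fulcrum(bundle))
        assert list(joined["flag_c_label_duplicated"]) == [True, True, False]

    def test_worms_on_sample_categories(self):
        bundle = make_bundle(
            [{"fulcrum_id": f"r{i}", "c_label": f"C-{i}"} for i in range(4)],
            isolations=[
                {"fulcrum_id": "i0", "c_label": "r0", "worms_on_sample": "Yes"},
                {"fulcrum_id": "i1", "c_label": "r1", "worms_on_sample": "No"},
                {"fulcrum_id": "i2", "c_label": "r2", "worms_on_sample": "Tracks"},
                {"fulcrum_id": "i3", "c_label": "r3", "worms_on_sample": None},
            ],
        )
        joined = join_fulcrum(proc_fulcrum(bundle)).sort_values("collection_fulcrum_id")
        assert list(joined["worms_on_sample"]) == [
            "present", "absent", "tracks_only", "unknown",
        ]

    def test_orphan_isolation_retained_and_flagged(self):
        bundle = make_bundle(
            [{"fulcrum_id": "r1", "c_label": "C-1"}],
            isolations=[{"fulcrum_id": "i9", "c_label": "unknown-record"}],
        )
        joined = join_fulcrum(proc_fulcrum(bundle))
        assert len(joined) == 2
        orphan = joined[joined["flag_orphan_isolation"]]
        assert len(orphan) == 1
        assert orphan.iloc[0]["isolation_fulcrum_id"] == "i9"

    def test_duplicate_collection_ids_fatal(self):
        bundle = make_bundle(
            [
                {"fulcrum_id": "r1", "c_label": "C-1"},
                {"fulcrum_id": "r1", "c_label": "C-2"},
            ]
        )
        with pytest.raises(IntegrityError):
            join_fulcrum(proc_fulcrum(bundle))

    def test_no_isolation_special_case(self, clean_project):
        layout, spec, _ = clean_project
        for role in ("isolation", "isolation_s_labeled_plates", "isolation_photos"):
            (layout.raw_fulcrum_dir / f"{spec.prefix}_{role}.csv").unlink()
        joined = join_fulcrum(proc_fulcrum(read_fulcrum(layout)))
        assert len(joined) == spec.n_collections
        assert joined["isolation_fulcrum_id"].isna().all()
        assert (joined["worms_on_sample"] == "unknown").all()

    def test_label_conservation_invariants(self, clean_pipeline):
        layout, manifest, processed, joined = clean_pipeline
        fs_labels = set(processed.field_sampling["c_label_proc"].dropna())
        assert set(joined["c_label"].dropna()) == fs_labels
        plate_labels = processed.isolation_s_labeled_plates["s_label_proc"].dropna()
        out_labels = joined["s_label"].dropna()
        assert sorted(out_labels) == sorted(plate_labels)  # each exactly once


class TestCheckJoin:
    def test_clean_fixture_empty_report(self, clean_pipeline):
        *_, joined = clean_pipeline
        assert check_join(joined).empty

    def test_missing_s_label_names_source_file(self):
        bundle = make_bundle(
            [{"fulcrum_id": "r1", "c_label": "C-1"}],
            isolations=[{"fulcrum_id": "i1", "c_label": "r1"}],
            plates=[{"fulcrum_id": "sp1", "fulcrum_parent_id": "i1", "s_label": None}],
        )
        report = check_join(join_fulcrum(proc_fulcrum(bundle)))
        row = report.entries[report.entries["flag"] == "flag_s_label_missing"]
        assert row.iloc[0]["source_file"] == "isolation_s_labeled_plates"

    def test_flag_counts_match_manifest(self, anomaly_project):
        layout, spec, manifest = anomaly_project
        joined = join_fulcrum(proc_fulcrum(read_fulcrum(layout)))
        coll = joined.drop_duplicates("collection_fulcrum_id")
        coll = coll[coll["collection_fulcrum_id"].notna()]
        for flag in (
            "flag_ambient_temperature_converted",
            "flag_substrate_temperature_converted",
            "flag_substrate_temperature_run",
            "flag_c_label_duplicated",
            "flag_c_label_missing",
            "flag_c_label_misformatted",
        ):
            assert int(coll[flag].sum()) == manifest.expected_flag_counts[flag], flag
        for flag in (
            "flag_s_label_duplicated",
            "flag_s_label_missing",
            "flag_s_label_misformatted",
        ):
            assert int(joined[flag].sum()) == manifest.expected_flag_counts[flag], flag
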