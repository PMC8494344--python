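import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fulcrumtools import (
    ProcessingConfig,
    check_temperatures,
    convert_temperature,
    fix_temperatures,
    proc_fulcrum,
    read_fulcrum,
)
from fulcrumtools.errors import LookupError_, ParseError
from conftest import make_bundle
from oracles import brute_force_runs


class TestConvertTemperature:
    @pytest.mark.parametrize(
        "value,threshold,expected,converted",
        [
            (104.0, 40.0, 40.0, True),  # (104-32)*5/9 is exactly 40
            (40.0, 40.0, 40.0, False),  # boundary: strictly greater only
            (-5.0, 40.0, -5.0, False),
            (95.0, 40.0, 35.0, True),
            (75.0, 40.0, (75 - 32) * 5 / 9, True),
        ],
    )
    def test_examples(self, value, threshold, expected, converted):
        got, flag = convert_temperature(value, threshold)
        assert flag is converted
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_passthrough(self):
        got, flag = convert_temperature(np.nan, 40.0)
        assert np.isnan(got) and flag is False

    def test_non_numeric_rejected(self):
        with pytest.raises(ParseError):
            convert_temperature("warm", 40.0)


class TestProcFulcrum:
    def test_fahrenheit_reading_converted_and_flagged(self):
        bundle = make_bundle(
            [{"fulcrum_id": "r1", "c_label": "C-1", "ambient_temperature_c": "75"}]
        )
        p = proc_fulcrum(bundle)
        row = p.field_sampling.iloc[0]
        assert row["ambient_temperature_c_proc"] == pytest.approx(23.888888888, abs=1e-6)
        assert row["flag_ambient_temperature_converted"]
        assert row["ambient_temperature_c"] == "75"  # raw preserved

    def test_label_normalization(self):
        bundle = make_bundle(
            [
                {"fulcrum_id": "r1", "c_label": "c-3205 "},
                {"fulcrum_id": "r2", "c_label": "C3205"},
                {"fulcrum_id": "r3", "c_label": None},
            ]
        )
        fs = proc_fulcrum(bundle).field_sampling
        assert fs.loc[0, "c_label_proc"] == "C-3205"
        assert not fs.loc[0, "flag_c_label_misformatted"]
        assert fs.loc[1, "flag_c_label_misformatted"]
        assert fs.loc[2, "flag_c_label_missing"]

    def test_unparseable_date_flagged_and_retained(self):
        bundle = make_bundle(
            [{"fulcrum_id": "r1", "c_label": "C-1", "date": "not a date"}]
        )
        fs = proc_fulcrum(bundle).field_sampling
        assert fs.loc[0, "flag_datetime_unparseable"]
        assert fs.loc[0, "date"] == "not a date"

    def test_out_of_range_gps_flagged_not_fatal(self):
        bundle = make_bundle(
            [{"fulcrum_id": "r1", "c_label": "C-1", "latitude": "95.0"}]
        )
        fs = proc_fulcrum(bundle).field_sampling
        assert fs.loc[0, "flag_gps_invalid"]
        assert pd.isna(fs.loc[0, "latitude_proc"])

    def test_row_counts_preserved(self, clean_project):
        layout, spec, _ = clean_project
        bundle = read_fulcrum(layout)
        p = proc_fulcrum(bundle)
        for role in (
            "field_sampling", "field_sampling_sample_photo",
            "isolation", "isolation_s_labeled_plates", "isolation_photos",
        ):
            assert len(getattr(p, role)) == len(bundle.table(role))


def _bundle_with_substrate(series):
    rows = []
    for i, v in enumerate(series):
        rows.append(
            {
                "fulcrum_id": f"r{i:02d}",
                "c_label": f"C-{i}",
                "time": f"08:{i:02d}:00",
                "substrate_temperature": str(v),
                "ambient_temperature_c": str(15 + 0.37 * i),
            }
        )
    return make_bundle(rows)


class TestCheckTemperatures:
    def test_run_of_three_flagged(self):
        p = proc_fulcrum(_bundle_with_substrate([20.1, 20.1, 20.1, 22]))
        report = check_temperatures(p)
        subs = report.runs[report.runs["field"] == "substrate"]
        assert len(subs) == 3 and set(subs["run_length"]) == {3}
        assert list(p.field_sampling["flag_substrate_temperature_run"]) == [
            True, True, True, False,
        ]

    def test_alternating_series_no_runs(self):
        p = proc_fulcrum(_bundle_with_substrate([20, 21, 20, 21]))
        assert check_temperatures(p).runs.empty

    def test_injected_fahrenheit_reported(self):
        p = proc_fulcrum(_bundle_with_substrate([20, 95, 21]))
        conv = check_temperatures(p).conversions
        assert len(conv) == 1
        assert conv.iloc[0]["raw_value"] == 95.0
        assert conv.iloc[0]["converted_value"] == pytest.approx(35.0)

    @settings(max_examples=50, deadline=None)
    @given(
        series=st.lists(
            st.sampled_from([18.0, 19.5, 20.1, 22.0]), min_size=1, max_size=15
        ),
        min_len=st.integers(min_value=2, max_value=4),
    )
    def test_matches_brute_force_run_oracle(self, series, min_len):
        p = proc_fulcrum(
            _bundle_with_substrate(series),
            ProcessingConfig(run_length_min=min_len),
        )
        report = check_temperatures(p)
        got = sorted(
            (int(r["fulcrum_id"][1:]), r["run_length"])
            for _, r in report.runs[report.runs["field"] == "substrate"].iterrows()
        )
        expected = sorted(
            (start + k, length)
            for start, length in brute_force_runs(series, min_len)
            for k in range(length)
        )
        assert got == expected


class TestFixTemperatures:
    def test_revert_restores_raw_value(self):
        p = proc_fulcrum(
            make_bundle([{"fulcrum_id": "r1", "c_label": "C-1", "ambient_temperature_c": "75"}])
        )
        fixed = fix_temperatures(p, revert_ids=[("r1", "ambient")])
        row = fixed.field_sampling.iloc[0]
        assert abs(row["ambient_temperature_c_proc"] - 75.0) < 1e-9
        assert not row["flag_ambient_temperature_converted"]
        assert check_temperatures(fixed).conversions.empty
        assert any(a["action"] == "revert" for a in fixed.audit)

    def test_remove_blanks_value_with_audit(self):
        p = proc_fulcrum(_bundle_with_substrate([20.1, 20.1, 20.1, 22]))
        rid = p.field_sampling.loc[1, "fulcrum_id"]
        fixed = fix_temperatures(p, remove_ids=[(rid, "substrate")])
        assert pd.isna(fixed.field_sampling.loc[1, "substrate_temperature_proc"])
        assert any(a["action"] == "remove" for a in fixed.audit)
        # run broken by the removal is no longer reported
        assert check_temperatures(fixed).runs.empty

    def test_empty_repairs_are_identity(self, clean_project):
        layout, _, _ = clean_project
        p = proc_fulcrum(read_fulcrum(layout))
        fixed = fix_temperatures(p, [], [])
        pd.testing.assert_frame_equal(p.field_sampling, fixed.field_sampling)
        assert fixed.audit == []

    def test_revert_non_converted_is_audited_noop(self):
        p = proc_fulcrum(
            make_bundle([{"fulcrum_id": "r1", "c_label": "C-1", "ambient_temperature_c": "20"}])
        )
        fixed = fix_temperatures(p, revert_ids=[("r1", "ambient")])
        assert fixed.field_sampling.loc[0, "ambient_temperature_c_proc"] == 20.0
        assert "no-op" in fixed.audit[0]["note"]

    def test_unknown_record_rejected(self):
        p = proc_fulcrum(make_bundle([{"fulcrum_id": "r1", "c_label": "C-1"}]))
        with pytest.raises(LookupError_):
            fix_temperatures(p, revert_ids=[("nope", "ambient")])
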