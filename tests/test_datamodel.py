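"""Domain types, readers/writers and table transforms."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soiltrace import (
    AbundanceTable,
    Environment,
    FeatureKind,
    SampleRecord,
    SampleType,
    ValueKind,
    display_filter,
    read_abundance_table,
    read_metadata,
    to_relative,
    write_abundance_table,
    write_metadata,
)
from soiltrace.datamodel import DistanceMatrix, validate_records

from conftest import make_counts, make_relative


class TestReadAbundanceTable:
    def test_count_identity_readback(self):
        tsv = "sample_id\tfA\tfB\ns1\t3\t1\ns2\t0\t2\n"
        t = read_abundance_table(io.StringIO(tsv), "taxon", "count")
        assert t.values.sum(axis=1).tolist() == [4.0, 2.0]
        assert t.sample_ids == ["s1", "s2"]
        assert t.feature_ids == ["fA", "fB"]

    def test_relative_within_tolerance_renormalized(self):
        tsv = "sample_id\tfA\tfB\ns1\t0.5\t0.5000001\n"
        t = read_abundance_table(io.StringIO(tsv), "taxon", "relative")
        assert t.values.sum(axis=1) == pytest.approx([1.0], abs=1e-12)

    def test_relative_outside_tolerance_rejected(self):
        tsv = "sample_id\tfA\tfB\ns1\t0.5\t0.51\n"
        with pytest.raises(ValueError, match="s1"):
            read_abundance_table(io.StringIO(tsv), "taxon", "relative")

    def test_negative_value_names_cell(self):
        tsv = "sample_id\tfA\tfB\ns1\t1\t-1\n"
        with pytest.raises(ValueError, match="s1.*fB"):
            read_abundance_table(io.StringIO(tsv), "taxon", "count")

    def test_duplicate_ids_rejected(self):
        tsv = "sample_id\tfA\tfA\ns1\t1\t1\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_abundance_table(io.StringIO(tsv), "taxon", "count")

    def test_roundtrip_value_identical(self, tmp_path):
        t = make_counts([[3, 1], [0, 2]])
        path = tmp_path / "t.tsv"
        write_abundance_table(t, path)
        back = read_abundance_table(path, t.feature_kind, t.value_kind)
        pd.testing.assert_frame_equal(t.data, back.data)


class TestToRelative:
    @pytest.mark.parametrize(
        "row, expected",
        [([3, 1], [0.75, 0.25]), ([5], [1.0])],
    )
    def test_closure(self, row, expected):
        t = to_relative(make_counts([row]))
        assert t.values[0] == pytest.approx(expected)
        assert t.value_kind is ValueKind.RELATIVE

    def test_all_zero_row_errors_with_sample_id(self):
        with pytest.raises(ValueError, match="s1"):
            to_relative(make_counts([[1, 1], [0, 0]]))

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_on_relative(self, row):
        t = to_relative(make_counts([row]))
        again = to_relative(t)
        assert np.allclose(t.values, again.values)


class TestDisplayFilter:
    def test_at_threshold_is_collapsed(self):
        t = make_relative([[0.9985, 0.0005, 0.001]])
        out = display_filter(t, threshold=0.001)
        assert out.data.loc["s0", "others"] == pytest.approx(0.0015)
        assert out.data.loc["s0", "f0"] == pytest.approx(0.9985)
        assert "f1" not in out.data.columns  # zero everywhere after collapse

    def test_all_above_threshold_unchanged_plus_empty_others(self):
        t = make_relative([[0.6, 0.4]])
        out = display_filter(t, threshold=0.001)
        assert out.data.loc["s0", "others"] == 0.0
        assert out.data.loc["s0", "f0"] == 0.6

    def test_threshold_zero_collapses_only_exact_zeros(self):
        t = make_relative([[0.5, 0.5, 0.0]])
        out = display_filter(t, threshold=0.0)
        assert out.data.loc["s0", "others"] == 0.0
        assert list(out.data.columns) == ["f0", "f1", "others"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            display_filter(make_relative([[1.0]]), threshold=1.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_row_sums_preserved(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.dirichlet(np.full(12, 0.5), size=3)
        out = display_filter(make_relative(rows), threshold=0.05)
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-12)


class TestSampleRecords:
    def test_soil_birthplace_must_match_env(self):
        with pytest.raises(ValueError):
            SampleRecord("s", "m", SampleType.SOIL, Environment.DESERT, Environment.FOREST, 0)

    def test_day60_gut_still_in_birthplace(self):
        with pytest.raises(ValueError):
            SampleRecord("s", "m", SampleType.GUT, Environment.DESERT, Environment.FOREST, 60)

    def test_duplicate_mouse_timepoint_rejected(self):
        r1 = SampleRecord("a", "m1", SampleType.GUT, Environment.DESERT, Environment.DESERT, 60)
        r2 = SampleRecord("b", "m1", SampleType.GUT, Environment.DESERT, Environment.DESERT, 60)
        with pytest.raises(ValueError, match="m1"):
            validate_records([r1, r2])

    def test_metadata_roundtrip(self, tmp_path):
        records = [
            SampleRecord("soil_d", "soil_d", SampleType.SOIL, Environment.DESERT, Environment.DESERT, 0),
            SampleRecord("m1_60", "m1", SampleType.GUT, Environment.DESERT, Environment.DESERT, 60),
            SampleRecord("m1_90", "m1", SampleType.GUT, Environment.DESERT, Environment.STEPPE, 90),
        ]
        path = tmp_path / "meta.tsv"
        write_metadata(records, path)
        assert read_metadata(path) == records


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))
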