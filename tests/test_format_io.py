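"""Container invariants, the concatenated-vector indexing convention,
summary semantics, HDF5 round trips and the validator."""

import dataclasses
import math

import h5py
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mearec import (
    Metadata,
    Recording,
    SchemaError,
    compute_summary,
    get_unit_spikes,
    read_recording,
    unit_slice,
    validate_recording,
    with_summary,
    write_recording,
)
from .conftest import random_recording


class TestUnitSlice:
    @pytest.mark.parametrize(
        "scount, j, expected",
        [
            ([2, 3, 1], 1, (1, 2)),
            ([2, 3, 1], 2, (3, 5)),
            ([2, 3, 1], 3, (6, 6)),
            ([0, 4], 1, (1, 0)),  # empty train: b < a
        ],
    )
    def test_one_based_inclusive_ranges(self, scount, j, expected):
        assert unit_slice(scount, j) == expected

    @pytest.mark.parametrize("j", [0, 4, -1])
    def test_out_of_range(self, j):
        with pytest.raises(IndexError):
            unit_slice([2, 3, 1], j)

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=30),
        st.data(),
    )
    @settings(deadline=None)
    def test_matches_cumulative_sum_oracle(self, scount, data):
        j = data.draw(st.integers(min_value=1, max_value=len(scount)))
        a, b = unit_slice(scount, j)
        assert a == 1 + sum(scount[: j - 1])
        assert b == a + scount[j - 1] - 1

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_slices_partition_the_spike_vector(self, scount):
        ranges = [unit_slice(scount, j) for j in range(1, len(scount) + 1)]
        covered = sum(max(0, b - a + 1) for a, b in ranges)
        assert covered == sum(scount)


class TestGetUnitSpikes:
    def test_middle_unit(self, small_rec):
        np.testing.assert_array_equal(
            get_unit_spikes(small_rec, 2), [0.2, 0.4, 0.8]
        )

    def test_last_unit(self, small_rec):
        np.testing.assert_array_equal(get_unit_spikes(small_rec, 3), [0.5])

    def test_empty_train(self):
        rec = with_summary(
            Recording(
                epos=np.zeros((2, 2)),
                spikes=np.array([1.0]),
                scount=np.array([0, 1]),
                array="MCS_8x8_100um",
                meta=Metadata(key="k", species="mouse", age=1),
            )
        )
        assert len(get_unit_spikes(rec, 1)) == 0

    def test_lengths_match_scount(self, rng):
        rec = random_recording(rng)
        for j in range(1, rec.n_units + 1):
            seg = get_unit_spikes(rec, j)
            assert len(seg) == rec.scount[j - 1]
            assert np.all(np.diff(seg) >= 0)


class TestComputeSummary:
    def test_duration_is_ceiling_of_max_spike(self):
        rec = Recording(
            epos=np.zeros((1, 2)),
            spikes=np.array([1.0, 9.2]),
            scount=np.array([2]),
            array="MCS_8x8_100um",
            meta=Metadata(key="k", species="mouse", age=1),
        )
        s = compute_summary(rec)
        assert s.duration == 10
        np.testing.assert_allclose(s.frate, [0.2])
        assert s.totalspikes == 2

    def test_whole_second_max_spike_not_bumped(self):
        rec = Recording(
            epos=np.zeros((1, 2)),
            spikes=np.array([10.0]),
            scount=np.array([1]),
            array="MCS_8x8_100um",
            meta=Metadata(key="k", species="mouse", age=1),
        )
        assert compute_summary(rec).duration == 10

    def test_empty_train_rate_zero(self):
        rec = Recording(
            epos=np.zeros((2, 2)),
            spikes=np.sort(np.linspace(0.5, 9.5, 5)),
            scount=np.array([5, 0]),
            array="MCS_8x8_100um",
            meta=Metadata(key="k", species="mouse", age=1),
        )
        np.testing.assert_allclose(compute_summary(rec).frate, [0.5, 0.0])

    def test_zero_spikes_needs_override(self):
        rec = Recording(
            epos=np.zeros((1, 2)),
            spikes=np.empty(0),
            scount=np.array([0]),
            array="MCS_8x8_100um",
            meta=Metadata(key="k", species="mouse", age=1),
        )
        with pytest.raises(SchemaError):
            compute_summary(rec)
        assert compute_summary(rec, duration=60).duration == 60

    def test_frate_times_duration_recovers_counts(self, rng):
        rec = random_recording(rng)
        s = rec.summary
        np.testing.assert_allclose(s.frate * s.duration, rec.scount)


class TestRoundTrip:
    def test_write_read_identity(self, rng, tmp_path):
        for i in range(5):
            rec = random_recording(rng, with_names=bool(i % 2))
            p = tmp_path / f"r{i}.h5"
            write_recording(rec, p)
            assert read_recording(p) == rec

    def test_spike_times_bit_exact(self, rng, tmp_path):
        rec = random_recording(rng)
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        back = read_recording(p)
        assert back.spikes.tobytes() == rec.spikes.tobytes()

    def test_absent_names_stay_absent(self, rng, tmp_path):
        rec = random_recording(rng, with_names=False)
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        with h5py.File(p) as f:
            assert "names" not in f
        assert read_recording(p).names is None

    def test_refuses_invalid_recording(self, small_rec, tmp_path):
        bad = dataclasses.replace(
            small_rec, spikes=small_rec.spikes[::-1].copy()
        )
        with pytest.raises(SchemaError, match="TRAIN_UNSORTED"):
            write_recording(bad, tmp_path / "bad.h5")

    def test_transposed_epos_normalised_on_read(self, rng, tmp_path):
        rec = random_recording(rng, n_units=5)
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        with h5py.File(p, "r+") as f:
            epos = f["epos"][()]
            del f["epos"]
            f.create_dataset("epos", data=epos.T)  # column-major writer
        back = read_recording(p)
        np.testing.assert_array_equal(back.epos, rec.epos)

    def test_missing_dataset_named_in_error(self, rng, tmp_path):
        rec = random_recording(rng)
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        with h5py.File(p, "r+") as f:
            del f["spikes"]
        with pytest.raises(SchemaError, match="spikes"):
            read_recording(p)

    def test_absent_meta_defaults_applied(self, rng, tmp_path):
        rec = random_recording(rng)
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        with h5py.File(p, "r+") as f:
            del f["meta/genotype"], f["meta/cond"]
        back = read_recording(p)
        assert back.meta.genotype == "wt"
        assert back.meta.cond == "ctl"

    def test_absent_summary_recomputed(self, rng, tmp_path):
        rec = random_recording(rng)
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        with h5py.File(p, "r+") as f:
            del f["summary"]
        assert read_recording(p).summary == rec.summary


class TestValidator:
    def test_valid_recording_has_no_violations(self, rng):
        assert validate_recording(random_recording(rng)) == []

    def test_written_file_validates_clean(self, rng, tmp_path):
        p = tmp_path / "r.h5"
        write_recording(random_recording(rng), p)
        assert validate_recording(p) == []

    def test_spikes_length_mismatch(self, small_rec):
        bad = dataclasses.replace(small_rec, spikes=small_rec.spikes[:-1].copy())
        codes = {v.code for v in validate_recording(bad)}
        assert "SPIKES_LEN_MISMATCH" in codes

    def test_unsorted_train(self, small_rec):
        spikes = small_rec.spikes.copy()
        spikes[2], spikes[3] = spikes[3], spikes[2]
        bad = dataclasses.replace(small_rec, spikes=spikes)
        codes = {v.code for v in validate_recording(bad)}
        assert "TRAIN_UNSORTED" in codes

    def test_stale_summary_duration(self, small_rec):
        stale = dataclasses.replace(
            small_rec,
            summary=dataclasses.replace(small_rec.summary, duration=9),
        )
        # max spike 0.9 -> true duration 1; ceil mismatch must be flagged
        codes = {v.code for v in validate_recording(stale)}
        assert "SUMMARY_DURATION_WRONG" in codes

    def test_missing_key(self, small_rec):
        bad = dataclasses.replace(
            small_rec, meta=dataclasses.replace(small_rec.meta, key="")
        )
        codes = {v.code for v in validate_recording(bad)}
        assert "META_MISSING_KEY" in codes

    def test_unseen_array_label_warns_but_passes(self, small_rec, caplog):
        odd = dataclasses.replace(small_rec, array="custom_lab_array")
        with caplog.at_level("WARNING", logger="mearec"):
            assert validate_recording(odd) == []
        assert any("custom_lab_array" in r.message for r in caplog.records)

    def test_unreadable_path_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            validate_recording(tmp_path / "missing.h5")


def test_age_sentinel_and_negative_ages_pass_through(rng, tmp_path):
    """Adult (500) and embryonic (negative) ages survive a round trip."""
    for age in (500, -3, 0):
        rec = random_recording(rng)
        rec = dataclasses.replace(
            rec, meta=dataclasses.replace(rec.meta, age=age)
        )
        p = tmp_path / f"age{age}.h5"
        write_recording(rec, p)
        assert read_recording(p).meta.age == age
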