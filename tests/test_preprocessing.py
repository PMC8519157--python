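import math

import numpy as np
import pytest

from actirar.preprocessing import (
    DailyProfileMatrix,
    bin_profiles,
    filter_valid_days,
    log_transform,
    subject_rar,
)

from conftest import make_series


class TestLogTransform:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, 0.0), (math.e - 1, 1.0), (9, math.log(10)), (99, math.log(100))],
    )
    def test_known_values(self, count, expected):
        s = log_transform(make_series([count] * 4))
        assert s.values == pytest.approx([expected] * 4)
        assert s.is_log

    def test_negative_count_names_epoch(self):
        s = make_series([3, 1, -2, 5])
        with pytest.raises(ValueError, match="epoch 2"):
            log_transform(s)

    def test_order_and_timestamps_unchanged(self):
        s = make_series([0, 9, 99])
        out = log_transform(s)
        assert np.array_equal(out.timestamps, s.timestamps)


class TestBinProfiles:
    def test_one_day_of_30s_epochs_gives_48_bins(self):
        s = log_transform(make_series(np.arange(2880)))
        m = bin_profiles(s, bin_minutes=30)
        assert m.values.shape == (1, 48)

    def test_constant_value_fills_every_cell(self):
        s = log_transform(make_series(np.full(2880, math.e - 1)))
        m = bin_profiles(s, bin_minutes=30)
        assert m.values == pytest.approx(np.ones((1, 48)))

    def test_60min_bins_are_means_of_adjacent_30min_bins(self, rng):
        s = log_transform(make_series(rng.integers(0, 500, size=2 * 2880)))
        m30 = bin_profiles(s, bin_minutes=30)
        m60 = bin_profiles(s, bin_minutes=60)
        assert m60.values.shape == (2, 24)
        nested = 0.5 * (m30.values[:, ::2] + m30.values[:, 1::2])
        np.testing.assert_allclose(m60.values, nested, rtol=0, atol=1e-12)

    def test_off_wrist_epochs_excluded_and_empty_cell_missing(self):
        counts = np.full(2880, math.e - 1)
        off = np.zeros(2880, dtype=bool)
        off[:60] = True  # whole first 30-min bin off-wrist
        counts[:60] = 1e6  # would wreck the mean if included
        s = log_transform(make_series(counts, off_wrist=off))
        m = bin_profiles(s, bin_minutes=30)
        assert np.isnan(m.values[0, 0])
        assert m.values[0, 1:] == pytest.approx(np.ones(47))

    def test_irregular_spacing_rejected(self):
        s = log_transform(make_series(np.zeros(10)))
        s.timestamps = s.timestamps.copy()
        s.timestamps[5:] += np.timedelta64(7, "s")
        with pytest.raises(ValueError, match="irregular"):
            bin_profiles(s)

    def test_partial_days_align_to_midnight(self):
        # start at 12:00, run 24 h: spans two calendar days with missing halves
        s = log_transform(
            make_series(np.zeros(2880), start="2020-01-06T12:00:00")
        )
        m = bin_profiles(s, bin_minutes=30)
        assert m.values.shape == (2, 48)
        assert np.isnan(m.values[0, :24]).all() and np.isfinite(m.values[0, 24:]).all()


class TestValidDays:
    def _matrix(self, values):
        return DailyProfileMatrix(
            subject_id="s", bin_minutes=30, values=values,
            dates=np.datetime64("2020-01-06", "D") + np.arange(len(values)),
        )

    def test_two_days_is_excluded_from_rar(self):
        m = filter_valid_days(self._matrix(np.zeros((2, 48))), min_valid_days=3)
        assert m.excluded_from_rar and m.n_valid_days == 2

    def test_six_full_days_all_valid(self):
        m = filter_valid_days(self._matrix(np.zeros((6, 48))))
        assert not m.excluded_from_rar and m.day_valid.all()

    def test_day_with_60pct_missing_is_invalid(self):
        values = np.zeros((4, 48))
        values[1, : int(0.6 * 48)] = np.nan
        m = filter_valid_days(self._matrix(values), max_missing_fraction=0.5)
        assert list(m.day_valid) == [True, False, True, True]


class TestSubjectRAR:
    def _matrix(self, values, valid=None):
        m = DailyProfileMatrix(
            subject_id="s", bin_minutes=30, values=values,
            dates=np.datetime64("2020-01-06", "D") + np.arange(len(values)),
        )
        if valid is not None:
            m.day_valid = np.asarray(valid)
        return m

    def test_identical_days_zero_sd(self, rng):
        day = rng.normal(size=48)
        r = subject_rar(self._matrix(np.tile(day, (4, 1))))
        assert r.mean_profile == pytest.approx(day)
        assert r.sd_profile == pytest.approx(np.zeros(48), abs=1e-12)

    def test_two_day_closed_form(self):
        a, b = 1.0, 4.0
        values = np.vstack([np.full(48, a), np.full(48, b)])
        r = subject_rar(self._matrix(values))
        assert r.mean_profile == pytest.approx(np.full(48, (a + b) / 2))
        assert r.sd_profile == pytest.approx(np.full(48, abs(a - b) / math.sqrt(2)))

    def test_matches_bruteforce_columnwise(self, rng):
        values = rng.normal(size=(5, 48))
        r = subject_rar(self._matrix(values))
        for t in range(48):
            col = [values[d, t] for d in range(5)]
            mean = sum(col) / 5
            sd = math.sqrt(sum((v - mean) ** 2 for v in col) / 4)
            assert r.mean_profile[t] == pytest.approx(mean)
            assert r.sd_profile[t] == pytest.approx(sd)

    def test_day_order_irrelevant(self, rng):
        values = rng.normal(size=(6, 48))
        r1 = subject_rar(self._matrix(values))
        r2 = subject_rar(self._matrix(values[rng.permutation(6)]))
        np.testing.assert_allclose(r1.mean_profile, r2.mean_profile)
        np.testing.assert_allclose(r1.sd_profile, r2.sd_profile)

    def test_binning_conserves_mass(self, rng):
        # mean over bins of the mean profile equals the mean of all valid cells
        values = rng.normal(size=(5, 48))
        r = subject_rar(self._matrix(values))
        assert r.mean_profile.mean() == pytest.approx(values.mean())

    def test_single_contributing_day_sd_missing_with_warning(self):
        values = np.zeros((3, 48))
        values[1:, 0] = np.nan  # bin 0 observed on one day only
        with pytest.warns(UserWarning, match="SD undefined"):
            r = subject_rar(self._matrix(values))
        assert np.isnan(r.sd_profile[0]) and np.isfinite(r.sd_profile[1:]).all()
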