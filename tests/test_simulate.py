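import dataclasses
import math

import numpy as np
import pytest

from actirar.io import read_cohort, write_cohort
from actirar.preprocessing import bin_profiles, log_transform
from actirar.simulate import (
    Bump,
    SimConfig,
    generate_cohort,
    group_effect,
    latent_mean,
)


def noiseless_config(**kwargs):
    base = dict(
        n_group_pos=2, n_group_neg=2, day_range=(3, 3), day_weights=(1.0,),
        subject_intercept_sd=0.0, day_phase_jitter_sd=0.0, noise_sd=0.0,
        rng_seed=1,
    )
    base.update(kwargs)
    return SimConfig(**base)


def binned_log_profile(series):
    m = bin_profiles(log_transform(series), bin_minutes=30)
    return m.values


class TestDeterministicLatentProcess:
    def test_constant_process_constant_counts(self):
        cfg = noiseless_config(baseline_amplitude=0.0, harmonics=(),
                               mean_effect_bumps=())
        cohort = generate_cohort(cfg)
        expected = max(0, round(math.exp(cfg.baseline_mesor) - 1))
        for s in cohort.subjects:
            assert (s.values == expected).all()

    def test_noiseless_profiles_match_discretised_ground_truth(self):
        cfg = noiseless_config()
        cohort = generate_cohort(cfg)
        t_epoch = (np.arange(2880) + 0.5) * 30 / 3600.0
        for s, ab in zip(cohort.subjects, cohort.covariates["abeta"]):
            latent = latent_mean(cfg, t_epoch)
            if ab == "pos":
                latent = latent + group_effect(cfg, t_epoch)
            counts = np.maximum(0.0, np.rint(np.exp(latent) - 1.0))
            oracle = np.log1p(counts).reshape(48, 60).mean(axis=1)
            np.testing.assert_allclose(binned_log_profile(s), oracle[None, :].repeat(3, 0),
                                       rtol=0, atol=1e-12)

    def test_noiseless_profiles_near_latent_mean(self):
        # count discretisation is the only deviation from mu(t) (+delta)
        cfg = noiseless_config()
        cohort = generate_cohort(cfg)
        mu = cohort.mu_neg
        prof = binned_log_profile(cohort.subjects[-1])[0]  # a negative subject
        # integer rounding is coarsest near the trough where counts ~ 1-2
        assert np.max(np.abs(prof - mu)) < 0.2
        assert np.mean(np.abs(prof - mu)) < 0.05

    def test_bump_height_monotone_in_group_difference(self):
        diffs = []
        for h in (0.2, 0.5, 0.9):
            cfg = noiseless_config(
                mean_effect_bumps=(Bump(center_hours=15.0, width_hours=1.5,
                                        height_log_units=h, sign=+1),),
            )
            cohort = generate_cohort(cfg)
            pos = binned_log_profile(cohort.subjects[0])[0]
            neg = binned_log_profile(cohort.subjects[-1])[0]
            diffs.append((pos - neg)[30])  # bin centred at 15:15
        assert diffs[0] < diffs[1] < diffs[2]


class TestStochasticGroundTruth:
    def test_group_mean_profiles_within_3_mc_se(self):
        cfg = SimConfig(n_group_pos=30, n_group_neg=30, day_range=(6, 6),
                        day_weights=(1.0,), rng_seed=42)
        cohort = generate_cohort(cfg)
        profiles = np.array([binned_log_profile(s).mean(axis=0)
                             for s in cohort.subjects])
        is_pos = (cohort.covariates["abeta"] == "pos").to_numpy()
        for mask, truth in ((~is_pos, cohort.mu_neg),
                            (is_pos, cohort.mu_neg + cohort.delta)):
            grp = profiles[mask]
            se = grp.std(axis=0, ddof=1) / math.sqrt(mask.sum())
            assert np.all(np.abs(grp.mean(axis=0) - truth) <= 3.0 * se)

    def test_null_config_groups_agree(self):
        cfg = SimConfig(n_group_pos=20, n_group_neg=20, day_range=(6, 6),
                        day_weights=(1.0,), mean_effect_bumps=(),
                        sd_effect_windows=(), rng_seed=3)
        cohort = generate_cohort(cfg)
        profiles = np.array([binned_log_profile(s).mean(axis=0)
                             for s in cohort.subjects])
        is_pos = (cohort.covariates["abeta"] == "pos").to_numpy()
        diff = profiles[is_pos].mean(0) - profiles[~is_pos].mean(0)
        pooled_se = math.sqrt(
            profiles[is_pos].var(0, ddof=1).mean() / 20
            + profiles[~is_pos].var(0, ddof=1).mean() / 20
        )
        assert np.abs(diff).max() < 4.0 * pooled_se

    def test_sd_windows_raise_positive_group_variability(self):
        cfg = SimConfig(n_group_pos=25, n_group_neg=25, day_range=(6, 6),
                        day_weights=(1.0,), mean_effect_bumps=(),
                        day_phase_jitter_sd=0.0, subject_intercept_sd=0.0,
                        rng_seed=5)
        cohort = generate_cohort(cfg)
        is_pos = (cohort.covariates["abeta"] == "pos").to_numpy()
        sds = []
        for s in cohort.subjects:
            m = bin_profiles(log_transform(s))
            sds.append(m.values.std(axis=0, ddof=1))
        sds = np.array(sds)
        bin_in_window = 10  # 05:00-05:30, inside the 04:30-08:30 multiplier window
        bin_outside = 26  # 13:00-13:30
        assert sds[is_pos, bin_in_window].mean() > 1.2 * sds[~is_pos, bin_in_window].mean()
        ratio_out = sds[is_pos, bin_outside].mean() / sds[~is_pos, bin_outside].mean()
        assert 0.8 < ratio_out < 1.25


class TestReproducibilityAndValidation:
    def test_same_seed_identical_cohort(self):
        c1 = generate_cohort(SimConfig(n_group_pos=3, n_group_neg=3, rng_seed=9))
        c2 = generate_cohort(SimConfig(n_group_pos=3, n_group_neg=3, rng_seed=9))
        assert c1.covariates.equals(c2.covariates)
        for a, b in zip(c1.subjects, c2.subjects):
            assert np.array_equal(a.values, b.values)

    def test_different_seed_differs(self):
        c1 = generate_cohort(SimConfig(n_group_pos=3, n_group_neg=3, rng_seed=9))
        c2 = generate_cohort(SimConfig(n_group_pos=3, n_group_neg=3, rng_seed=10))
        assert not np.array_equal(c1.subjects[0].values, c2.subjects[0].values)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(baseline_mesor=25.0),  # exp overflow guard
            dict(day_range=(1, 6), day_weights=(0.2,) * 6),
            dict(epoch_seconds=7),
            dict(noise_sd=-0.1),
            dict(mean_effect_bumps=(Bump(center_hours=25.0),)),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        cfg = dataclasses.replace(SimConfig(), **bad)
        with pytest.raises(ValueError):
            cfg.validate()


class TestRoundTrip:
    def test_one_subject_one_day_row_count(self, tmp_path):
        cfg = noiseless_config(n_group_pos=1, n_group_neg=1, day_range=(2, 2),
                               day_weights=(1.0,))
        cohort = generate_cohort(cfg)
        write_cohort(cohort, tmp_path / "c")
        lines = (tmp_path / "c" / "epochs.csv").read_text().splitlines()
        assert len(lines) == 1 + 2 * 2 * 2880  # header + 2 subjects x 2 days

    def test_write_then_read_bitwise_identical(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert back.covariates.equals(small_cohort.covariates)
        assert len(back.subjects) == len(small_cohort.subjects)
        for a, b in zip(small_cohort.subjects, back.subjects):
            assert a.subject_id == b.subject_id
            assert np.array_equal(a.values, b.values)
            assert np.array_equal(a.timestamps, b.timestamps)
        np.testing.assert_allclose(back.delta, small_cohort.delta, atol=1e-10)

    def test_refuses_overwrite_without_flag(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path / "c")
        with pytest.raises(FileExistsError):
            write_cohort(small_cohort, tmp_path / "c")
        write_cohort(small_cohort, tmp_path / "c", overwrite=True)
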