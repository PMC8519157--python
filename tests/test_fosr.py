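import warnings

import numpy as np
import pytest
from scipy import linalg
from scipy.stats import norm

from actirar.fosr import (
    Band,
    FunctionalDesign,
    build_basis,
    build_design,
    fit_fosr,
    global_f_test,
    pointwise_band,
    significant_windows,
    simultaneous_band,
)
from actirar.preprocessing import subject_rar
from actirar.pipeline import preprocess_subject
from actirar.simulate import Bump, SimConfig, generate_cohort

GRID48 = (np.arange(48) + 0.5) * 0.5


def random_design(rng, n=30, T=16, q=5, n_basis=8, signal=None):
    grid = (np.arange(T) + 0.5) * (24.0 / T)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))])
    Y = rng.standard_normal((n, T))
    if signal is not None:
        Y = Y + X @ signal(grid)
    names = ("intercept",) + tuple(f"x{j}" for j in range(1, q))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return FunctionalDesign(Y=Y, X=X, grid=grid, n_basis=n_basis,
                                col_names=names)


class TestBasis:
    @pytest.mark.parametrize("periodic", [False, True])
    @pytest.mark.parametrize("n_basis", [4, 8, 12])
    def test_partition_of_unity(self, periodic, n_basis):
        B, P = build_basis(GRID48, n_basis, periodic=periodic)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert P.shape == (n_basis, n_basis)

    def test_saturated_basis_spans_all_grid_functions(self):
        B, _ = build_basis(GRID48, 48)
        assert np.linalg.matrix_rank(B) == 48

    def test_too_few_basis_functions_rejected(self):
        with pytest.raises(ValueError, match="n_basis >= 4"):
            build_basis(GRID48, 3)

    def test_periodic_basis_wraps_at_midnight(self, rng):
        B, _ = build_basis(np.array([0.0, 24.0 - 1e-9]), 8, periodic=True)
        theta = rng.standard_normal(8)
        assert B[0] @ theta == pytest.approx(B[1] @ theta, abs=1e-6)

    def test_fourier_family(self):
        B, P = build_basis(GRID48, 9, family="fourier")
        assert B.shape == (48, 9)
        assert np.diag(P)[0] == 0.0  # intercept unpenalised


class TestFitOracles:
    def test_saturated_zero_penalty_identity_equals_per_bin_ols(self, rng):
        des = random_design(rng, n=25, T=12, q=5, n_basis=12)
        fit = fit_fosr(des, lambdas=0.0, cov_structure="identity")
        beta_ols = np.linalg.solve(des.X.T @ des.X, des.X.T @ des.Y)
        assert np.abs(fit.coef - beta_ols).max() < 1e-8

    def test_noiseless_spline_representable_truth_recovered(self, rng):
        T, q, K = 24, 3, 8
        grid = (np.arange(T) + 0.5) * (24.0 / T)
        B, _ = build_basis(grid, K)
        theta_true = rng.standard_normal((q, K))
        X = np.column_stack([np.ones(40), rng.standard_normal((40, q - 1))])
        Y = X @ theta_true @ B.T  # zero noise
        des = FunctionalDesign(Y=Y, X=X, grid=grid, n_basis=K,
                               col_names=("intercept", "a", "b"))
        fit = fit_fosr(des, lambdas=0.0, cov_structure="identity")
        assert np.abs(fit.coef - theta_true @ B.T).max() < 1e-6

    def test_collinear_design_rejected(self, rng):
        des = random_design(rng, n=30, T=16, q=4)
        X = des.X.copy()
        X[:, 3] = X[:, 2]  # duplicated covariate column
        bad = FunctionalDesign(Y=des.Y, X=X, grid=des.grid, n_basis=8,
                               col_names=("intercept", "a", "b", "b_dup"))
        with pytest.raises(linalg.LinAlgError, match="collinear"):
            fit_fosr(bad)

    def test_known_bump_argmax_within_one_hour(self):
        cfg = SimConfig(
            n_group_pos=30, n_group_neg=30, day_range=(6, 6), day_weights=(1.0,),
            mean_effect_bumps=(Bump(center_hours=15.0, width_hours=2.0,
                                    height_log_units=0.5, sign=+1),),
            rng_seed=101,
        )
        cohort = generate_cohort(cfg)
        mats = [preprocess_subject(s) for s in cohort.subjects]
        rars = [subject_rar(m) for m in mats]
        des = build_design(rars, cohort.covariates, outcome="mean")
        fit = fit_fosr(des)
        t_max = des.grid[np.argmax(fit.coef[4])]
        assert abs(t_max - 15.0) <= 1.0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    des = random_design(rng, n=40, T=20, q=5)
    return des, fit_fosr(des)


class TestBands:
    def test_alpha_one_gives_zero_width(self, fitted):
        _, fit = fitted
        band = pointwise_band(fit, 4, alpha=1.0 - 1e-12)
        np.testing.assert_allclose(band.lo, band.hi, atol=1e-8)

    def test_exclusion_matches_z_statistic(self, fitted):
        _, fit = fitted
        band = pointwise_band(fit, 2, alpha=0.05)
        z = norm.ppf(0.975)
        excl = (band.lo > 0) | (band.hi < 0)
        np.testing.assert_array_equal(
            excl, np.abs(fit.coef[2]) / fit.se[2] > z
        )

    def test_simultaneous_contains_pointwise(self, fitted):
        _, fit = fitted
        pw = pointwise_band(fit, 4, alpha=0.05)
        sb = simultaneous_band(fit, 4, alpha=0.05, n_sim=2000, seed=0)
        assert sb.critical >= pw.critical
        assert (sb.lo <= pw.lo + 1e-12).all() and (sb.hi >= pw.hi - 1e-12).all()

    def test_rank_one_covariance_collapses_to_pointwise(self, fitted):
        # perfectly correlated coefficient uncertainty: the max statistic is a
        # single normal, so q* equals z up to Monte-Carlo error
        _, fit = fitted
        K = fit.B.shape[1]
        v = np.ones(K)
        block = np.outer(v, v) * 0.01
        fit2 = fit.__class__(**{**fit.__dict__})
        cov = fit.cov_theta.copy()
        cov[4 * K : 5 * K, 4 * K : 5 * K] = block
        fit2.cov_theta = cov
        fit2.se = fit.se.copy()
        fit2.se[4] = np.sqrt(np.diag(fit.B @ block @ fit.B.T))
        sb = simultaneous_band(fit2, 4, alpha=0.05, n_sim=40_000, seed=1)
        assert sb.critical == pytest.approx(norm.ppf(0.975), abs=0.03)

    def test_simultaneous_deterministic_given_seed(self, fitted):
        _, fit = fitted
        b1 = simultaneous_band(fit, 1, n_sim=1000, seed=42)
        b2 = simultaneous_band(fit, 1, n_sim=1000, seed=42)
        np.testing.assert_array_equal(b1.lo, b2.lo)


class TestGlobalFTest:
    def test_strong_effect_detected(self, rng):
        def signal(grid):
            s = np.zeros((5, len(grid)))
            s[4] = 1.0 * np.exp(-0.5 * ((grid - 15) / 2.0) ** 2)
            return s

        des = random_design(rng, n=40, T=16, q=5, signal=signal)
        F, p = global_f_test(des, 4, n_perm=199, seed=3)
        assert F > 2.0 and p <= 0.01

    def test_null_covariate_not_rejected_too_often(self, rng):
        ps = []
        for k in range(20):
            des = random_design(np.random.default_rng(100 + k), n=30, T=12, q=3)
            _, p = global_f_test(des, 2, n_perm=99, seed=k)
            ps.append(p)
        assert np.mean(np.array(ps) <= 0.05) <= 0.25  # ~1 rejection expected

    def test_intercept_has_no_f_test(self, rng):
        des = random_design(rng)
        with pytest.raises(ValueError, match="intercept"):
            global_f_test(des, 0)

    def test_low_n_perm_warns(self, rng):
        des = random_design(rng, n=25, T=10, q=3)
        with pytest.warns(UserWarning, match="unstable"):
            global_f_test(des, 1, n_perm=19, seed=0)


class TestSignificantWindows:
    def _band(self, lo, hi):
        est = (np.asarray(lo) + np.asarray(hi)) / 2
        return Band(j=4, name="abeta", kind="pointwise", alpha=0.05,
                    estimate=est, lo=np.asarray(lo, float), hi=np.asarray(hi, float),
                    critical=1.96)

    def test_no_exclusion_empty_list(self):
        band = self._band(-np.ones(48), np.ones(48))
        assert significant_windows(band, GRID48) == []

    def test_wrapped_window_merges_across_midnight(self):
        lo, hi = -np.ones(48), np.ones(48)
        # excluded (negative) at 23:30-24:00 (bin 47) and 00:00-03:00 (bins 0-5)
        for b in [47, 0, 1, 2, 3, 4, 5]:
            lo[b], hi[b] = -2.0, -0.5
        ws = significant_windows(self._band(lo, hi), GRID48)
        assert len(ws) == 1
        w = ws[0]
        assert (w.start_clock, w.end_clock, w.sign) == ("23:30", "03:00", -1)
        assert w.n_bins == 7

    def test_single_bin_window(self):
        lo, hi = -np.ones(48), np.ones(48)
        lo[20] = 0.4  # positive exclusion at 10:00-10:30
        ws = significant_windows(self._band(lo, hi), GRID48)
        assert len(ws) == 1
        assert (ws[0].start_clock, ws[0].end_clock, ws[0].sign) == ("10:00", "10:30", 1)

    def test_adjacent_opposite_signs_split(self):
        lo, hi = -np.ones(48), np.ones(48)
        lo[10], hi[10] = 0.2, 1.0
        lo[11], hi[11] = -1.0, -0.2
        ws = significant_windows(self._band(lo, hi), GRID48)
        assert [w.sign for w in ws] == [1, -1]


class TestSDOutcomePath:
    def test_sd_profiles_run_through_same_engine(self, small_cohort):
        mats = [preprocess_subject(s) for s in small_cohort.subjects]
        rars = [subject_rar(m) for m in mats if not m.excluded_from_rar]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            des = build_design(rars, small_cohort.covariates, outcome="sd")
            fit = fit_fosr(des)
        assert fit.coef.shape == (5, 48)
        assert np.isfinite(fit.se).all()
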