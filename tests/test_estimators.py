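"""MR estimators against hand calculations and independent WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from triomr import (
    estimate_all,
    ivw,
    ivw_headline,
    mode_estimators,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from triomr.errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    RankDeficiencyError,
)
from triomr.estimators import MREstimate, MRFailure

from conftest import make_instruments, random_instruments


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [
            (0.1, -0.003, 0.01, -0.03, 0.1),
            (1.0, 0.42, 0.05, 0.42, 0.05),
            (0.5, 0.02, 0.004, 0.04, 0.008),
        ],
    )
    def test_ratio_and_delta_se(self, bx, by, sy, beta, se):
        est = wald_ratio(bx, 0.01, by, sy)
        np.testing.assert_allclose([est.beta, est.se], [beta, se])

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


class TestIVW:
    def test_two_snp_hand_oracle(self):
        instr = make_instruments([1, 1], [0.01, 0.01], [0.1, 0.3],
                                 [0.1, 0.1])
        fe, re = ivw(instr)
        np.testing.assert_allclose(fe.beta, 0.2)
        np.testing.assert_allclose(fe.se, np.sqrt(1 / 200))

    def test_shared_ratio_is_degenerate_homogeneous(self):
        bx = np.array([0.1, 0.2, 0.3])
        instr = make_instruments(bx, 0.01 * np.ones(3), 0.04 * bx,
                                 [0.01, 0.02, 0.03])
        fe, re = ivw(instr)
        np.testing.assert_allclose(fe.beta, 0.04)
        np.testing.assert_allclose(fe.extra["q_stat"], 0.0, atol=1e-20)
        assert fe.se == re.se

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_wls_through_origin(self, seed):
        instr = random_instruments(np.random.default_rng(seed))
        fe, _ = ivw(instr)
        wls = sm.WLS(instr.beta_out, instr.beta_exp,
                     weights=1 / instr.se_out**2).fit()
        np.testing.assert_allclose(fe.beta, wls.params[0], atol=1e-10,
                                   rtol=0)

    def test_headline_picks_random_effects_when_overdispersed(self):
        bx = np.ones(5)
        instr = make_instruments(bx, 0.01 * bx,
                                 [0.5, -0.5, 0.4, -0.4, 0.0],
                                 0.01 * np.ones(5))
        assert ivw_headline(instr).method == "ivw_re"

    def test_single_snp_insufficient(self):
        instr = make_instruments([0.1], [0.01], [0.01], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(instr)


class TestEgger:
    def test_exact_linear_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.2 * bx
        instr = make_instruments(bx, 0.01 * np.ones(4), by,
                                 0.02 * np.ones(4))
        est = mr_egger(instr)
        np.testing.assert_allclose(est.beta, 0.2, atol=1e-12)
        np.testing.assert_allclose(est.extra["intercept"], 0.05, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_wls_with_intercept(self, seed):
        instr = random_instruments(np.random.default_rng(seed))
        est = mr_egger(instr)
        sign = np.where(instr.beta_exp < 0, -1.0, 1.0)
        X = sm.add_constant(instr.beta_exp * sign)
        wls = sm.WLS(instr.beta_out * sign, X,
                     weights=1 / instr.se_out**2).fit()
        np.testing.assert_allclose(est.extra["intercept"], wls.params[0],
                                   atol=1e-10, rtol=0)
        np.testing.assert_allclose(est.beta, wls.params[1], atol=1e-10,
                                   rtol=0)
        np.testing.assert_allclose(
            [est.extra["intercept_se"], est.se], wls.bse, atol=1e-10, rtol=0
        )

    def test_identical_exposure_effects_rank_deficient(self):
        instr = make_instruments([0.2, 0.2, -0.2], [0.01] * 3,
                                 [0.1, 0.2, 0.1], [0.02] * 3)
        with pytest.raises(RankDeficiencyError):
            mr_egger(instr)

    def test_intercept_test_calibrated_under_null(self):
        """No pleiotropy: intercept rejection rate stays near 5%."""
        rng = np.random.default_rng(11)
        k, reps, rej = 15, 2000, 0
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.5, k)
            sy = rng.uniform(0.01, 0.05, k)
            by = 0.1 * bx + rng.normal(0, sy)
            instr = make_instruments(bx, 0.01 * np.ones(k), by, sy)
            rej += mr_egger(instr).extra["intercept_p"] < 0.05
        assert abs(rej / reps - 0.05) < 0.017  # ±3 Monte-Carlo SDs


def median_oracle(ratios, weights):
    """Cumulative-weight interpolation, written independently."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    below = np.searchsorted(cum, 0.5)
    if below == 0:
        return r[0]
    if below == len(r):
        return r[-1]
    x0, x1 = cum[below - 1], cum[below]
    return r[below - 1] + (0.5 - x0) / (x1 - x0) * (r[below] - r[below - 1])


class TestWeightedMedian:
    def test_equal_weights_is_median(self):
        instr = make_instruments([1, 1, 1], [0.01] * 3, [1, 2, 3],
                                 [0.1] * 3)
        assert weighted_median(instr, n_boot=50, seed=1).beta == 2.0

    def test_dominant_weight_pulls_to_that_ratio(self):
        instr = make_instruments(
            [1, 1, 1], [0.01] * 3, [1.0, 2.0, 5.0],
            [10.0, 10.0, 0.01],
        )
        est = weighted_median(instr, n_boot=50, seed=1)
        assert abs(est.beta - 5.0) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_interpolation_oracle(self, seed):
        instr = random_instruments(np.random.default_rng(seed), k=15)
        est = weighted_median(instr, n_boot=10, seed=0)
        expect = median_oracle(instr.beta_out / instr.beta_exp,
                               instr.beta_exp**2 / instr.se_out**2)
        np.testing.assert_allclose(est.beta, expect, atol=1e-12)

    def test_bootstrap_seed_reproducible(self):
        instr = random_instruments(np.random.default_rng(3), k=10)
        a = weighted_median(instr, n_boot=200, seed=7)
        b = weighted_median(instr, n_boot=200, seed=7)
        assert a.se == b.se


class TestModes:
    def test_dominant_cluster_sets_simple_mode(self):
        instr = make_instruments([1, 1, 1, 1], [0.01] * 4,
                                 [0.1, 0.1, 0.1, 0.5], [0.05] * 4)
        simple, _ = mode_estimators(instr, n_boot=50, seed=1)
        assert abs(simple.beta - 0.1) < 0.05

    def test_identical_ratios_returned_exactly(self):
        bx = np.array([0.1, 0.2, 0.3])
        instr = make_instruments(bx, [0.01] * 3, 0.04 * bx, [0.05] * 3)
        simple, weighted = mode_estimators(instr, n_boot=50, seed=1)
        assert simple.beta == 0.04 and weighted.beta == 0.04

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(5)
        instr = random_instruments(rng, k=12)
        simple, weighted = mode_estimators(instr, n_boot=10, seed=0)
        ratios = instr.beta_out / instr.beta_exp
        s = np.std(ratios, ddof=1)
        from scipy.stats import median_abs_deviation

        mad = median_abs_deviation(ratios, scale="normal")
        h = 0.9 * min(s, mad) * len(ratios) ** (-1 / 5)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h,
                           20001)
        dens = np.exp(
            -0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2
        ).sum(axis=1)
        # agreement limited by the implementation's own 512-point grid
        coarse_step = (np.ptp(ratios) + 6 * h) / 511
        assert abs(simple.beta - grid[np.argmax(dens)]) < 1.5 * coarse_step


class TestEstimateAll:
    def test_single_snp_dispatches_wald(self):
        instr = make_instruments([0.1], [0.01], [-0.003], [0.01])
        out = estimate_all(instr)
        assert [e.method for e in out] == ["wald"]

    def test_two_snps_run_ivw_only(self):
        instr = make_instruments([0.1, 0.2], [0.01] * 2, [0.01, 0.02],
                                 [0.01] * 2)
        methods = [e.method for e in estimate_all(instr)]
        assert methods == ["ivw_fe", "ivw_re"]

    def test_full_battery_has_six_estimates(self, rng):
        instr = random_instruments(rng, k=10)
        out = estimate_all(instr, seed=1, n_boot=50)
        methods = [e.method for e in out if isinstance(e, MREstimate)]
        assert methods == [
            "ivw_fe", "ivw_re", "egger", "weighted_median",
            "simple_mode", "weighted_mode",
        ]

    def test_member_failure_recorded_not_raised(self):
        # identical exposure effects break Egger but nothing else
        instr = make_instruments([0.2] * 4, [0.01] * 4,
                                 [0.1, 0.11, 0.09, 0.1], [0.02] * 4)
        out = estimate_all(instr, n_boot=20)
        failures = [e for e in out if isinstance(e, MRFailure)]
        assert len(failures) == 1 and failures[0].method == "egger"


class TestEstimatorProperties:
    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_outcome_scale_equivariance(self, c, rng):
        instr = random_instruments(rng, k=10)
        scaled = make_instruments(
            instr.beta_exp, instr.se_exp, c * instr.beta_out,
            c * instr.se_out,
        )
        for f in (lambda i: ivw(i)[0], mr_egger,
                  lambda i: weighted_median(i, n_boot=100, seed=2)):
            a, b = f(instr), f(scaled)
            np.testing.assert_allclose(b.beta, c * a.beta, rtol=1e-9)
            np.testing.assert_allclose(b.se, c * a.se, rtol=0.2)

    def test_instrument_orientation_invariance(self, rng):
        instr = random_instruments(rng, k=10)
        flip = np.ones(10)
        flip[[1, 4, 7]] = -1
        flipped = make_instruments(
            flip * instr.beta_exp, instr.se_exp, flip * instr.beta_out,
            instr.se_out,
        )
        for f in (lambda i: ivw(i)[0], mr_egger,
                  lambda i: weighted_median(i, n_boot=50, seed=2)):
            np.testing.assert_allclose(f(flipped).beta, f(instr).beta,
                                       atol=1e-12)

    def test_parameter_recovery_no_pleiotropy(self):
        """All methods near the true effect with strong instruments."""
        rng = np.random.default_rng(99)
        true = 0.12
        k = 40
        bx = rng.uniform(0.2, 0.6, k)
        sy = np.full(k, 0.005)
        by = true * bx + rng.normal(0, sy)
        instr = make_instruments(bx, np.full(k, 0.002), by, sy)
        ests = [e for e in estimate_all(instr, seed=4, n_boot=100)
                if isinstance(e, MREstimate)]
        for e in ests:
            assert abs(e.beta - true) < 0.03, e.method
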