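"""Estimators: growth windows, log-linear mu, Lineweaver-Burk, threshold,
yields, Luedeking-Piret fits, and temperature recalibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chokinetics as ck
from chokinetics.estimation import GrowthScreen


def exp_culture(mu, t, X0=2e5, S=4.8):
    t = np.asarray(t, dtype=float)
    return ck.CultureTimeSeries(
        time=t, X=X0 * np.exp(mu * t), S=np.full_like(t, S)
    )


class TestSelectExponentialWindow:
    def test_pure_exponential_selects_full_series(self):
        s = exp_culture(0.035, np.arange(0.0, 168.0 + 1e-9, 24.0))
        assert ck.select_exponential_window(s) == (0.0, 168.0)

    def test_exponential_then_plateau_matches_brute_force(self):
        t = np.arange(0.0, 192.0 + 1e-9, 24.0)
        X = np.where(t <= 96.0, 2e5 * np.exp(0.035 * t), 2e5 * np.exp(0.035 * 96.0))
        s = ck.CultureTimeSeries(time=t, X=X, S=np.full_like(t, 4.8))

        # independent oracle: enumerate every contiguous window
        def r2(i, j):
            res = np.polyfit(t[i:j], np.log(X[i:j]), 1, full=True)
            ss_res = float(res[1][0]) if res[1].size else 0.0
            y = np.log(X[i:j])
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        best = None
        for i in range(t.size):
            for j in range(i + 3, t.size + 1):
                if r2(i, j) >= 0.98:
                    cand = (j - i, -i, j)
                    best = max(best, cand) if best else cand
        expected = (t[-best[1]], t[best[2] - 1])
        assert ck.select_exponential_window(s, 3, 0.98) == expected
        assert expected == (0.0, 96.0)  # the exponential prefix

    def test_too_few_samples_rejected(self):
        s = exp_culture(0.035, [0.0, 24.0])
        with pytest.raises(ValueError):
            ck.select_exponential_window(s, min_points=3)

    def test_no_qualifying_window_suggests_lower_floor(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 96.0 + 1e-9, 24.0)
        s = ck.CultureTimeSeries(
            time=t, X=1e5 * (1 + rng.uniform(0, 5, t.size)), S=np.full_like(t, 4.8)
        )
        with pytest.raises(ValueError, match="floor"):
            ck.select_exponential_window(s, 3, r2_floor=0.999999)


class TestEstimateMuLoglinear:
    def test_exact_exponential(self):
        s = exp_culture(0.035, [0.0, 24.0, 48.0, 72.0])
        fit = ck.estimate_mu_loglinear(s)
        assert fit["mu"] == pytest.approx(0.035, rel=1e-12)
        assert fit["ln_X0"] == pytest.approx(np.log(2e5), rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_culture_zero_mu(self):
        s = ck.CultureTimeSeries(
            time=[0.0, 24.0, 48.0], X=[2e5] * 3, S=[4.8] * 3
        )
        assert ck.estimate_mu_loglinear(s)["mu"] == pytest.approx(0.0, abs=1e-15)

    def test_noisy_exponential_matches_direct_regression_oracle(self):
        t = np.arange(0.0, 168.0 + 1e-9, 24.0)
        eps = 0.01 * (-1.0) ** np.arange(t.size)  # alternating +-1%
        X = 2e5 * np.exp(0.040 * t) * (1 + eps)
        s = ck.CultureTimeSeries(time=t, X=X, S=np.full_like(t, 4.8))
        fit = ck.estimate_mu_loglinear(s)
        oracle = np.polyfit(t, np.log(X), 1)[0]
        assert fit["mu"] == pytest.approx(oracle, rel=1e-12)
        assert fit["mu"] == pytest.approx(0.040, abs=1e-3)

    def test_nonpositive_cells_rejected(self):
        s = ck.CultureTimeSeries(
            time=[0.0, 24.0, 48.0], X=[2e5, 0.0, 3e5], S=[4.8] * 3
        )
        with pytest.raises(ValueError):
            ck.estimate_mu_loglinear(s)


class TestLineweaverBurk:
    S0_GRID = (4.8, 3.6, 2.4, 1.2)

    @pytest.mark.parametrize(
        "mu_max, K_s, S_t",
        [
            (0.040, 0.664, 0.58),   # shipped r-CHO
            (0.038, 0.286, 0.96),   # shipped n-CHO 33 C
            (0.050, 1.023, 0.58),   # shipped n-CHO 37 C
            (0.050, 2.058, 0.60),   # alternate n-CHO fit
        ],
    )
    def test_noiseless_roundtrip_is_algebraically_exact(self, mu_max, K_s, S_t):
        p = ck.KineticParameters(mu_max=mu_max, K_s=K_s, S_t=S_t, Y_xs=1e6)
        pairs = [(s0, ck.monod_mu(s0, p)) for s0 in self.S0_GRID]
        fit = ck.fit_monod_lineweaver_burk(pairs, S_t=S_t)
        assert fit["mu_max"] == pytest.approx(mu_max, rel=1e-9)
        assert fit["K_s"] == pytest.approx(K_s, rel=1e-9)
        assert fit.valid

    @settings(derandomize=True, max_examples=100)
    @given(
        mu_max=st.floats(0.01, 0.2),
        K_s=st.floats(0.05, 5.0),
        S_t=st.floats(0.0, 1.0),
    )
    def test_roundtrip_property_any_positive_triple(self, mu_max, K_s, S_t):
        p = ck.KineticParameters(mu_max=mu_max, K_s=K_s, S_t=S_t, Y_xs=1e6)
        pairs = [(S_t + ds, ck.monod_mu(S_t + ds, p)) for ds in (0.5, 1.0, 2.0, 4.0)]
        fit = ck.fit_monod_lineweaver_burk(pairs, S_t=S_t)
        assert fit["mu_max"] == pytest.approx(mu_max, rel=1e-6)
        assert fit["K_s"] == pytest.approx(K_s, rel=1e-6)

    def test_saturated_flat_mu(self):
        fit = ck.fit_monod_lineweaver_burk(
            [(2.0, 0.04), (3.0, 0.04), (4.0, 0.04)], S_t=0.5
        )
        assert fit["mu_max"] == pytest.approx(0.04)
        assert fit["K_s"] == 0.0

    def test_subthreshold_points_excluded_with_warning(self, rcho):
        pairs = [(s0, ck.monod_mu(s0, rcho)) for s0 in self.S0_GRID]
        pairs.append((0.4, 0.01))  # below threshold, must be dropped
        with pytest.warns(UserWarning, match="excluded"):
            fit = ck.fit_monod_lineweaver_burk(pairs, S_t=0.58)
        assert fit["mu_max"] == pytest.approx(0.040, rel=1e-9)

    def test_too_few_usable_points(self):
        with pytest.raises(ValueError, match="3 usable"):
            ck.fit_monod_lineweaver_burk([(1.0, 0.01), (2.0, 0.02)], S_t=0.5)

    def test_nonpositive_intercept_rejected(self):
        # reciprocal line with negative intercept: no finite mu_max
        S_t = 0.0
        s0 = np.array([1.0, 2.0, 3.0])
        inv_mu = 2.0 / s0 - 0.5
        pairs = list(zip(s0, 1.0 / inv_mu))
        with pytest.raises(ValueError, match="intercept"):
            ck.fit_monod_lineweaver_burk(pairs, S_t=S_t)

    def test_agrees_with_nonlinear_cross_check(self, rcho):
        pairs = [(s0, ck.monod_mu(s0, rcho)) for s0 in self.S0_GRID]
        lb = ck.fit_monod_lineweaver_burk(pairs, S_t=0.58)
        nl = ck.fit_monod_nonlinear(pairs, S_t=0.58)
        assert lb["mu_max"] == pytest.approx(nl["mu_max"], rel=1e-6)
        assert lb["K_s"] == pytest.approx(nl["K_s"], rel=1e-6)


class TestEstimateThreshold:
    def test_screen_design_midpoint(self):
        screen = GrowthScreen(
            entries=(
                (0.25, False, None),
                (0.45, False, None),
                (0.65, True, 0.003),
                (1.2, True, 0.019),
            )
        )
        est, bracket = ck.estimate_threshold(screen)
        assert bracket == (0.45, 0.65)
        assert est == pytest.approx(0.55)

    def test_tight_bracket_converges_on_truth(self):
        d = 1e-4
        screen = GrowthScreen(
            entries=((0.58 - d, False, None), (0.58 + d, True, 1e-4))
        )
        est, _ = ck.estimate_threshold(screen)
        assert est == pytest.approx(0.58, abs=1e-6)

    def test_all_grew_is_an_error(self):
        screen = GrowthScreen(entries=((1.0, True, 0.01), (2.0, True, 0.02)))
        with pytest.raises(ValueError):
            ck.estimate_threshold(screen)


class TestEstimateYield:
    def test_constant_ratio_recovers_slope(self):
        r_s = -np.array([1e-3, 2e-3, 4e-3, 8e-3])
        r_x = 2.79e6 * (-r_s)
        fit = ck.estimate_yield(r_x, r_s)
        assert fit["Y_xs"] == pytest.approx(2.79e6, rel=1e-12)

    def test_zero_growth_zero_yield(self):
        fit = ck.estimate_yield(np.zeros(4), -np.array([1e-3, 2e-3, 3e-3, 4e-3]))
        assert fit["Y_xs"] == 0.0

    def test_no_consumption_is_an_error(self):
        with pytest.raises(ValueError, match="consumption"):
            ck.estimate_yield(np.ones(3), np.array([0.0, 1e-3, 2e-3]))

    def test_simulator_roundtrip_through_rate_pipeline(self, rcho):
        truth = 1.70e6
        p = rcho.with_(Y_xs=truth)
        t = np.arange(0.0, 96.0 + 1e-9, 24.0)
        s = ck.simulate_batch(p, 2e5, 4.8, 96.0, 0.1, sample_times=t)
        px = ck.fit_polynomial_window(s, "X", 2)
        ps = ck.fit_polynomial_window(s, "S", 2)
        fit = ck.estimate_yield(ck.differentiate(px, t), ck.differentiate(ps, t))
        assert fit["Y_xs"] == pytest.approx(truth, rel=0.02)

    def test_invariant_to_halving_the_window_sampling(self, rcho):
        t_full = np.arange(0.0, 96.0 + 1e-9, 12.0)
        s = ck.simulate_batch(rcho, 2e5, 4.8, 96.0, 0.1, sample_times=t_full)
        px = ck.fit_polynomial_window(s, "X", 2)
        ps = ck.fit_polynomial_window(s, "S", 2)
        y_full = ck.estimate_yield(
            ck.differentiate(px, t_full), ck.differentiate(ps, t_full)
        )["Y_xs"]
        t_half = t_full[::2]
        y_half = ck.estimate_yield(
            ck.differentiate(px, t_half), ck.differentiate(ps, t_half)
        )["Y_xs"]
        assert y_half == pytest.approx(y_full, rel=1e-3)


class TestLuedekingPiretFits:
    def logistic_profile(self, dt=0.1):
        from chokinetics.synthetic_data import logistic_decline_profile

        t = np.arange(0.0, 240.0 + 1e-9, dt)
        X = logistic_decline_profile(t)
        r_x = np.gradient(X, t)
        return t, X, r_x

    def test_direct_fit_recovers_generating_constants(self, rcho):
        t, X, r_x = self.logistic_profile()
        P = ck.euler_integrate_product(t, X, r_x, rcho, P0=0.0)
        r_p = np.diff(P) / np.diff(t)
        fit = ck.fit_lp_direct(r_p, r_x[:-1], X[:-1])
        assert fit["alpha"] == pytest.approx(7.65e-7, rel=1e-9)
        assert fit["beta"] == pytest.approx(7.68e-8, rel=1e-9)

    def test_beta_zero_generator(self, rcho):
        t, X, r_x = self.logistic_profile()
        p = rcho.with_(beta=0.0)
        P = ck.euler_integrate_product(t, X, r_x, p, P0=0.0)
        r_p = np.diff(P) / np.diff(t)
        fit = ck.fit_lp_direct(r_p, r_x[:-1], X[:-1])
        assert fit["alpha"] == pytest.approx(7.65e-7, rel=1e-9)
        assert fit["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_exponential_is_ill_posed(self, rcho):
        t = np.arange(0.0, 96.0 + 1e-9, 1.0)
        X = 2e5 * np.exp(0.03 * t)
        r_x = 0.03 * X  # exactly proportional to X
        r_p = ck.luedeking_piret_rate(r_x, X, rcho)
        with pytest.raises(ValueError, match="integral"):
            ck.fit_lp_direct(r_p, r_x, X)

    def test_integral_fit_self_consistent_roundtrip(self, rcho):
        t, X, r_x = self.logistic_profile(dt=1.0)
        P = ck.euler_integrate_product(t, X, r_x, rcho, P0=0.0)
        fit = ck.fit_lp_integral(t, P, X, r_x)
        assert fit["alpha"] == pytest.approx(7.65e-7, rel=1e-3)
        assert fit["beta"] == pytest.approx(7.68e-8, rel=1e-3)

    def test_constant_product_gives_zero_constants(self):
        t = np.arange(0.0, 96.0 + 1e-9, 12.0)
        X = 1e6 + 1e4 * t
        fit = ck.fit_lp_integral(t, np.full_like(t, 5.0), X, np.full_like(t, 1e4))
        assert fit["alpha"] == pytest.approx(0.0, abs=1e-10)
        assert fit["beta"] == pytest.approx(0.0, abs=1e-11)

    def test_direct_and_integral_agree_on_clean_data(self, rcho):
        t, X, r_x = self.logistic_profile(dt=1.0)
        P = ck.euler_integrate_product(t, X, r_x, rcho, P0=0.0)
        r_p = np.diff(P) / np.diff(t)
        direct = ck.fit_lp_direct(r_p, r_x[:-1], X[:-1])
        integral = ck.fit_lp_integral(t, P, X, r_x)
        assert integral["alpha"] == pytest.approx(direct["alpha"], rel=0.01)
        assert integral["beta"] == pytest.approx(direct["beta"], rel=0.01)


class TestRecalibration:
    def observed(self, params, dt=0.1):
        t = np.arange(0.0, 168.0 + 1e-9, 24.0)
        return ck.simulate_batch(params, 2e5, 4.8, 168.0, dt, sample_times=t)

    def test_recovers_perturbed_triple(self, rcho):
        truth = rcho.with_(
            mu_max=rcho.mu_max * 1.25,
            Y_xs=rcho.Y_xs * 0.66,
            beta=rcho.beta * 0.4,
        )
        rec = ck.recalibrate_at_temperature(self.observed(truth), rcho)
        assert rec.mu_max == pytest.approx(truth.mu_max, rel=0.01)
        assert rec.Y_xs == pytest.approx(truth.Y_xs, rel=0.01)
        assert rec.beta == pytest.approx(truth.beta, rel=0.01)
        # held fixed by construction
        assert (rec.S_t, rec.alpha, rec.K_s) == (rcho.S_t, rcho.alpha, rcho.K_s)

    def test_fixed_point_returns_base(self, rcho):
        rec = ck.recalibrate_at_temperature(self.observed(rcho), rcho)
        assert rec.mu_max == pytest.approx(rcho.mu_max, rel=0.01)
        assert rec.Y_xs == pytest.approx(rcho.Y_xs, rel=0.01)
        assert rec.beta == pytest.approx(rcho.beta, rel=0.01)

    def test_beta_recovered_within_published_37C_range(self, rcho):
        # 37 C-like cultures: slower product accumulation, beta = 2e-8
        truth = rcho.with_(beta=2e-8)
        rec = ck.recalibrate_at_temperature(self.observed(truth), rcho)
        assert 1.38e-8 <= rec.beta <= 3.38e-8


class TestGrowthPipeline:
    def test_noiseless_dataset_recovers_monod_parameters(self, rcho):
        from chokinetics.synthetic_data import (
            ExperimentDesign,
            NoiseModel,
            generate_batch_dataset,
        )

        design = ExperimentDesign(replicates=1)
        data = generate_batch_dataset(
            design, rcho, NoiseModel.noiseless(), dt=0.25
        )
        fit = ck.estimate_growth_parameters(data, S_t=rcho.S_t)
        assert fit["mu_max"] == pytest.approx(rcho.mu_max, rel=0.01)
        assert fit["K_s"] == pytest.approx(rcho.K_s, rel=0.01)
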