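"""Beer-Lambert conversion, kinetic fitting, stoichiometry and model choice."""

import warnings

import numpy as np
import pytest

import dpphkin as dk
from dpphkin.estimation import round_half_up

from conftest import (
    AOH_KNOWN,
    DPPH0,
    GALLIC_AOH0,
    GALLIC_K1,
    GALLIC_K2,
    SINAPIC_AOH0,
    SINAPIC_K1,
    as_conc_trace,
)


class TestBeerLambert:
    def test_assay_start_absorbance_maps_to_100uM(self):
        trace = dk.AbsorbanceTrace(times=[0.0, 1.0], absorbance=[1.087, 1.087])
        conc = dk.absorbance_to_concentration(trace)
        assert conc.dpph[0] == pytest.approx(100e-6, rel=1e-9)

    def test_zero_absorbance_is_zero_concentration(self):
        trace = dk.AbsorbanceTrace(times=[0.0, 1.0], absorbance=[0.0, 0.0])
        assert dk.absorbance_to_concentration(trace).dpph[0] == 0.0

    def test_linearity_in_epsilon(self):
        a = dk.AbsorbanceTrace(times=[0.0, 1.0], absorbance=[0.5, 0.4],
                               epsilon=10_870.0)
        b = dk.AbsorbanceTrace(times=[0.0, 1.0], absorbance=[0.5, 0.4],
                               epsilon=21_740.0)
        np.testing.assert_allclose(
            dk.absorbance_to_concentration(b).dpph,
            dk.absorbance_to_concentration(a).dpph / 2,
        )

    def test_negative_absorbance_clipped_with_warning(self):
        trace = dk.AbsorbanceTrace(times=[0.0, 1.0], absorbance=[0.01, -0.002])
        with pytest.warns(UserWarning):
            conc = dk.absorbance_to_concentration(trace)
        assert conc.dpph[-1] == 0.0


class TestRSquared:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert dk.compute_r_squared(obs, obs) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.full(3, 2.0)
        assert dk.compute_r_squared(obs, pred) == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        # SSR = (1-3)^2+(2-2)^2+(3-1)^2 = 8; SStot = 2 -> R^2 = -3
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([3.0, 2.0, 1.0])
        assert dk.compute_r_squared(obs, pred) == pytest.approx(-3.0)

    def test_constant_observed_is_undefined(self):
        with pytest.raises(ValueError):
            dk.compute_r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestStoichiometricFactors:
    def test_fitted_ratio_worked_example(self):
        assert dk.stoichiometric_factor_fitted(20e-6, 10e-6) == pytest.approx(2.0)

    def test_fitted_ratio_identity_and_gallic_value(self):
        assert dk.stoichiometric_factor_fitted(1e-5, 1e-5) == pytest.approx(1.0)
        assert dk.stoichiometric_factor_fitted(29e-6, 10e-6) == pytest.approx(2.9)

    def test_graphical_worked_example(self, assay_ctx):
        # loss of 20 uM over a plateaued trace, known 10 uM -> n = 2
        t = np.arange(0.0, 11.0)
        d = np.concatenate([np.linspace(100e-6, 80e-6, 6), np.full(5, 80e-6)])
        z = np.zeros_like(d)
        trace = dk.ConcentrationTrace(times=t, dpph=d, aoh=z, ao=z)
        assert dk.stoichiometric_factor_graphical(trace, assay_ctx) == pytest.approx(2.0)

    def test_graphical_zero_loss(self, assay_ctx):
        t = np.arange(0.0, 11.0)
        d = np.full(11, 1e-4)
        z = np.zeros_like(d)
        trace = dk.ConcentrationTrace(times=t, dpph=d, aoh=z, ao=z)
        assert dk.stoichiometric_factor_graphical(trace, assay_ctx) == 0.0

    def test_graphical_warns_before_plateau(self, assay_ctx):
        t = np.arange(0.0, 11.0)
        d = np.linspace(100e-6, 80e-6, 11)  # still falling linearly
        z = np.zeros_like(d)
        trace = dk.ConcentrationTrace(times=t, dpph=d, aoh=z, ao=z)
        with pytest.warns(UserWarning):
            dk.stoichiometric_factor_graphical(trace, assay_ctx)

    def test_graphical_agrees_with_fitted_ratio_at_completion(self, assay_ctx, fit_cfg):
        """Simple scheme run to completion: both n routes agree within 1%."""
        aoh0 = 2 * AOH_KNOWN
        trace = dk.simulate_decay(
            dk.RateParameters(k1=5e3, include_side=False),
            dk.InitialState(DPPH0, aoh0),
            dk.TimeGrid.regular(3000.0, 10.0),
        )
        conc = as_conc_trace(trace)
        n_graph = dk.stoichiometric_factor_graphical(conc, assay_ctx)
        res = dk.fit_kinetics(conc, assay_ctx, "simple", fit_cfg)
        n_fit = dk.stoichiometric_factor_fitted(res.aoh0_fit, assay_ctx.aoh_known)
        assert n_graph == pytest.approx(n_fit, rel=0.01)


class TestAggregateN:
    def test_panel_mean_half_up(self):
        pairs = [(10e-6, 1.8), (20e-6, 1.5), (50e-6, 1.3), (100e-6, 1.0)]
        assert dk.aggregate_n(pairs) == pytest.approx(1.7)

    def test_identical_values(self):
        assert dk.aggregate_n([(1e-5, 2.0), (2e-5, 2.0)]) == pytest.approx(2.0)

    def test_only_two_lowest_used_and_half_up(self):
        assert dk.aggregate_n([(10e-6, 2.0), (20e-6, 2.1), (50e-6, 0.5)]) == \
            pytest.approx(2.1)

    def test_too_few_entries(self):
        with pytest.raises(ValueError):
            dk.aggregate_n([(1e-5, 2.0)])

    def test_round_half_up_vs_bankers(self):
        assert round_half_up(2.05, 1) == 2.1
        assert round_half_up(1.65, 1) == 1.7


class TestFitKinetics:
    def test_simple_recovery_noiseless(self, sinapic_trace, assay_ctx, fit_cfg):
        res = dk.fit_kinetics(as_conc_trace(sinapic_trace), assay_ctx,
                              "simple", fit_cfg)
        assert res.k1 == pytest.approx(SINAPIC_K1, rel=1e-3)
        assert res.aoh0_fit == pytest.approx(SINAPIC_AOH0, rel=1e-3)
        assert res.r_squared > 0.999999

    def test_side_recovery_noiseless(self, gallic_trace, assay_ctx, fit_cfg):
        res = dk.fit_kinetics(as_conc_trace(gallic_trace), assay_ctx,
                              "side", fit_cfg)
        assert res.k1 == pytest.approx(GALLIC_K1, rel=1e-3)
        assert res.k2 == pytest.approx(GALLIC_K2, rel=1e-3)
        assert res.aoh0_fit == pytest.approx(GALLIC_AOH0, rel=1e-3)
        assert res.n_fit == pytest.approx(2.9, rel=1e-3)

    def test_constant_trace_is_degenerate(self, assay_ctx, fit_cfg):
        t = np.arange(0.0, 20.0)
        d = np.full(20, 1e-4)
        z = np.zeros_like(d)
        conc = dk.ConcentrationTrace(times=t, dpph=d, aoh=z, ao=z)
        with pytest.raises(dk.estimation.FitFailureError):
            dk.fit_kinetics(conc, assay_ctx, "simple", fit_cfg)

    def test_short_trace_rejected(self, assay_ctx, fit_cfg):
        t = np.arange(0.0, 5.0)
        d = np.linspace(1e-4, 9e-5, 5)
        z = np.zeros_like(d)
        conc = dk.ConcentrationTrace(times=t, dpph=d, aoh=z, ao=z)
        with pytest.raises(ValueError):
            dk.fit_kinetics(conc, assay_ctx, "simple", fit_cfg)

    def test_recovery_over_random_parameter_sets(self, assay_ctx):
        """Noiseless refits recover free parameters within 0.5%."""
        rng = np.random.default_rng(7)
        cfg = dk.FitConfig(seed=3, n_starts=3)
        for _ in range(10):
            k1 = rng.uniform(0.1e3, 12e3)
            k2 = rng.uniform(0.0, 150.0)
            ratio = rng.uniform(0.1, 0.5)
            aoh0 = ratio * DPPH0
            side = k2 > 0
            trace = dk.simulate_decay(
                dk.RateParameters(k1=k1, k2=k2, include_side=side),
                dk.InitialState(DPPH0, aoh0),
                dk.TimeGrid.regular(300.0),
            )
            res = dk.fit_kinetics(as_conc_trace(trace), assay_ctx,
                                  "side" if side else "simple", cfg)
            assert res.k1 == pytest.approx(k1, rel=5e-3)
            assert res.aoh0_fit == pytest.approx(aoh0, rel=5e-3)
            if side and k2 > 1.0:
                assert res.k2 == pytest.approx(k2, rel=5e-3)


class TestEstimatorInterface:
    def test_get_set_params_clone(self):
        from sklearn.base import clone

        est = dk.DPPHKineticsEstimator(model="side", seed=5)
        params = est.get_params()
        assert params["model"] == "side" and params["seed"] == 5
        est2 = clone(est).set_params(model="simple")
        assert est2.model == "simple"

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError):
            dk.DPPHKineticsEstimator().predict([0.0, 1.0])

    def test_fitted_attributes_and_predict(self, sinapic_trace):
        est = dk.DPPHKineticsEstimator(model="simple", dpph0=DPPH0,
                                       aoh_known=AOH_KNOWN, seed=1)
        est.fit(sinapic_trace.times.reshape(-1, 1), sinapic_trace.dpph)
        for attr in ("k1_", "aoh0_", "n_fit_", "r_squared_", "ssr_", "model_"):
            assert hasattr(est, attr)
        pred = est.predict(sinapic_trace.times)
        np.testing.assert_allclose(pred, sinapic_trace.dpph, atol=1e-9)
        # RegressorMixin score = R^2
        assert est.score(sinapic_trace.times.reshape(-1, 1),
                         sinapic_trace.dpph) > 0.999999


class TestModelSelection:
    def test_simple_data_selects_simple(self, sinapic_trace, assay_ctx, fit_cfg):
        conc = as_conc_trace(sinapic_trace)
        fs = dk.fit_kinetics(conc, assay_ctx, "simple", fit_cfg)
        fx = dk.fit_kinetics(conc, assay_ctx, "side", fit_cfg)
        sel = dk.select_model(fs, fx)
        assert sel.chosen == "simple"

    def test_side_data_selects_side(self, gallic_trace, assay_ctx, fit_cfg):
        conc = as_conc_trace(gallic_trace)
        fs = dk.fit_kinetics(conc, assay_ctx, "simple", fit_cfg)
        fx = dk.fit_kinetics(conc, assay_ctx, "side", fit_cfg)
        sel = dk.select_model(fs, fx)
        assert sel.chosen == "side"
        assert sel.r_squared_side > sel.r_squared_simple

    def test_simple_model_underfits_side_data(self, gallic_trace, assay_ctx,
                                              fit_cfg):
        """The one-reaction scheme cannot explain side-reaction kinetics."""
        conc = as_conc_trace(gallic_trace)
        fs = dk.fit_kinetics(conc, assay_ctx, "simple", fit_cfg)
        fx = dk.fit_kinetics(conc, assay_ctx, "side", fit_cfg)
        assert fs.r_squared < fx.r_squared
        assert fx.r_squared > 0.999

    def test_identical_fits_prefer_simple(self):
        res = dict(aoh0_fit=2e-5, r_squared=0.99, ssr=1e-12,
                   residuals=np.zeros(3), n_fit=2.0, n_points=100,
                   success=True, message="")
        fs = dk.FitResult(model="simple", k1=1e3, k2=None, n_params=2, **res)
        fx = dk.FitResult(model="side", k1=1e3, k2=0.0, n_params=3, **res)
        assert dk.select_model(fs, fx).chosen == "simple"


class TestScanIntegerN:
    def test_gallic_like_trace_selects_three(self, gallic_trace, assay_ctx,
                                             fit_cfg):
        scan = dk.scan_integer_n(as_conc_trace(gallic_trace), assay_ctx,
                                 range(1, 6), fit_cfg)
        assert scan.best_n == 3
        assert set(scan.r_squared_profile) == {1, 2, 3, 4, 5}

    def test_simple_trace_with_n2_selects_two(self, assay_ctx, fit_cfg):
        trace = dk.simulate_decay(
            dk.RateParameters(k1=5e3, k2=0.0, include_side=True),
            dk.InitialState(DPPH0, 2 * AOH_KNOWN),
            dk.TimeGrid.regular(300.0),
        )
        scan = dk.scan_integer_n(as_conc_trace(trace), assay_ctx,
                                 range(1, 6), fit_cfg)
        assert scan.best_n == 2

    def test_single_candidate_returned(self, gallic_trace, assay_ctx, fit_cfg):
        scan = dk.scan_integer_n(as_conc_trace(gallic_trace), assay_ctx,
                                 [3], fit_cfg)
        assert scan.best_n == 3
        assert list(scan.r_squared_profile) == [3]

    def test_empty_candidates_rejected(self, gallic_trace, assay_ctx, fit_cfg):
        with pytest.raises(ValueError):
            dk.scan_integer_n(as_conc_trace(gallic_trace), assay_ctx, [], fit_cfg)


class TestInverseRateRegression:
    # panel of (concentration uM -> M, k1 in 10^3 M^-1 s^-1 -> M^-1 s^-1)
    PANEL = [(10e-6, 5.67e3), (20e-6, 4.99e3), (50e-6, 3.37e3),
             (100e-6, 2.59e3), (200e-6, 1.37e3), (400e-6, 0.80e3),
             (800e-6, 0.44e3)]

    def test_panel_regression_r_squared(self):
        reg = dk.inverse_rate_regression(self.PANEL)
        assert round(reg.r_squared, 3) == 0.999

    def test_collinear_pairs_give_unity(self):
        pairs = [(c, 1.0 / (1e-4 + 2.0 * c)) for c in (1e-5, 2e-5, 5e-5, 1e-4)]
        reg = dk.inverse_rate_regression(pairs)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1e-4)

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            dk.inverse_rate_regression(self.PANEL[:2])

    def test_nonpositive_k1_rejected(self):
        with pytest.raises(ValueError):
            dk.inverse_rate_regression([(1e-5, 1e3), (2e-5, -1.0), (5e-5, 3e3)])


class TestExtractFit:
    def test_recovery_and_n_prime(self, fit_cfg):
        trace, truth = dk.generate_extract_trace(
            k1=0.88e3, k2=123.0, aoh0_true=33.9e-6, aoh_folin=26.7e-6,
            duration=300.0,
        )
        conc = dk.absorbance_to_concentration(trace)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 26.7 uM > 100/4 uM triggers note
            ef = dk.fit_extract(conc, 26.7e-6, fit_cfg)
        assert ef.fit.k1 == pytest.approx(0.88e3, rel=5e-3)
        assert ef.fit.k2 == pytest.approx(123.0, rel=5e-3)
        assert round_half_up(ef.n_prime, 1) == pytest.approx(1.3)

    def test_n_prime_identity(self):
        res = dk.FitResult(model="side", k1=1e3, k2=20.0, aoh0_fit=25e-6,
                           r_squared=0.999, ssr=0.0, residuals=np.zeros(2),
                           n_fit=1.0, n_points=100, n_params=3)
        ef = dk.ExtractFit(fit=res, aoh_folin=25e-6,
                           n_prime=res.aoh0_fit / 25e-6)
        assert ef.n_prime == pytest.approx(1.0)

    def test_dilution_warning(self, fit_cfg):
        trace, _ = dk.generate_extract_trace(
            k1=1e3, k2=30.0, aoh0_true=30e-6, aoh_folin=30e-6, duration=120.0,
        )
        conc = dk.absorbance_to_concentration(trace)
        with pytest.warns(UserWarning, match="1/4"):
            dk.fit_extract(conc, 30e-6, fit_cfg)
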