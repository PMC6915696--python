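"""Ratio-vs-Q calibration: family selection, inversion, propagation, trends."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyqlen import (
    CalibrationModel,
    FourPLParams,
    PolyQCalibrator,
    estimate_average_polyq,
    evaluate_four_pl,
    fit_param_trends,
    predict_curve_for_q,
    predict_fold_increase,
    propagate_ratio_sd,
    select_regression_model,
)
from polyqlen.fourpl import FourPLFitResult
from polyqlen.polyq import DegenerateDataError

QS = np.array([19, 32, 38, 48, 55, 72], dtype=float)


class TestModelSelection:
    def test_exact_linear_data_recovers_linear_family(self):
        model = select_regression_model(QS, 0.5 + 0.1 * QS)
        assert model.family == "linear"
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.a == pytest.approx(0.5)
        assert model.b == pytest.approx(0.1)

    def test_exact_power_data_recovers_power_family(self):
        model = select_regression_model(QS, 2.0 * QS**1.5)
        assert model.family == "power"
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)
        assert model.a == pytest.approx(2.0, rel=1e-6)
        assert model.b == pytest.approx(1.5, rel=1e-6)

    def test_exact_exponential_and_log_families_recovered(self):
        assert select_regression_model(QS, 0.2 * np.exp(0.03 * QS)).family == "exponential"
        assert select_regression_model(QS, -1.0 + 0.8 * np.log(QS)).family == "logarithmic"

    def test_noisy_linear_r_squared_matches_closed_form(self):
        rng = np.random.default_rng(42)
        r = 0.5 + 0.1 * QS + rng.normal(0, 0.05, QS.size)
        model = select_regression_model(QS, r)
        pred = model(QS)
        ss_res = float(np.sum((r - pred) ** 2))
        ss_tot = float(np.sum((r - r.mean()) ** 2))
        assert model.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_selected_family_is_never_materially_beaten(self):
        rng = np.random.default_rng(8)
        cal = PolyQCalibrator().fit(QS, 0.3 + 0.02 * QS + rng.normal(0, 0.02, QS.size))
        assert cal.r_squared_ >= max(cal.candidate_r_squared_.values()) - cal.tie_tol

    def test_degenerate_constant_response_rejected(self):
        with pytest.raises(DegenerateDataError):
            select_regression_model(QS, np.full(QS.size, 3.0))

    def test_too_few_distinct_q_rejected(self):
        with pytest.raises(ValueError):
            select_regression_model([20, 20, 30], [1, 1, 2])


class TestInversion:
    @pytest.fixture()
    def linear_model(self):
        return select_regression_model(QS, 0.5 + 0.1 * QS)

    def test_round_trip_identity_at_training_value(self, linear_model):
        est = estimate_average_polyq(float(linear_model(48.0)), 0.0, linear_model)
        assert est.q_mean == pytest.approx(48.0, abs=1e-9)
        assert est.q_sd == 0.0

    def test_closed_form_linear_inverse(self, linear_model):
        est = estimate_average_polyq(5.3, 0.0, linear_model)
        assert est.q_mean == pytest.approx(48.0, abs=1e-12)

    @pytest.mark.parametrize("family,rule", [
        ("linear", lambda q: 0.5 + 0.1 * q),
        ("exponential", lambda q: 0.2 * np.exp(0.03 * q)),
        ("logarithmic", lambda q: -1.0 + 0.8 * np.log(q)),
        ("power", lambda q: 0.05 * q**1.2),
    ])
    def test_round_trip_across_families(self, family, rule):
        model = select_regression_model(QS, rule(QS))
        assert model.family == family
        for q in QS:
            est = estimate_average_polyq(float(model(q)), 0.0, model)
            assert est.q_mean == pytest.approx(q, abs=1e-7)

    def test_delta_method_sd_matches_monte_carlo(self, linear_model):
        ratio, ratio_sd = 5.3, 0.12
        est = estimate_average_polyq(ratio, ratio_sd, linear_model)
        rng = np.random.default_rng(77)
        qs = (rng.normal(ratio, ratio_sd, 10**6) - linear_model.a) / linear_model.b
        assert est.q_sd == pytest.approx(float(np.std(qs, ddof=1)), rel=0.02)

    def test_mc_inversion_agrees_with_delta_method_at_small_cv(self):
        model = select_regression_model(QS, 0.2 * np.exp(0.03 * QS))
        ratio = float(model(48.0))
        delta = estimate_average_polyq(ratio, 0.02 * ratio, model)
        mc = estimate_average_polyq(ratio, 0.02 * ratio, model, mc_inversion=True,
                                    mc_draws=200_000, random_state=5)
        assert mc.q_mean == pytest.approx(delta.q_mean, rel=0.01)
        assert mc.q_sd == pytest.approx(delta.q_sd, rel=0.05)

    def test_extrapolation_flagged_not_clipped(self, linear_model):
        hi = linear_model.ratio_range[1]
        est = estimate_average_polyq(hi * 2, 0.0, linear_model)
        assert est.extrapolated
        assert est.q_mean > 72

    def test_non_invertible_ratio_raises(self):
        model = select_regression_model(QS, 0.2 * np.exp(0.03 * QS))
        with pytest.raises(ValueError):
            estimate_average_polyq(-0.5, 0.0, model)


class TestPropagation:
    def test_zero_variance(self):
        assert propagate_ratio_sd(100, 0, 50, 0) == (2.0, 0.0)

    def test_direct_substitution(self):
        r, sd = propagate_ratio_sd(100, 10, 50, 5)
        assert r == pytest.approx(2.0)
        assert sd == pytest.approx(2.0 * np.sqrt(0.02))

    def test_swap_preserves_relative_sd(self):
        r1, sd1 = propagate_ratio_sd(100, 10, 50, 5)
        r2, sd2 = propagate_ratio_sd(50, 5, 100, 10)
        assert r2 == pytest.approx(1 / r1)
        assert sd2 / r2 == pytest.approx(sd1 / r1)

    def test_zero_numerator_with_sd_undefined(self):
        with pytest.raises(ValueError):
            propagate_ratio_sd(0.0, 1.0, 10.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(10, 1000), cv_a=st.floats(0.001, 0.1),
        b=st.floats(10, 1000), cv_b=st.floats(0.001, 0.1),
    )
    def test_agrees_with_monte_carlo_within_3_se(self, a, cv_a, b, cv_b):
        """First-order propagation tracks sampling SD at relative SDs <= 10%."""
        n = 40_000
        _, sd = propagate_ratio_sd(a, cv_a * a, b, cv_b * b)
        rng = np.random.default_rng(123)
        draws = rng.normal(a, cv_a * a, n) / rng.normal(b, cv_b * b, n)
        mc_sd = float(np.std(draws, ddof=1))
        se = mc_sd / np.sqrt(2 * (n - 1))  # SE of a sample SD (normal approx)
        assert abs(sd - mc_sd) <= 3 * se + 0.05 * mc_sd


class TestFoldIncrease:
    @pytest.fixture()
    def model(self):
        return select_regression_model(QS, 0.2 * np.exp(0.099 * QS))

    def test_self_normalization(self, model):
        np.testing.assert_allclose(predict_fold_increase(model, 38, [38]), [1.0])

    def test_monotone_model_gives_monotone_folds(self, model):
        folds = predict_fold_increase(model, 38, np.arange(38, 63))
        assert np.all(np.diff(folds) > 0)

    def test_doubling_length_matches_brute_force_scan(self, model):
        """Smallest dQ with fold >= 2, by 0.1-residue scan vs closed form."""
        grid = np.arange(0, 40.0001, 0.1)
        folds = predict_fold_increase(model, 38.0, 38.0 + grid)
        scan_dq = grid[np.argmax(folds >= 2.0)]
        # closed form for an exponential rule: dq = ln2 / b = 7.0013,
        # so the scan must stop at the next 0.1-residue grid point
        exact = np.log(2) / 0.099
        assert exact == pytest.approx(7.0, abs=0.01)
        assert scan_dq == pytest.approx(np.ceil(exact / 0.1) * 0.1, abs=1e-9)

    def test_nonpositive_reference_rejected(self):
        model = CalibrationModel("linear", a=-10.0, b=0.1, r_squared=1.0,
                                 q_domain=(19, 72), ratio_range=(-8, -3))
        with pytest.raises(ValueError, match="reference"):
            predict_fold_increase(model, 38, [40])


class TestParamTrends:
    def _fits(self, qs, top_rule, ec50_rule, bottom=100.0, hill=1.0):
        out = []
        for q in qs:
            p = FourPLParams(bottom, top_rule(q), ec50_rule(q), hill)
            out.append((q, FourPLFitResult(p, np.zeros(4), 0.0, 1.0, True, 16)))
        return out

    def test_noiseless_recovery_at_training_q(self):
        qs = [19, 32, 48, 72]
        trends = fit_param_trends(self._fits(qs, lambda q: 50 * q, lambda q: 2000 - 10 * q))
        for q in qs:
            pred = predict_curve_for_q(trends, q)
            assert pred.bottom == pytest.approx(100.0)
            assert pred.hillslope == pytest.approx(1.0)
            assert pred.top == pytest.approx(50 * q, rel=1e-6)
            assert pred.ec50 == pytest.approx(2000 - 10 * q, rel=1e-6)
        assert not trends.monotone_warning

    def test_interpolated_top_is_bracketed(self):
        trends = fit_param_trends(
            self._fits([19, 38, 48, 72], lambda q: 50 * q, lambda q: 2000 - 10 * q)
        )
        top45 = predict_curve_for_q(trends, 45).top
        assert 50 * 38 < top45 < 50 * 48

    def test_predicted_curves_reproduce_training_slope_ratios(self, noiseless_config):
        """End-to-end: per-Q 4PL fits -> trends -> predicted curves -> ratios."""
        from polyqlen import fit_standard_series, simulate_standard_curves

        polyq = fit_standard_series(simulate_standard_curves(noiseless_config, "polyq"))
        total = fit_standard_series(simulate_standard_curves(noiseless_config, "total"))
        trends_p = fit_param_trends([(s.q, s.fit) for s in polyq])
        trends_t = fit_param_trends([(s.q, s.fit) for s in total])
        total_by_q = {s.q: s for s in total}
        for s in polyq:
            pred_p = predict_curve_for_q(trends_p, s.q)
            pred_t = predict_curve_for_q(trends_t, s.q)
            # first-order linear-range slope of the predicted curves (Hill = 1)
            pred_ratio = ((pred_p.top - pred_p.bottom) / pred_p.ec50) / (
                (pred_t.top - pred_t.bottom) / pred_t.ec50
            )
            training_ratio = s.slope.slope / total_by_q[s.q].slope.slope
            assert pred_ratio == pytest.approx(training_ratio, rel=0.01)

    def test_requires_three_converged_fits(self):
        fits = self._fits([19, 32], lambda q: 50 * q, lambda q: 2000 - 10 * q)
        with pytest.raises(ValueError):
            fit_param_trends(fits)


def test_calibration_yaml_round_trip(tmp_path):
    model = select_regression_model(QS, 0.5 + 0.1 * QS)
    path = tmp_path / "cal.yaml"
    path.write_text(model.to_yaml())
    back = CalibrationModel.from_yaml(path.read_text())
    assert back == model


def test_analytic_mixture_identity(noiseless_config):
    """Linear calibration + linear-range additivity => the mixture ratio equals
    the ratio at the fraction-weighted mean Q, so the estimate is exact."""
    from polyqlen import MixtureSpec, simulate_mixture_signals, true_signal_ratio

    cfg = noiseless_config
    mix = MixtureSpec(
        components=[(25, 0.18), (38, 0.21), (48, 0.21), (55, 0.20), (72, 0.20)],
        total_concentration=100.0, label="avgQ48-style",
    )
    qbar = sum(q * f for q, f in mix.components)
    assert true_signal_ratio(mix, cfg) == pytest.approx(true_signal_ratio(qbar, cfg), abs=1e-12)

    sp = simulate_mixture_signals(mix, cfg, "polyq")
    st_ = simulate_mixture_signals(mix, cfg, "total")
    ratio = (sp.signals.mean() - cfg.bottom) / (st_.signals.mean() - cfg.bottom)

    model = select_regression_model(QS, np.array([true_signal_ratio(q, cfg) for q in QS]))
    assert model.family == "linear"
    est = estimate_average_polyq(ratio, 0.0, model)
    assert est.q_mean == pytest.approx(qbar, abs=1e-9)
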