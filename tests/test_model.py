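"""Growth-curve fitting: recovery, degenerate-ridge bounds, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorgrowth import (
    GrowthCurveModel,
    InsufficientDataError,
    VolumeSeries,
    fit_growth_law,
    goodness_of_fit,
    two_point_solve,
)
from tumorgrowth.laws import GrowthLawParams, composite_rate

from conftest import make_gompertz_series

HYP = settings(derandomize=True, max_examples=40, deadline=None)


class TestTwoPointSolve:
    def test_untreated_l3_interpolation(self):
        # frozen closed-form values: x = ln1.9/ln1.6 - 1, k = -ln(x)/15,
        # ln Vinf = ln1.6/(1-x)
        p = two_point_solve(1.6, 1.9, 15.0)
        assert p.rate == pytest.approx(0.0670744612, rel=1e-8)
        assert p.Vinf == pytest.approx(2.0978338, rel=1e-7)
        # interpolates both points exactly
        assert float(p.volume(15.0)) == pytest.approx(1.6, rel=1e-12)
        assert float(p.volume(30.0)) == pytest.approx(1.9, rel=1e-12)

    @pytest.mark.parametrize("r1,r2", [(1.2, 1.81), (1.32, 2.02)])
    def test_superexponential_growth_has_no_solution(self, r1, r2):
        # ln r2 / ln r1 > 2: no Gompertz through the points with V0 = 1
        assert math.log(r2) / math.log(r1) > 2
        assert two_point_solve(r1, r2, 15.0) is None

    def test_flat_first_ratio_has_no_solution(self):
        assert two_point_solve(1.0, 1.5, 15.0) is None

    def test_saturated_limit_recovers_vinf(self):
        p_true = GrowthLawParams("gompertz", 1.0, 2.5, 0.1)
        t1 = 230.0  # k*t1 >> 1: both ratios ~ Vinf
        r1, r2 = float(p_true.volume(t1)), float(p_true.volume(2 * t1))
        p = two_point_solve(r1, r2, t1)
        assert p is not None and p.Vinf == pytest.approx(2.5, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        from tumorgrowth import DomainError
        with pytest.raises(DomainError):
            two_point_solve(-1.0, 1.5, 15.0)
        with pytest.raises(DomainError):
            two_point_solve(1.5, 1.9, 0.0)


class TestFitRecovery:
    def test_exact_recovery_zero_noise(self):
        series, p = make_gompertz_series(vinf_ratio=0.3, k=0.03)
        res = GrowthCurveModel(series).fit()
        assert res.status == "point_estimate"
        assert res.params.Vinf == pytest.approx(0.3, rel=1e-6)
        assert res.params.rate == pytest.approx(0.03, rel=1e-6)
        assert res.sse < 1e-12

    def test_exact_recovery_logistic(self):
        series, p = make_gompertz_series(vinf_ratio=0.3, k=0.06, law="logistic")
        res = GrowthCurveModel(series, law="logistic").fit()
        assert res.params.Vinf == pytest.approx(0.3, rel=1e-5)
        assert res.params.rate == pytest.approx(0.06, rel=1e-5)

    def test_untreated_l3_fit_matches_reported(self, l3_nt_series):
        res = GrowthCurveModel(l3_nt_series).fit()
        assert res.status == "point_estimate"
        # reported values 2.06 and 0.07 carry ~10% uncertainty
        assert res.params.Vinf == pytest.approx(2.06, rel=0.10)
        assert res.params.rate == pytest.approx(0.07, rel=0.10)

    def test_pure_exponential_is_bound_with_composite_from_slope(self):
        t = np.arange(0.0, 31.0, 1.5)
        series = VolumeSeries("exp", t, np.exp(-0.1 * t))
        res = GrowthCurveModel(series).fit()
        assert res.status == "bound"
        # independent oracle: log-linear regression slope of the same series
        slope = abs(np.polyfit(t, np.log(series.volumes), 1)[0])
        assert res.composite_rate == pytest.approx(slope, rel=1e-9)
        assert res.composite_rate == pytest.approx(0.1, rel=1e-9)
        assert res.bound_info.vinf_ratio_bound[0] == "<"

    def test_bound_correctness_objective_flat_below_limit(self):
        t = np.arange(0.0, 31.0, 1.5)
        series = VolumeSeries("exp", t, np.exp(-0.1 * t))
        model = GrowthCurveModel(series)
        res = model.fit()
        direction, c = res.bound_info.vinf_ratio_bound
        assert direction == "<"
        # pinning Vinf/V0 anywhere below the limit changes the objective by
        # less than the flatness threshold
        b_vals = np.linspace(math.log(c), -16.0, 20)
        sse, _ = model.profile(b_vals)
        assert np.all(sse <= res.profile_sse.min() * (1 + res.flatness) + 1e-10)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_growth_law(VolumeSeries("x", [0.0, 15.0], [1.0, 1.6]))

    def test_growth_side_degeneracy_reports_bound(self):
        # superexponential growth (no interpolating Gompertz): status bound,
        # with a one-sided lower limit on Vinf/V0
        series = VolumeSeries("L4-NT", [0.0, 15.0, 30.0], [1.0, 1.2, 1.81])
        res = GrowthCurveModel(series).fit()
        assert res.status == "bound"
        assert res.bound_info.vinf_ratio_bound[0] == ">"
        slope = float(np.dot(series.times, np.log(series.volumes)) / np.dot(series.times, series.times))
        assert res.composite_rate == pytest.approx(slope, rel=1e-9)

    @HYP
    @given(
        ratio=st.floats(0.05, 0.9),
        k=st.floats(0.01, 0.3),
        t1=st.floats(5.0, 30.0),
    )
    def test_oracle_equivalence_on_exact_three_point_series(self, ratio, k, t1):
        # on an exactly Gompertzian 3-point series the least-squares fit
        # attains the closed-form interpolation (objective ~ 0)
        p = GrowthLawParams("gompertz", 1.0, ratio, k)
        series = VolumeSeries("h", [0.0, t1, 2 * t1],
                              [1.0, float(p.volume(t1)), float(p.volume(2 * t1))])
        oracle = two_point_solve(series.volumes[1], series.volumes[2], t1)
        res = GrowthCurveModel(series).fit()
        assert res.sse <= 1e-8
        if oracle is not None and res.status == "point_estimate":
            assert res.params.rate == pytest.approx(oracle.rate, rel=1e-4)

    def test_parameter_recovery_smoke_cohort(self):
        # reduced version of the recovery study run by the acceptance suite
        errs = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            ratio = math.exp(rng.uniform(math.log(0.2), math.log(0.65)))
            k = rng.uniform(0.03, 0.11)
            series, p = make_gompertz_series(
                vinf_ratio=ratio, k=k, v0=80.0, times=np.linspace(0, 28, 23),
                noise_rel=0.05, seed=2000 + seed)
            res = GrowthCurveModel(series, fix_v0=False).fit()
            c = composite_rate(p)
            errs.append(abs(res.composite_rate - c) / c)
        assert np.median(errs) < 0.15


class TestGoodnessOfFit:
    def test_perfect_fit_is_zero(self, l3_nt_series):
        res = GrowthCurveModel(l3_nt_series).fit()
        assert res.chi2_per_dof == pytest.approx(0.0, abs=1e-12)

    def test_single_sigma_deviation_is_unity(self):
        p = GrowthLawParams("gompertz", 1.0, 2.0, 0.1)
        t = np.array([0.0, 10.0, 20.0, 30.0])
        v = np.asarray(p.volume(t))
        v[2] = v[2] / (1.0 - 0.10)  # off by exactly sigma_rel * V_obs
        series = VolumeSeries("x", t, v)
        # n=4, p=2 -> dof=2; one 1-sigma deviation -> chi2/dof = 1/2
        assert goodness_of_fit(series, p, sigma_rel=0.10) == pytest.approx(0.5, rel=1e-9)

    def test_chi2_calibrated_on_matching_noise(self):
        series, p = make_gompertz_series(vinf_ratio=0.3, k=0.05, v0=1.0,
                                         times=np.linspace(0, 60, 102),
                                         noise_rel=0.10, seed=7)
        assert goodness_of_fit(series, p, sigma_rel=0.10) == pytest.approx(1.0, abs=0.3)

    def test_undefined_dof(self):
        p = GrowthLawParams("gompertz", 1.0, 2.0, 0.1)
        series = VolumeSeries("x", [0.0, 10.0], [1.0, 1.3])
        with pytest.raises(InsufficientDataError):
            goodness_of_fit(series, p)


class TestResultsAPI:
    def test_summary_and_record(self, l3_nt_series):
        res = GrowthCurveModel(l3_nt_series).fit()
        text = res.summary()
        assert "Vinf/V0" in text and "composite rate" in text
        rec = res.to_record()
        assert rec["status"] == "point_estimate"
        assert rec["subject_id"] == "L3-NT"

    def test_predict_matches_observations_for_exact_fit(self):
        series, p = make_gompertz_series(vinf_ratio=0.4, k=0.08)
        res = GrowthCurveModel(series).fit()
        assert np.allclose(res.predict(series.times), series.volumes, rtol=1e-6)
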