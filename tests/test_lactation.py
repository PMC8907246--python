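"""Lactation-curve and mixed-model checks: closed-form curve values,
noiseless parameter recovery, residual conservation, 305-day totals and
rumination worked examples from the published coefficient tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from herdspace import published
from herdspace.errors import DomainError, FitError
from herdspace.lactation import (GroupDimFixedEffects, MilkBotParams,
                                 add_rolling_volume,
                                 compute_lactation_residuals, fit_milkbot,
                                 fit_group_by_dim_mixed_model,
                                 intraclass_correlation, milkbot_predict,
                                 predict_305d_yield, predict_mean_rumination)

PUBLISHED_PARAMS = published.MILKBOT_FIT


def _noiseless_milk(params, n_cows=3, dims=None):
    dims = np.arange(1, 306) if dims is None else dims
    frames = [pd.DataFrame({"cow_lactation_id": f"c{i}", "dim": dims,
                            "volume_l": milkbot_predict(params, dims)})
              for i in range(n_cows)]
    return pd.concat(frames, ignore_index=True)


class TestMilkBotCurve:
    def test_half_scale_at_offset_with_zero_decay(self):
        p = MilkBotParams(60.0, 30.0, 17.0, 0.0)
        assert milkbot_predict(p, 17) == pytest.approx(30.0)

    @pytest.mark.parametrize("dim,expected", [(100, 49.5697), (1, 34.9019)])
    def test_published_parameter_evaluations(self, dim, expected):
        # frozen from direct evaluation of the curve formula
        assert milkbot_predict(PUBLISHED_PARAMS, dim) == pytest.approx(
            expected, abs=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            MilkBotParams(60.0, 0.0, 0.0, 0.001)
        with pytest.raises(DomainError):
            MilkBotParams(-1.0, 30.0, 0.0, 0.001)

    @given(st.floats(5.0, 300.0))
    def test_nondecreasing_in_dim_without_decay(self, dim):
        p = MilkBotParams(55.0, 25.0, 2.0, 0.0)
        assert milkbot_predict(p, dim + 1.0) >= milkbot_predict(p, dim)


class TestFitMilkbot:
    @pytest.mark.parametrize("truth", [
        (55.0, 28.0, -3.0, 0.002),
        (60.19, 30.2, -4.33, 0.001782),
        (45.0, 20.0, 2.0, 0.003),
        (70.0, 35.0, -8.0, 0.001),
        (50.0, 25.0, 0.5, 0.0025),
    ])
    def test_noiseless_recovery(self, truth):
        params = MilkBotParams(*truth)
        milk = _noiseless_milk(params)
        fit = fit_milkbot(milk, source="daily")
        np.testing.assert_allclose(fit.params.as_array(), params.as_array(),
                                   rtol=1e-6)

    def test_flat_curve_limit(self):
        params = MilkBotParams(40.0, 10.0, -200.0, 0.0)
        milk = _noiseless_milk(params)
        fit = fit_milkbot(milk, source="daily")
        assert fit.params.scale == pytest.approx(40.0, rel=1e-4)

    def test_too_few_dim_values(self):
        milk = pd.DataFrame({"cow_lactation_id": "c", "dim": [1, 2, 3],
                             "volume_l": [30.0, 31.0, 32.0]})
        with pytest.raises(FitError):
            fit_milkbot(milk, source="daily")

    def test_noisy_recovery_within_2se(self):
        rng = np.random.default_rng(0)
        dims = np.tile(np.arange(1, 306), 40)
        vol = milkbot_predict(PUBLISHED_PARAMS, dims) + rng.normal(0, 4, dims.size)
        milk = pd.DataFrame({"cow_lactation_id": np.repeat(np.arange(40), 305),
                             "dim": dims, "volume_l": vol})
        fit = fit_milkbot(milk, source="daily")
        err = np.abs(fit.params.as_array() - PUBLISHED_PARAMS.as_array())
        assert (err <= 2 * fit.se).all()


class TestResiduals:
    def test_exact_and_shifted(self):
        milk = _noiseless_milk(PUBLISHED_PARAMS, n_cows=1)
        res = compute_lactation_residuals(milk, PUBLISHED_PARAMS)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)
        milk2 = milk.assign(volume_l=milk["volume_l"] + 5.0)
        np.testing.assert_allclose(
            compute_lactation_residuals(milk2, PUBLISHED_PARAMS), 5.0)

    def test_published_point_residual(self):
        milk = pd.DataFrame({"cow_lactation_id": "c", "dim": [100],
                             "volume_l": [50.0]})
        res = compute_lactation_residuals(milk, PUBLISHED_PARAMS)
        assert res.iloc[0] == pytest.approx(50.0 - 49.5697, abs=1e-3)

    def test_conservation_reconstructs_observed(self):
        rng = np.random.default_rng(1)
        milk = _noiseless_milk(PUBLISHED_PARAMS, n_cows=2)
        milk["volume_l"] += rng.normal(0, 3, len(milk))
        res = compute_lactation_residuals(milk, PUBLISHED_PARAMS)
        recon = res + milkbot_predict(PUBLISHED_PARAMS, milk["dim"].to_numpy())
        np.testing.assert_allclose(recon, milk["volume_l"], rtol=1e-12)

    def test_rolling_window_requires_min_days(self):
        milk = _noiseless_milk(PUBLISHED_PARAMS, n_cows=1)
        rolled = add_rolling_volume(milk)
        assert rolled["rolling7_l"].isna().sum() == 3   # dims 1-3 lack 4 days
        # trailing mean at dim 10 is the mean of dims 4..10
        expected = milk.loc[milk["dim"].between(4, 10), "volume_l"].mean()
        assert rolled.loc[rolled["dim"] == 10, "rolling7_l"].iloc[0] == \
            pytest.approx(expected)


def _simulate_residual_data(rng, n_cows=60, n_days=120, fixed=None,
                            cow_var=64.23, res_var=16.37):
    fixed = fixed or GroupDimFixedEffects(intercept=0.0, dim_slope=0.0)
    groups = np.tile(["primiparous-control", "primiparous-high",
                      "multiparous-control", "multiparous-high"],
                     n_cows // 4 + 1)[:n_cows]
    frames = []
    for i in range(n_cows):
        dims = np.arange(1, n_days + 1)
        y = (fixed.predict(groups[i], dims) + rng.normal(0, np.sqrt(cow_var))
             + rng.normal(0, np.sqrt(res_var), dims.size))
        frames.append(pd.DataFrame({
            "cow_lactation_id": f"c{i}", "parity_group": groups[i],
            "dim": dims, "milk_residual": y}))
    return pd.concat(frames, ignore_index=True)


class TestGroupDimMixedModel:
    def test_null_group_effects_within_2se(self):
        data = _simulate_residual_data(np.random.default_rng(2))
        fit = fit_group_by_dim_mixed_model(data, outcome="milk_residual")
        for term in fit.table.index:
            if term.startswith("group"):
                est = fit.table.loc[term, "estimate"]
                se = fit.table.loc[term, "se"]
                assert abs(est) <= 2.5 * se

    def test_known_offset_and_interaction_recovery(self):
        fixed = GroupDimFixedEffects(
            intercept=-10.0, dim_slope=0.03,
            group_offsets={"multiparous-high": 16.0},
            group_dim_interactions={"multiparous-high": -0.04})
        data = _simulate_residual_data(np.random.default_rng(3), n_cows=80,
                                       fixed=fixed)
        fit = fit_group_by_dim_mixed_model(data, outcome="milk_residual")
        t = fit.table
        assert abs(t.loc["group[multiparous-high]", "estimate"] - 16.0) <= \
            2 * t.loc["group[multiparous-high]", "se"]
        assert abs(t.loc["group[multiparous-high]:dim", "estimate"] + 0.04) \
            <= 2 * t.loc["group[multiparous-high]:dim", "se"]

    def test_icc_recovered(self):
        data = _simulate_residual_data(np.random.default_rng(4), n_cows=150)
        fit = fit_group_by_dim_mixed_model(data, outcome="milk_residual")
        assert fit.icc == pytest.approx(0.797, abs=0.03)


class TestPredict305d:
    def test_zero_coefficients_reduce_to_curve_sum(self):
        fe = GroupDimFixedEffects(intercept=0.0, dim_slope=0.0)
        total = predict_305d_yield(PUBLISHED_PARAMS, fe, "primiparous-control")
        oracle = sum(milkbot_predict(PUBLISHED_PARAMS, d) for d in range(1, 306))
        assert total == pytest.approx(oracle, rel=1e-12)

    def test_constant_shift(self):
        fe = GroupDimFixedEffects(intercept=-10.0, dim_slope=0.0)
        base = GroupDimFixedEffects(intercept=0.0, dim_slope=0.0)
        delta = (predict_305d_yield(PUBLISHED_PARAMS, base, "primiparous-control")
                 - predict_305d_yield(PUBLISHED_PARAMS, fe, "primiparous-control"))
        assert delta == pytest.approx(3050.0, rel=1e-12)

    def test_published_coefficients_within_band(self):
        """Printed-table coefficients reproduce the published 305-day totals
        to within 2% (printed rounding propagates through the DIM slope)."""
        fe = published.MILK_RESIDUAL_FIXED_EFFECTS
        expected = {"primiparous-control": 11592.0,
                    "multiparous-high": 14746.0,
                    "multiparous-control": 14644.0}
        for group, target in expected.items():
            total = predict_305d_yield(PUBLISHED_PARAMS, fe, group)
            assert total == pytest.approx(target, rel=0.02)


class TestRumination:
    def test_published_first100_means(self):
        fe = published.RUMINATION_FIXED_EFFECTS
        assert round(predict_mean_rumination(fe, "primiparous-high",
                                             (1, 100))) == 469
        assert round(predict_mean_rumination(fe, "multiparous-high",
                                             (1, 100))) == 485

    def test_published_305d_means(self):
        fe = published.RUMINATION_FIXED_EFFECTS
        assert predict_mean_rumination(fe, "multiparous-high", (1, 305)) == \
            pytest.approx(462, abs=2)
        assert predict_mean_rumination(fe, "multiparous-control", (1, 305)) \
            == pytest.approx(444, abs=2)

    def test_single_day_range_identity(self):
        fe = published.RUMINATION_FIXED_EFFECTS
        d = 37
        expected = (fe.intercept + fe.group_offsets["multiparous-high"]
                    + (fe.dim_slope
                       + fe.group_dim_interactions["multiparous-high"]) * d)
        assert predict_mean_rumination(fe, "multiparous-high", (d, d)) == \
            pytest.approx(expected, rel=1e-12)

    def test_empty_range_rejected(self):
        with pytest.raises(DomainError):
            predict_mean_rumination(published.RUMINATION_FIXED_EFFECTS,
                                    "primiparous-high", (10, 9))


class TestICC:
    def test_published_variance_components(self):
        assert intraclass_correlation(64.23, 16.37) == pytest.approx(
            0.80, abs=0.005)
        assert intraclass_correlation(0.33, 0.26) == pytest.approx(
            0.56, abs=0.005)

    def test_negative_variance_rejected(self):
        with pytest.raises(DomainError):
            intraclass_correlation(-1.0, 1.0)
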