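"""Survival analysis, inter-service intervals, progesterone rules,
contingency tests and metabolite flags, each checked against hand or
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from herdspace.errors import (ClassificationError, DegenerateTableError,
                              DomainError, FitError)
from herdspace.reproduction import (build_tte_dataset, categorize_isi,
                                    classify_p4_profile, contingency_chisq,
                                    detect_cla, fit_cox_ph,
                                    flag_metabolite_panel,
                                    inter_service_intervals, km_estimate,
                                    metabolite_exclusion_pairs)
from herdspace.simulate import simulate_tte_exponential

from conftest import make_roster


def km_oracle(times, events):
    """Brute-force product-limit estimator on a small sample."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    curve = {}
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        curve[t] = s
    return curve


class TestTTEDataset:
    def _conceptions(self, roster, mapping):
        return pd.DataFrame({
            "cow_lactation_id": roster["cow_lactation_id"],
            "conception_dim": [mapping.get(c, np.nan)
                               for c in roster["cow_lactation_id"]],
        })

    def test_event_and_censoring_times(self):
        roster, _ = make_roster(n_pairs=2, seed=20,
                                pregnant_pair_fraction=0.0)
        cow = roster["cow_lactation_id"].iloc[0]
        tte = build_tte_dataset(roster, self._conceptions(roster,
                                                          {cow: 120.0}))
        rec = tte.set_index("cow_lactation_id").loc[cow]
        assert (rec["time"], rec["event"]) == (120.0, 1)
        open_cow = tte[tte["event"] == 0].iloc[0]
        ros = roster.set_index("cow_lactation_id").loc[
            open_cow["cow_lactation_id"]]
        assert open_cow["time"] == ros["entry_dim"] + ros["exit_day"]

    def test_pregnant_pair_excluded_whole(self):
        roster, _ = make_roster(n_pairs=6, seed=21,
                                pregnant_pair_fraction=1.0)
        tte = build_tte_dataset(roster, self._conceptions(roster, {}))
        assert tte.empty


class TestKaplanMeier:
    def test_three_event_median(self, tiny_tte):
        km = km_estimate(tiny_tte)
        assert km.median("control") == 2.0

    def test_all_censored_median_not_reached(self, tiny_tte):
        tte = tiny_tte.assign(event=0)
        with pytest.warns(UserWarning, match="no events"):
            km = km_estimate(tte)
        assert np.isinf(km.median("control"))
        assert (km.curves["control"].to_numpy() == 1.0).all()

    def test_matches_bruteforce_product_limit(self):
        rng = np.random.default_rng(22)
        times = rng.integers(1, 30, 10).astype(float)
        events = rng.integers(0, 2, 10)
        events[0] = 1
        tte = pd.DataFrame({"cow_lactation_id": [f"c{i}" for i in range(10)],
                            "group": "g", "parity_group": "g",
                            "time": times, "event": events})
        km = km_estimate(tte)
        oracle = km_oracle(times, events)
        curve = km.curves["g"]["g"]
        for t, s in oracle.items():
            assert curve.loc[t] == pytest.approx(s, rel=1e-12)

    def test_exponential_median_closed_form(self):
        lam = 1 / 100.0
        rng = np.random.default_rng(23)
        t = rng.exponential(1 / lam, 4000)
        tte = pd.DataFrame({"cow_lactation_id": np.arange(t.size),
                            "group": "g", "parity_group": "g", "time": t,
                            "event": 1})
        km = km_estimate(tte)
        assert km.median("g") == pytest.approx(np.log(2) / lam, rel=0.06)

    def test_risk_table_counts(self, tiny_tte):
        km = km_estimate(tiny_tte, risk_times=(0, 2))
        assert km.risk_table.loc["control"].tolist() == [3, 2]


class TestCox:
    def test_identical_groups_hr_near_one(self):
        rng = np.random.default_rng(24)
        n = 200
        tte = pd.DataFrame({
            "cow_lactation_id": np.arange(2 * n),
            "group": ["high"] * n + ["control"] * n,
            "parity_group": ["primiparous-high"] * n
            + ["primiparous-control"] * n,
            "time": rng.exponential(100, 2 * n),
            "event": 1})
        fit = fit_cox_ph(tte)
        row = fit.table.loc["primiparous-high"]
        assert row["hr_ci_low"] <= 1.0 <= row["hr_ci_high"]

    def test_single_arm_rejected(self, tiny_tte):
        with pytest.raises(FitError):
            fit_cox_ph(tiny_tte)

    def test_hazard_ratio_recovery(self):
        tte = simulate_tte_exponential(500, 0.58, 1 / 100.0, 300.0,
                                       np.random.default_rng(25))
        tte["parity_group"] = np.where(tte["group"] == "high",
                                       "primiparous-high",
                                       "primiparous-control")
        tte["cow_lactation_id"] = np.arange(len(tte))
        fit = fit_cox_ph(tte)
        row = fit.table.loc["primiparous-high"]
        assert abs(row["coef"] - np.log(0.58)) <= 2 * row["se"]
        assert not fit.ph_test.empty

    def test_sign_agrees_with_median_difference(self):
        tte = simulate_tte_exponential(300, 0.5, 1 / 80.0, 1e9,
                                       np.random.default_rng(26))
        tte["parity_group"] = np.where(tte["group"] == "high",
                                       "primiparous-high",
                                       "primiparous-control")
        tte["cow_lactation_id"] = np.arange(len(tte))
        fit = fit_cox_ph(tte)
        med = tte.groupby("group")["time"].median()
        assert (fit.table.loc["primiparous-high", "coef"] < 0) == \
            (med["high"] > med["control"])


class TestISI:
    @pytest.mark.parametrize("days,block", [
        (1, "1-17"), (17, "1-17"), (18, "18-26"), (21, "18-26"),
        (26, "18-26"), (27, "27-35"), (35, "27-35"), (36, "36-52"),
        (52, "36-52"), (53, "52+"), (60, "52+"), (1000, "52+")])
    def test_blocks(self, days, block):
        assert categorize_isi(days) == block

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            categorize_isi(0)

    @given(st.integers(1, 1000))
    def test_partition(self, days):
        blocks = [b for b in ("1-17", "18-26", "27-35", "36-52", "52+")
                  if categorize_isi(days) == b]
        assert len(blocks) == 1

    def test_intervals_from_services(self):
        services = pd.DataFrame({
            "cow_lactation_id": ["a", "a", "a", "b"],
            "dim": [60, 81, 140, 70], "group": "high"})
        isi = inter_service_intervals(services)
        assert isi["interval_days"].tolist() == [21, 59]
        assert isi["block"].tolist() == ["18-26", "52+"]


class TestP4Profile:
    def test_dov_first_rise_after_45(self):
        dims = [48, 52, 55]
        assert classify_p4_profile(dims, [1.0, 4.0, 8.0])[0] == "DOV"

    def test_normal_cyclicity(self):
        # rise at 28, luteal runs of ~13 d separated by ~5 d lows
        dims = np.array([14, 17, 21, 24, 28, 31, 35, 38, 42, 45, 49, 52, 56,
                         59, 63, 66, 70, 73, 77, 80, 84])
        lut = lambda d: ((28 <= d <= 41) or (47 <= d <= 60) or
                         (66 <= d <= 79))
        p4 = [9.0 if lut(d) else 1.0 for d in dims]
        assert classify_p4_profile(dims, p4) == ("Normal", None)

    def test_cessation_after_rise(self):
        dims = np.array([20, 23, 27, 30, 34, 37, 41, 44, 48, 51, 55])
        p4 = [1, 1, 6, 7, 6, 1, 1, 1, 1, 1, 1]     # 16+ d low after rise
        cls, sub = classify_p4_profile(dims, p4)
        assert (cls, sub) == ("Abnormal", "cessation")

    def test_prolonged_luteal_requires_no_ai(self):
        dims = np.arange(20, 60, 3)
        p4 = [8.0] * dims.size
        assert classify_p4_profile(dims, p4) == ("Abnormal",
                                                 "prolonged_luteal")
        # an AI inside the run makes it legitimate
        assert classify_p4_profile(dims, p4, ai_dims=[35])[0] != "Abnormal"

    def test_short_luteal_second_cycle(self):
        dims = np.array([14, 18, 21, 25, 28, 32, 35, 39, 42, 46, 49, 53, 56,
                         60, 63, 67, 70, 74, 77, 81, 84])
        lut = lambda d: (18 <= d <= 32) or (39 <= d <= 44) or (53 <= d <= 70)
        p4 = [9.0 if lut(d) else 1.0 for d in dims]
        cls, sub = classify_p4_profile(dims, p4)
        assert (cls, sub) == ("Abnormal", "short_luteal")

    def test_first_cycle_short_phase_is_typical(self):
        dims = np.array([14, 18, 21, 25, 28, 32, 35, 39, 42, 46, 49, 53, 56,
                         60, 63, 67, 70, 74, 77, 81, 84])
        lut = lambda d: (18 <= d <= 24) or (32 <= d <= 46) or (53 <= d <= 70)
        p4 = [9.0 if lut(d) else 1.0 for d in dims]
        assert classify_p4_profile(dims, p4) == ("Normal", None)

    def test_empty_series_rejected(self):
        with pytest.raises(ClassificationError):
            classify_p4_profile([], [])


class TestCLA:
    def test_consecutive_pair_rule(self):
        assert detect_cla([20, 23, 25], [2.0, 6.0, 7.0]) == (23.0, False)

    def test_isolated_value_censored(self):
        assert detect_cla([20, 23, 25], [2.0, 6.0, 2.0]) == (84.0, True)

    def test_appending_samples_never_changes_found_cla(self):
        rng = np.random.default_rng(27)
        for _ in range(200):
            n = rng.integers(3, 20)
            dims = np.sort(rng.choice(np.arange(14, 85), n, replace=False))
            p4 = rng.uniform(0, 12, n)
            day, censored = detect_cla(dims, p4)
            if censored:
                continue
            extra_dims = np.concatenate([dims, dims[-1] + rng.integers(
                1, 5, 3).cumsum()])
            extra_p4 = np.concatenate([p4, rng.uniform(0, 12, 3)])
            assert detect_cla(extra_dims, extra_p4)[0] == day

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(28)
        for _ in range(1000):
            n = rng.integers(2, 25)
            dims = np.sort(rng.choice(np.arange(14, 85), n, replace=False))
            p4 = rng.uniform(0, 10, n)
            hits = [dims[i] for i in range(n - 1)
                    if p4[i] > 5 and p4[i + 1] > 5]
            expected = (float(hits[0]), False) if hits else (84.0, True)
            assert detect_cla(dims, p4) == expected


class TestContingency:
    def test_service_outcome_table(self):
        stat, df, p = contingency_chisq([[29, 91], [37, 62]])
        assert df == 1
        assert stat == pytest.approx(3.89, abs=0.01)
        assert round(p, 3) == 0.049

    def test_profile_table(self):
        stat, df, p = contingency_chisq([[8, 12, 19], [11, 11, 17]])
        assert df == 2
        assert stat == pytest.approx(0.63, abs=0.01)
        assert round(p, 2) == 0.73

    def test_uniform_table(self):
        stat, df, p = contingency_chisq([[10, 10], [10, 10]],
                                        correction=False)
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            contingency_chisq([[0, 0], [5, 3]])


class TestMetaboliteFlags:
    @pytest.mark.parametrize("bhb,nefa,b_high,n_high", [
        (1.2, 0.5, True, False),     # inclusive BHB threshold
        (1.19, 0.8, False, True),    # inclusive NEFA threshold
        (0.0, 0.79, False, False)])
    def test_thresholds(self, bhb, nefa, b_high, n_high):
        panel = pd.DataFrame({"cow_lactation_id": ["x"], "window": [1],
                              "bhb_mmol_l": [bhb], "nefa_mmol_l": [nefa]})
        out = flag_metabolite_panel(panel)
        assert bool(out["bhb_high"].iloc[0]) is b_high
        assert bool(out["nefa_high"].iloc[0]) is n_high

    def test_negative_rejected(self):
        panel = pd.DataFrame({"cow_lactation_id": ["x"], "window": [1],
                              "bhb_mmol_l": [-0.1], "nefa_mmol_l": [0.2]})
        with pytest.raises(DomainError):
            flag_metabolite_panel(panel)

    def test_exclusion_pairs(self):
        roster, _ = make_roster(n_pairs=3, seed=29)
        flagged = pd.DataFrame({
            "cow_lactation_id": roster["cow_lactation_id"],
            "bhb_high": [True] + [False] * 5,
            "nefa_high": [False] * 6})
        pairs = metabolite_exclusion_pairs(flagged, roster)
        assert pairs == {roster["pair_id"].iloc[0]}
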