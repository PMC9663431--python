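"""Selectivity screen: ANOVA oracle, interval criterion, tuning, contrasts."""

import itertools

import numpy as np
import pytest

from numprod import (
    AnovaTimecourse,
    BehaviorParams,
    PopulationSpec,
    UnitParams,
    detect_selective_interval,
    generate_session,
    include_unit,
    population_tuning,
    sliding_anova,
    tuning_and_normalize,
    analyze_session,
    error_trial_contrast,
)
from numprod._anova import TwoWayAnova
from conftest import make_session, make_trial


# ----------------------------------------------------------------------
# ANOVA oracle

# 2 numbers x 2 protocols x 3 trials, sums of squares worked by hand with
# exact fractions: SS_num = 147/4, SS_prot = SS_int = 3/4, SS_err = 20,
# SS_tot = 233/4, MS_err = 5/2.
TOY_RATES = np.array([2, 3, 4, 3, 4, 5, 6, 7, 8, 5, 6, 10], dtype=float)
TOY_NUMBERS = np.array([1] * 6 + [2] * 6)
TOY_PROTOCOLS = np.array(["dot"] * 3 + ["sign"] * 3 + ["dot"] * 3 + ["sign"] * 3)


def _balanced_twoway_oracle(y, a, b):
    """Textbook balanced two-way decomposition via explicit cell means."""
    a_lv, b_lv = np.unique(a), np.unique(b)
    grand = y.mean()
    r = y.size // (a_lv.size * b_lv.size)
    ss_a = sum(b_lv.size * r * (y[a == ai].mean() - grand) ** 2 for ai in a_lv)
    ss_b = sum(a_lv.size * r * (y[b == bi].mean() - grand) ** 2 for bi in b_lv)
    ss_cells = sum(
        r * (y[(a == ai) & (b == bi)].mean() - grand) ** 2
        for ai in a_lv
        for bi in b_lv
    )
    ss_tot = ((y - grand) ** 2).sum()
    return {
        "a": ss_a,
        "b": ss_b,
        "ab": ss_cells - ss_a - ss_b,
        "error": ss_tot - ss_cells,
        "total": ss_tot,
    }


class TestTwoWayAnova:
    def test_matches_hand_computed_table(self):
        model = TwoWayAnova(TOY_NUMBERS, TOY_PROTOCOLS)
        ss = model.sums_of_squares(TOY_RATES)
        assert abs(ss["a"] - 147 / 4) < 1e-10
        assert abs(ss["b"] - 3 / 4) < 1e-10
        assert abs(ss["ab"] - 3 / 4) < 1e-10
        assert abs(ss["error"] - 20.0) < 1e-10
        res = model.anova(TOY_RATES)
        assert abs(res["a"]["F"] - 14.7) < 1e-10
        assert abs(res["a"]["p"] - 0.004989085602820781) < 1e-10
        assert abs(res["b"]["p"] - 0.598827136697289) < 1e-10

    def test_matches_cell_mean_oracle_on_random_balanced_tables(self):
        rng = np.random.default_rng(7)
        a = np.repeat([1, 2, 3, 4, 5], 8)
        b = np.tile(np.repeat(["dot", "sign"], 4), 5)
        model = TwoWayAnova(a, b)
        for _ in range(5):
            y = rng.gamma(2.0, 3.0, size=a.size)
            ss = model.sums_of_squares(y)
            oracle = _balanced_twoway_oracle(y, a, b)
            for k, v in oracle.items():
                assert abs(ss[k] - v) < 1e-9

    def test_unbalanced_matches_statsmodels_type2(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(1)
        a = np.array([1] * 7 + [2] * 5 + [3] * 6)
        b = np.array((["d"] * 4 + ["s"] * 3) + (["d"] * 2 + ["s"] * 3) + (["d"] * 3 + ["s"] * 3))
        y = rng.normal(a.astype(float), 1.0)
        model = TwoWayAnova(a, b)
        res = model.anova(y)
        df = pd.DataFrame({"y": y, "a": a.astype(str), "b": b})
        tab = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", df).fit(), typ=2)
        assert res["a"]["p"] == pytest.approx(tab.loc["C(a)", "PR(>F)"], abs=1e-10)
        assert res["b"]["p"] == pytest.approx(tab.loc["C(b)", "PR(>F)"], abs=1e-10)
        assert res["ab"]["p"] == pytest.approx(tab.loc["C(a):C(b)", "PR(>F)"], abs=1e-10)

    def test_null_calibration_of_p_values(self):
        rng = np.random.default_rng(2)
        a = np.repeat([1, 2, 3, 4, 5], 8)
        b = np.tile(np.repeat(["dot", "sign"], 4), 5)
        model = TwoWayAnova(a, b)
        y = rng.normal(size=(a.size, 4000))
        frac = np.mean(model.anova(y)["a"]["p"] < 0.01)
        assert 0.005 < frac < 0.016

    def test_empty_cell_rejected(self):
        a = np.array([1, 1, 2, 2])
        b = np.array(["dot", "dot", "dot", "sign"])
        with pytest.raises(ValueError):
            TwoWayAnova(a, b)


# ----------------------------------------------------------------------
# Inclusion and interval detection


class TestIncludeUnit:
    def _balanced_trials(self, reps=2):
        trials = []
        i = 0
        for n in range(1, 6):
            for prot in ("dot", "sign"):
                for cond in ("standard", "control"):
                    for _ in range(reps):
                        trials.append(make_trial(i, n, protocol=prot, condition=cond))
                        i += 1
        return trials

    def test_silent_unit_excluded(self):
        trials = self._balanced_trials()
        s = make_session(trials, units={"u0": {0: [100.0]}})
        assert not include_unit(s, "u0")

    def test_missing_design_cell_excluded(self):
        trials = [t for t in self._balanced_trials() if
                  not (t.target_number == 3 and t.protocol == "sign"
                       and t.condition == "control")]
        units = {"u0": {t.trial_id: list(np.arange(-250.0, 1600.0, 50.0)) for t in trials}}
        s = make_session(trials, units)
        assert not include_unit(s, "u0")

    def test_active_unit_with_full_design_included(self):
        trials = self._balanced_trials()
        units = {"u0": {t.trial_id: list(np.arange(-250.0, 1600.0, 100.0)) for t in trials}}
        s = make_session(trials, units)
        assert include_unit(s, "u0")


def _tc(p_number, p_protocol=None, p_interaction=None):
    n = len(p_number)
    return AnovaTimecourse(
        unit_id="u",
        bin_starts=800.0 + 10.0 * np.arange(n),
        width=200.0,
        step=10.0,
        p_number=np.asarray(p_number, dtype=float),
        p_protocol=np.ones(n) if p_protocol is None else np.asarray(p_protocol),
        p_interaction=np.ones(n) if p_interaction is None else np.asarray(p_interaction),
    )


class TestSelectiveInterval:
    def test_ten_bin_run_is_below_criterion(self):
        p = np.ones(30)
        p[5:15] = 0.001  # 10 consecutive bins
        assert not detect_selective_interval(_tc(p)).selective

    def test_eleven_bin_run_qualifies_spanning_300ms(self):
        p = np.ones(30)
        p[5:16] = 0.001  # 11 consecutive bins
        res = detect_selective_interval(_tc(p))
        assert res.selective
        start, end = res.interval
        assert start == 800.0 + 50.0
        assert end - start == pytest.approx(300.0)  # 10 steps + 200 ms window

    def test_protocol_effect_inside_run_disqualifies_it(self):
        p = np.ones(30)
        p[5:16] = 0.001
        p_prot = np.ones(30)
        p_prot[10] = 0.005  # protocol main effect mid-run
        assert not detect_selective_interval(_tc(p, p_protocol=p_prot)).selective

    def test_run_with_larger_rate_spread_wins(self):
        p = np.ones(40)
        p[0:11] = 0.001
        p[25:36] = 0.001
        numbers = np.repeat([1, 2], 10)
        rates = np.zeros((20, 40))
        rates[numbers == 2, 0:11] = 4.0   # spread 4 Hz in run 1
        rates[numbers == 2, 25:36] = 9.0  # spread 9 Hz in run 2
        res = detect_selective_interval(_tc(p), rates, numbers)
        assert res.interval[0] == 800.0 + 250.0


class TestTuning:
    def _session_with_rates(self, rates_by_number):
        trials, units = [], {"u0": {}}
        i = 0
        for n, hz in rates_by_number.items():
            for _ in range(4):
                trials.append(make_trial(i, n))
                units["u0"][i] = list(np.linspace(800.0, 1699.0, int(hz * 0.9)))
                i += 1
        return make_session(trials, units)

    def test_min_max_normalization_arithmetic(self):
        s = self._session_with_rates({1: 2, 2: 4, 3: 8, 4: 4, 5: 2})
        res = tuning_and_normalize(s, "u0", (800.0, 1700.0))
        assert res.preferred_number == 3
        norm = [res.normalized_tuning[n] for n in range(1, 6)]
        np.testing.assert_allclose(norm, [0, 1 / 3, 1, 1 / 3, 0], atol=1e-9)

    def test_tie_breaks_to_smaller_number_with_flag(self):
        s = self._session_with_rates({1: 2, 2: 8, 3: 8, 4: 4, 5: 2})
        res = tuning_and_normalize(s, "u0", (800.0, 1700.0))
        assert res.preferred_number == 2
        assert "preferred_tie" in res.flags

    def test_flat_tuning_flagged_with_undefined_normalization(self):
        s = self._session_with_rates({n: 5 for n in range(1, 6)})
        res = tuning_and_normalize(s, "u0", (800.0, 1700.0))
        assert "flat_tuning" in res.flags and res.normalized_tuning is None


class TestPopulationTuning:
    def test_single_unit_group_equals_unit_curve(self, rich):
        results = [r for r in analyze_session(rich) if r.selective and r.normalized_tuning]
        by_pref, by_dist = population_tuning(results)
        groups = by_pref.groupby("preferred")
        for pref, g in groups:
            units = [r for r in results if r.preferred_number == pref]
            if len(units) == 1:
                for _, row in g.iterrows():
                    assert row["mean"] == pytest.approx(
                        units[0].normalized_tuning[row["number"]]
                    )
        # distance 0 is the normalized peak of every unit
        d0 = by_dist.set_index("distance").loc[0, "mean"]
        assert d0 == pytest.approx(1.0)

    def test_strongly_tuned_units_recovered(self, rich, rich_truth):
        results = analyze_session(rich)
        hits = total = 0
        for r in results:
            truth = rich_truth.units[r.unit_id]
            if truth.preferred_number is None:
                continue
            if truth.peak_gain >= 3 * truth.baseline_rate and r.selective:
                total += 1
                hits += r.preferred_number == truth.preferred_number
        assert total >= 5
        assert hits / total >= 0.8


def test_false_positive_rate_on_untuned_populations():
    """Per-bin alpha=0.01 plus the 11-bin run criterion keeps unit-level
    false positives far below 5%."""
    n_selective = n_units = 0
    for seed in range(10):
        spec = PopulationSpec(n_units=8, tuned_fraction=0.0, seed=seed)
        s, _ = generate_session(spec, BehaviorParams(trials_per_cell=12), seed=seed)
        results = analyze_session(s)
        n_units += len(results)
        n_selective += sum(r.selective for r in results)
    assert n_units >= 40
    assert n_selective / n_units <= 0.05


def test_transient_unit_interval_covers_tuned_window():
    units = {
        "t0": UnitParams(preferred_number=4, baseline_rate=3.0, peak_gain=25.0,
                         tuning_sigma_log=0.3,
                         temporal_profile=("transient", 1000.0, 1400.0)),
        "bg": UnitParams(preferred_number=None, baseline_rate=5.0),
    }
    s, _ = generate_session(
        PopulationSpec(n_units=2), BehaviorParams(weber_fraction=0.08, trials_per_cell=12),
        seed=3, units=units,
    )
    tc = sliding_anova(s, "t0")
    sig = tc.p_number < 0.01
    # the bins overlapping [1000, 1400) should be solidly significant
    inside = (tc.bin_starts >= 1050) & (tc.bin_starts + tc.width <= 1350)
    assert sig[inside].mean() > 0.9
    res = detect_selective_interval(tc)
    assert res.selective
    assert res.interval[0] < 1200 < res.interval[1]


# ----------------------------------------------------------------------
# Error-trial contrast


def test_wilcoxon_matches_exact_enumeration():
    """The signed-rank p-value inside the contrast equals brute-force
    enumeration over all 2^6 sign assignments."""
    correct = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    error = correct - np.array([0.5, 1.0, -1.5, 2.0, 2.5, 3.0])
    d = correct - error
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_pos = ranks[d > 0].sum()
    dist = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=6)
    ]
    dist = np.asarray(dist)
    p_exact = min(1.0, 2 * min(np.mean(dist <= w_pos), np.mean(dist >= w_pos)))
    from scipy import stats

    assert stats.wilcoxon(correct, error).pvalue == pytest.approx(p_exact, abs=1e-12)


def test_identical_rates_give_null_contrast(rich):
    results = analyze_session(rich)
    out = error_trial_contrast(rich, results)
    # the same-session contrast on real draws should at least report shape
    assert "preferred_contrast" in out
    # and a hand-built all-tie contrast degenerates to p = 1
    from numprod.selectivity import SelectivityResult

    trials = []
    i = 0
    for n in range(1, 6):
        for produced in (n, max(n - 1, 0)):
            for _ in range(3):
                trials.append(make_trial(i, n, produced=produced))
                i += 1
    units = {"u0": {t.trial_id: list(np.linspace(850.0, 1650.0, 9)) for t in trials},
             "u1": {t.trial_id: list(np.linspace(850.0, 1650.0, 9)) for t in trials}}
    s = make_session(trials, units)
    fake = [
        SelectivityResult(uid, True, interval=(800.0, 1700.0), preferred_number=3)
        for uid in ("u0", "u1")
    ]
    res = error_trial_contrast(s, fake)
    assert res["preferred_contrast"]["pvalue"] == 1.0
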