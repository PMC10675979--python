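"""Kaplan-Meier, log-rank, maxstat cutpoints, Cox fits, HR pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from metascreen.io import SurvivalTable
from metascreen.survival import (
    HrRecord,
    cox_fit,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    pool_hr,
)


def surv_table(time, event, **covars):
    return SurvivalTable(pd.DataFrame({"time": time, "event": event, **covars}))


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimate(surv_table([1, 2, 3], [0, 0, 0]), ["a"] * 3)
        assert (km["a"]["survival"] == 1.0).all()

    def test_all_events_product_limit(self):
        km = km_estimate(surv_table([1, 2, 3], [1, 1, 1]), ["a"] * 3)["a"]
        s = km.set_index("time")["survival"]
        assert s.loc[1] == pytest.approx(2 / 3)
        assert s.loc[2] == pytest.approx(1 / 3)
        assert s.loc[3] == pytest.approx(0.0)

    def test_censoring_risk_set_bookkeeping(self):
        # events at 1 and 3, censored at 2: S(1)=2/3, S(3)=2/3*(1-1/1)=0
        km = km_estimate(surv_table([1, 2, 3], [1, 0, 1]), ["a"] * 3)["a"]
        s = km.set_index("time")["survival"]
        assert s.loc[1] == pytest.approx(2 / 3)
        assert s.loc[3] == pytest.approx(0.0)

    def test_uncensored_km_is_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 40).round(3)
        km = km_estimate(surv_table(t, np.ones(40, int)), ["a"] * 40)["a"]
        for _, row in km[km["time"] > 0].iterrows():
            assert row["survival"] == pytest.approx(np.mean(t > row["time"]), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(surv_table([1.0], [1]), [])


class TestLogrank:
    def test_hand_tally_example(self):
        # A events at 1,3; B events at 2,4: hypergeometric tally gives 0.6154
        table = surv_table([1, 3, 2, 4], [1, 1, 1, 1])
        chi2, p = logrank_test(table, ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(0.6154, abs=1e-3)

    def test_label_symmetry(self):
        rng = np.random.default_rng(4)
        table = surv_table(rng.exponential(5, 30), rng.integers(0, 2, 30))
        grp = np.array(["A"] * 15 + ["B"] * 15)
        c1, p1 = logrank_test(table, grp)
        c2, p2 = logrank_test(table, np.where(grp == "A", "B", "A"))
        assert c1 == pytest.approx(c2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_identical_groups_zero_statistic(self):
        t, e = [1, 2, 3], [1, 1, 1]
        table = surv_table(t + t, e + e)
        chi2, _ = logrank_test(table, ["A"] * 3 + ["B"] * 3)
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(surv_table([1, 2], [1, 1]), ["A", "A"])


class TestMaxstat:
    def test_minprop_half_with_odd_n_rejected(self):
        table = surv_table(np.arange(1, 12), np.ones(11, int))
        with pytest.raises(ValueError, match="candidate"):
            maxstat_cutpoint(table, np.arange(11.0), minprop=0.5)

    def test_constant_expression_rejected(self):
        table = surv_table(np.arange(1, 12), np.ones(11, int))
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutpoint(table, np.ones(11))

    def test_monotone_transform_maps_cutpoint(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(0, 1, n)
        table = surv_table(rng.exponential(5, n), rng.integers(0, 2, n) | 1)
        base = maxstat_cutpoint(table, x)
        trans = maxstat_cutpoint(table, np.exp(x))
        assert trans.cutpoint == pytest.approx(np.exp(base.cutpoint), rel=1e-9)
        assert trans.max_stat == pytest.approx(base.max_stat, rel=1e-9)
        assert (trans.groups == base.groups).all()

    def test_strong_step_effect_recovered(self):
        rng = np.random.default_rng(17)
        n = 300
        x = rng.normal(0, 1, n)
        high = x > np.median(x)
        rate = np.exp(np.log(0.05) + np.log(4.0) * high)
        table = surv_table(rng.exponential(1 / rate), np.ones(n, int))
        cut = maxstat_cutpoint(table, x)
        pct = np.mean(x <= cut.cutpoint)
        assert 0.30 <= pct <= 0.70

    def test_null_still_returns_a_cutpoint(self):
        rng = np.random.default_rng(30)
        table = surv_table(rng.exponential(5, 40), np.ones(40, int))
        cut = maxstat_cutpoint(table, rng.normal(0, 1, 40))
        assert np.isfinite(cut.cutpoint)
        assert set(cut.groups.unique()) == {"high", "low"}


def breslow_loglik_oracle(beta, time, event, x):
    """Explicit Breslow partial likelihood, written independently."""
    ll = 0.0
    for t in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        risk = [i for i, ti in enumerate(time) if ti >= t]
        dead = [i for i, (ti, ei) in enumerate(zip(time, event)) if ti == t and ei == 1]
        ll += sum(beta * x[i] for i in dead)
        ll -= len(dead) * np.log(sum(np.exp(beta * x[i]) for i in risk))
    return ll


class TestCox:
    def test_matches_grid_oracle_with_ties(self):
        time = np.array([1, 1, 2, 2, 2, 3, 4, 4, 5, 6], dtype=float)
        event = np.array([1, 1, 1, 0, 1, 1, 1, 0, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        res = cox_fit(surv_table(time, event, grp=x), ["grp"])
        opt = minimize_scalar(
            lambda b: -breslow_loglik_oracle(b, time, event, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.table.iloc[0]["coef"] == pytest.approx(opt.x, abs=1e-5)

    def test_small_sample_score_equation(self):
        # two groups, one event each (times 1 and 2), others censored:
        # one-dimensional score equation with a finite root
        time = np.array([1.0, 2.0, 3.0, 3.0])
        event = np.array([1, 1, 0, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_fit(surv_table(time, event, grp=x), ["grp"])
        opt = minimize_scalar(
            lambda b: -breslow_loglik_oracle(b, time, event, x),
            bounds=(-10, 10), method="bounded", options={"xatol": 1e-10},
        )
        assert res.table.iloc[0]["coef"] == pytest.approx(opt.x, abs=1e-6)

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(14)
        n = 120
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        t = rng.exponential(1 / np.exp(0.5 * x - 0.3 * z))
        e = (rng.random(n) < 0.8).astype(int)
        df = pd.DataFrame({"time": t, "event": e, "x": x, "z": z})
        res = cox_fit(SurvivalTable(df), ["x", "z"])
        cph = CoxPHFitter().fit(df, "time", "event")
        for term in ("x", "z"):
            ours = res.table.set_index("term").loc[term]
            assert ours["coef"] == pytest.approx(cph.params_[term], rel=1e-4, abs=1e-6)
            assert ours["se"] == pytest.approx(cph.standard_errors_[term], rel=1e-3)

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="constant"):
            res = cox_fit(
                surv_table(
                    rng.exponential(5, 20), np.ones(20, int),
                    flat=np.ones(20), x=rng.normal(0, 1, 20),
                ),
                ["flat", "x"],
            )
        assert res.dropped == ["flat"]
        assert list(res.table["term"]) == ["x"]

    def test_separation_reported_non_estimable(self):
        # all events in one arm, the other entirely censored later
        time = np.array([1, 2, 3, 4, 5, 10, 10, 10, 10, 10], dtype=float)
        event = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        x = np.array([1.0] * 5 + [0.0] * 5)
        res = cox_fit(surv_table(time, event, grp=x), ["grp"])
        row = res.table.iloc[0]
        assert not row["estimable"]
        assert np.isnan(row["hr"])

    def test_categorical_reference_is_first_sorted_level(self):
        rng = np.random.default_rng(10)
        n = 40
        stage = rng.choice(["I", "II"], n)
        res = cox_fit(
            surv_table(rng.exponential(5, n), np.ones(n, int), stage=stage), ["stage"]
        )
        assert list(res.table["term"]) == ["stage[II]"]

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(surv_table([1, 2], [0, 0], x=[0.0, 1.0]), ["x"])


class TestPoolHr:
    def test_identical_records(self):
        r = HrRecord("a", 2.0, 1.5, 2.67)
        pooled = pool_hr([r, r, r])
        assert pooled.pooled_hr == pytest.approx(2.0, abs=1e-9)

    def test_hand_inverse_variance_example(self):
        z = 1.959963984540054
        recs = [
            HrRecord("a", 2.0, np.exp(np.log(2.0) - z * 0.1), np.exp(np.log(2.0) + z * 0.1)),
            HrRecord("b", 2.5, np.exp(np.log(2.5) - z * 0.2), np.exp(np.log(2.5) + z * 0.2)),
        ]
        pooled = pool_hr(recs)
        y = (100 * np.log(2.0) + 25 * np.log(2.5)) / 125
        assert pooled.pooled_hr == pytest.approx(np.exp(y), rel=1e-9)
        assert pooled.pooled_hr == pytest.approx(2.09, abs=0.005)
        assert pooled.ci95[0] == pytest.approx(1.75, abs=0.01)
        assert pooled.ci95[1] == pytest.approx(2.49, abs=0.01)

    def test_single_record_passthrough(self):
        z, se = 1.959963984540054, 0.15
        lo, hi = np.exp(np.log(1.8) - z * se), np.exp(np.log(1.8) + z * se)
        pooled = pool_hr([HrRecord("a", 1.8, lo, hi)])
        assert pooled.pooled_hr == pytest.approx(1.8, rel=1e-9)
        assert pooled.ci95[0] == pytest.approx(lo, rel=1e-9)
        assert pooled.ci95[1] == pytest.approx(hi, rel=1e-9)

    def test_invalid_ci_rejected(self):
        with pytest.raises(ValueError, match="lo >= hi"):
            pool_hr([HrRecord("a", 2.0, 2.5, 2.1)])
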