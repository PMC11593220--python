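"""Kaplan-Meier, log-rank, Cox PH, the time-dependent PH check and
association tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import ithquant as iq


def cohort_frame(time, event, **cols):
    df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(len(time))],
                       "time_months": np.asarray(time, float),
                       "event": np.asarray(event, int)})
    for k, v in cols.items():
        df[k] = v
    return df


def random_cohort(n, seed, beta=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    c = rng.exponential(40.0, size=n)
    return cohort_frame(np.minimum(t, c), (t <= c).astype(int), x=x)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = iq.km_estimate(cohort_frame([5, 8, 9], [0, 0, 0]))
        assert (km.survival == 1.0).all()

    def test_all_events_closed_form(self):
        km = iq.km_estimate(cohort_frame([1, 2, 3], [1, 1, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(1 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_matches_brute_force_product(self):
        """Product-limit estimate equals the direct product over risk sets."""
        df = random_cohort(60, seed=2)
        km = iq.km_estimate(df)
        t = df["time_months"].to_numpy()
        e = df["event"].to_numpy()
        for t0 in np.quantile(t, [0.2, 0.5, 0.8]):
            s = 1.0
            for ti in np.unique(t[(e == 1) & (t <= t0)]):
                d = ((t == ti) & (e == 1)).sum()
                n_at = (t >= ti).sum()
                s *= 1 - d / n_at
            assert km.survival_at(t0) == pytest.approx(s)

    def test_monotone_and_grouped(self):
        df = random_cohort(80, seed=3)
        groups = np.where(df["x"] > 0, "a", "b")
        curves = iq.km_estimate(df, group=groups)
        assert set(curves) == {"a", "b"}
        for c in curves.values():
            assert (np.diff(c.survival) <= 1e-12).all()
            assert c.survival[0] <= 1.0

    def test_no_censoring_equals_empirical_survival(self):
        df = random_cohort(50, seed=4)
        df["event"] = 1
        km = iq.km_estimate(df)
        t = df["time_months"].to_numpy()
        for t0 in np.quantile(t, [0.3, 0.7]):
            assert km.survival_at(t0) == pytest.approx((t > t0).mean())

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty"):
            iq.km_estimate(cohort_frame([], []))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        df = random_cohort(30, seed=5)
        dup = pd.concat([df, df], ignore_index=True)
        labels = np.repeat(["a", "b"], 30)
        stat, p = iq.logrank_test(dup["time_months"], dup["event"], labels)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_calculation(self):
        """O-E/V computed by hand over the pooled risk sets.

        group A: times 1 (event), 3 (event), 5 (censored)
        group B: times 2 (event), 4 (censored), 6 (event)
        t=1: n=6, nA=3, d=1, dA=1 -> e=0.5,   v=0.25
        t=2: n=5, nA=2, d=1, dA=0 -> e=0.4,   v=0.24
        t=3: n=4, nA=2, d=1, dA=1 -> e=0.5,   v=0.25
        t=6: n=1, nA=0, d=1, dA=0 -> e=0,     v=0
        O-E = 2 - 1.4 = 0.6, V = 0.74, chi2 = 0.36/0.74
        """
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 1, 1, 0, 0, 1]
        labels = ["a", "b", "a", "b", "a", "b"]
        stat, p = iq.logrank_test(time, event, labels)
        assert stat == pytest.approx(0.36 / 0.74)
        assert p == pytest.approx(stats.chi2.sf(0.36 / 0.74, 1))

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        for seed in range(5):
            df = random_cohort(40, seed=seed, beta=0.5)
            labels = np.where(df["x"] > 0, "hi", "lo")
            stat, p = iq.logrank_test(df["time_months"], df["event"], labels)
            ref = ll_logrank(df.loc[labels == "hi", "time_months"],
                             df.loc[labels == "lo", "time_months"],
                             df.loc[labels == "hi", "event"],
                             df.loc[labels == "lo", "event"])
            assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_size_under_null(self):
        """Exchangeable null: rejection rate ~ 0.05 at alpha = 0.05."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            t = rng.exponential(10.0, size=40)
            labels = np.repeat(["a", "b"], 20)
            _, p = iq.logrank_test(t, np.ones(40, int), labels)
            rejections += p < 0.05
        rate = rejections / n_sims
        assert 0.03 < rate < 0.07  # 3 sigma band around 0.05

    def test_invariant_to_monotone_time_transform(self):
        df = random_cohort(50, seed=6, beta=1.0)
        labels = np.where(df["x"] > 0, "hi", "lo")
        s1, _ = iq.logrank_test(df["time_months"], df["event"], labels)
        s2, _ = iq.logrank_test(np.log1p(df["time_months"]), df["event"], labels)
        assert s1 == pytest.approx(s2)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            iq.logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCoxFit:
    def test_null_covariate_near_zero(self):
        df = random_cohort(300, seed=7, beta=0.0)
        fit = iq.cox_fit(df, ["x"])
        assert abs(fit.params.iloc[0]) < 2 * fit.bse.iloc[0]

    def test_recovery_at_n_1000(self):
        df = random_cohort(1000, seed=8, beta=1.0)
        fit = iq.cox_fit(df, ["x"])
        assert fit.params.iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_matches_hand_coded_efron_likelihood(self):
        """Independent oracle: numerically maximize a hand-written Efron
        partial likelihood on a small cohort and compare the beta."""
        df = cohort_frame([2, 3, 3, 5, 7, 9], [1, 1, 1, 0, 1, 1],
                          x=[1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        t = df["time_months"].to_numpy()
        e = df["event"].to_numpy()
        x = df["x"].to_numpy()

        def neg_pll(beta):
            ll = 0.0
            for ti in np.unique(t[e == 1]):
                deaths = (t == ti) & (e == 1)
                at_risk = t >= ti
                xd = x[deaths]
                ll += beta * xd.sum()
                r = np.exp(beta * x[at_risk]).sum()
                rd = np.exp(beta * xd).sum()
                m = deaths.sum()
                for j in range(m):
                    ll -= np.log(r - j / m * rd)
            return -ll

        res = optimize.minimize_scalar(neg_pll, bounds=(-5, 5),
                                       method="bounded")
        fit = iq.cox_fit(df, ["x"])
        assert fit.params.iloc[0] == pytest.approx(res.x, abs=1e-4)

    def test_hr_and_ci_consistent(self):
        df = random_cohort(200, seed=9, beta=0.8)
        fit = iq.cox_fit(df, ["x"])
        b, se = fit.params.iloc[0], fit.bse.iloc[0]
        assert fit.hazard_ratios.iloc[0] == pytest.approx(np.exp(b))
        assert fit.conf_int.iloc[0, 0] == pytest.approx(np.exp(b - 1.96 * se),
                                                        rel=1e-3)

    def test_sign_agrees_with_logrank_direction(self):
        for seed in range(5):
            df = random_cohort(120, seed=seed + 20, beta=1.2)
            labels = np.where(df["x"] > 0, 1.0, 0.0)
            df["grp"] = labels
            fit = iq.cox_fit(df, ["grp"])
            km = iq.km_estimate(df, group=np.where(labels == 1, "hi", "lo"))
            med = df["time_months"].median()
            worse_is_hi = km["hi"].survival_at(med) < km["lo"].survival_at(med)
            assert (fit.params.iloc[0] > 0) == worse_is_hi

    def test_zero_events_raises(self):
        df = cohort_frame([1, 2, 3], [0, 0, 0], x=[0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="event"):
            iq.cox_fit(df, ["x"])


class TestPHCheck:
    def test_null_interaction_p_roughly_uniform(self):
        """Under exact PH the interaction p-value is ~ Uniform(0,1)."""
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(60):
            n = 80
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.08 * np.exp(0.5 * x)))
            df = cohort_frame(t, np.ones(n, int), x=x)
            _, p = iq.ph_check(df, "x")
            pvals.append(p)
        d, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_detects_time_decaying_effect(self):
        """A strongly time-decaying covariate effect produces a negative
        log-time interaction that is detected."""
        rng = np.random.default_rng(14)
        detected = 0
        for _ in range(5):
            n = 600
            x = rng.binomial(1, 0.5, size=n).astype(float)
            # piecewise hazard: strong effect before t0, none after
            t0, h0, beta = 12.0, 0.04, 1.8
            u = rng.random(n)
            rate1 = h0 * np.exp(beta * x)
            t = -np.log(u) / rate1
            late = t > t0
            t[late] = t0 - np.log(u[late] * np.exp(rate1[late] * t0)) / h0
            df = cohort_frame(np.minimum(t, 60.0), (t <= 60.0).astype(int),
                              x=x)
            b, p = iq.ph_check(df, "x")
            detected += (p < 0.05) and (b < 0)
        assert detected >= 4

    def test_constant_covariate_raises(self):
        df = cohort_frame([1, 2, 3], [1, 1, 1], x=[1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            iq.ph_check(df, "x")


class TestAssociation:
    def test_balanced_table_chi2_zero(self):
        groups = ["a"] * 20 + ["b"] * 20
        cats = (["x"] * 10 + ["y"] * 10) * 2
        stat, p = iq.association_table(groups, cats)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula_on_toy_table(self):
        """Table (20,30 / 40,10): chi2 = sum (O-E)^2 / E with E from the
        margins: rows 50/50, cols 60/40 -> E = (30,20 / 30,20)."""
        groups = ["a"] * 50 + ["b"] * 50
        cats = ["x"] * 20 + ["y"] * 30 + ["x"] * 40 + ["y"] * 10
        stat, p = iq.association_table(groups, cats)
        expected = (100 / 30 + 100 / 20) * 2
        assert stat == pytest.approx(expected)
        assert p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError):
            iq.association_table(["a", "a"], ["x", "y"])

    def test_anova_identical_means(self):
        rng = np.random.default_rng(15)
        v = rng.normal(size=30)
        groups = np.tile(["a", "b", "c"], 10)
        vals = np.concatenate([v[:10], v[:10], v[:10]])
        f, p = iq.anova_across(np.repeat(["a", "b", "c"], 10), vals)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_anova_separated_means(self):
        vals = np.concatenate([np.zeros(10), np.ones(10) * 5])
        vals += np.random.default_rng(16).normal(0, 0.1, 20)
        f, p = iq.anova_across(np.repeat(["a", "b"], 10), vals)
        assert p < 1e-10
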