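"""Feature normalization, family scores, screening, the Cox-weighted ITH
score and cut-point dichotomization."""

import numpy as np
import pandas as pd
import pytest

import ithquant as iq
from ithquant.scoring import (
    _miller_siegmund,
    prune_collinear,
    scale_features,
    screen_features,
)


def null_cohort(n, seed, censor_rate=0.005):
    params = iq.SyntheticParams(n_patients=n, log_hr_per_theta=0.0,
                                censor_rate=censor_rate, seed=seed)
    rng = np.random.default_rng(seed)
    return iq.simulate_survival(rng.beta(2, 2, size=n), params)


class TestScaleFeatures:
    def test_affine_scaling(self):
        fm = pd.DataFrame({"f": [2.0, 4.0, 6.0]})
        scaled, bounds = scale_features(fm)
        np.testing.assert_allclose(scaled["f"], [0.0, 50.0, 100.0])
        assert bounds.loc["f", "min"] == 2.0 and bounds.loc["f", "max"] == 6.0

    def test_constant_feature_dropped(self):
        fm = pd.DataFrame({"c": [1.0, 1.0, 1.0], "v": [0.0, 1.0, 2.0]})
        scaled, _ = scale_features(fm)
        assert list(scaled.columns) == ["v"]

    def test_all_missing_feature_dropped(self):
        fm = pd.DataFrame({"m": [np.nan] * 3, "v": [0.0, 1.0, 2.0]})
        scaled, _ = scale_features(fm)
        assert list(scaled.columns) == ["v"]

    def test_bounds_attained(self):
        rng = np.random.default_rng(0)
        fm = pd.DataFrame(rng.normal(size=(30, 6)),
                          columns=[f"f{i}" for i in range(6)])
        scaled, _ = scale_features(fm)
        np.testing.assert_allclose(scaled.max(axis=0), 100.0)
        np.testing.assert_allclose(scaled.min(axis=0), 0.0)


class TestFamilyScore:
    def make_cat(self):
        from ithquant.catalogue import FeatureCatalogue, FeatureDef
        return FeatureCatalogue([
            FeatureDef("a", "texture", "contrast", ("x",), "differentiation"),
            FeatureDef("b", "texture", "entropy", ("x",), "differentiation"),
            FeatureDef("c", "texture", "contrast", ("y",), "tils"),
        ])

    def test_mean_of_members(self):
        fm = pd.DataFrame({"a": [40.0], "b": [60.0], "c": [10.0]})
        s = iq.family_score(fm, self.make_cat(), "differentiation")
        assert s.iloc[0] == 50.0

    def test_pairwise_complete(self):
        fm = pd.DataFrame({"a": [40.0, np.nan], "b": [np.nan, np.nan],
                           "c": [0.0, 0.0]})
        s = iq.family_score(fm, self.make_cat(), "differentiation")
        assert s.iloc[0] == 40.0
        assert np.isnan(s.iloc[1])

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError, match="family"):
            iq.family_score(pd.DataFrame({"a": [1.0]}), self.make_cat(),
                            "stroma")


class TestScreening:
    def test_strong_signal_retained_and_null_not(self):
        n = 400
        cohort = null_cohort(n, seed=1)
        params = iq.SyntheticParams(n_patients=n, log_hr_per_theta=1.5, seed=2)
        rng = np.random.default_rng(3)
        theta = rng.beta(2, 2, size=n)
        cohort = iq.simulate_survival(theta, params)
        fm = pd.DataFrame({"signal": theta * 100,
                           "noise": rng.normal(size=n)},
                          index=cohort["patient_id"])
        scr = screen_features(fm, cohort)
        assert scr.loc["signal", "retained"]
        assert scr.loc["signal", "p"] < 0.01

    def test_zero_events_is_error(self):
        cohort = null_cohort(20, seed=4)
        cohort["event"] = 0
        fm = pd.DataFrame({"f": np.arange(20.0)},
                          index=cohort["patient_id"])
        with pytest.raises(ValueError, match="event"):
            screen_features(fm, cohort)

    def test_constant_feature_not_retained(self):
        cohort = null_cohort(30, seed=5)
        fm = pd.DataFrame({"c": np.ones(30)}, index=cohort["patient_id"])
        scr = screen_features(fm, cohort)
        assert not scr.loc["c", "retained"]
        assert np.isnan(scr.loc["c", "p"])


class TestPruneCollinear:
    def test_duplicate_feature_pruned_keeping_lower_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        fm = pd.DataFrame({"a": x, "b": x * 2 + 1e-9, "c": rng.normal(size=50)})
        p = pd.Series({"a": 0.01, "b": 0.001, "c": 0.02})
        kept = prune_collinear(fm, ["a", "b", "c"], p)
        assert kept == ["b", "c"]


class TestFitITHModel:
    def test_single_theta_feature_recovers_beta(self):
        """Feature identical to the simulator's theta: the Cox beta on the
        0-100 scaled feature, mapped back to the theta scale, recovers
        beta_true = 1 within +-0.15 at n = 1000."""
        n = 1000
        params = iq.SyntheticParams(n_patients=n, log_hr_per_theta=1.0,
                                    seed=11)
        rng = np.random.default_rng(11)
        theta = rng.beta(2, 2, size=n)
        cohort = iq.simulate_survival(theta, params)
        fm = pd.DataFrame({"theta_feature": theta},
                          index=cohort["patient_id"])
        res = iq.ITHScoreModel(fm, cohort).fit(alpha=0.05)
        beta_scaled = res.params["theta_feature"]
        span = theta.max() - theta.min()
        beta_theta = beta_scaled * 100.0 / span
        assert beta_theta == pytest.approx(1.0, abs=0.15)

    def test_collinear_pair_converges(self):
        n = 300
        params = iq.SyntheticParams(n_patients=n, log_hr_per_theta=2.0, seed=8)
        rng = np.random.default_rng(8)
        theta = rng.beta(2, 2, size=n)
        cohort = iq.simulate_survival(theta, params)
        fm = pd.DataFrame({"f1": theta, "f2": theta * 3 + 0.01},
                          index=cohort["patient_id"])
        res = iq.ITHScoreModel(fm, cohort).fit()
        assert len(res.pruned) == 1  # perfect collinearity pruned

    def test_score_is_affine_in_each_feature(self):
        """Holding other features fixed, the score moves linearly with one
        feature's scaled value, slope = its beta."""
        n = 300
        params = iq.SyntheticParams(n_patients=n, log_hr_per_theta=2.0, seed=6)
        rng = np.random.default_rng(6)
        theta = rng.beta(2, 2, size=n)
        cohort = iq.simulate_survival(theta, params)
        fm = pd.DataFrame({"f1": theta, "f2": rng.normal(size=n)},
                          index=cohort["patient_id"])
        res = iq.ITHScoreModel(fm, cohort).fit()
        name = res.params.index[0]
        lo, hi = res.bounds.loc[name, "min"], res.bounds.loc[name, "max"]
        base = fm.iloc[[0]].copy()
        base[name] = lo + 0.3 * (hi - lo)  # keep both points inside bounds
        bumped = base.copy()
        bumped[name] += (hi - lo) * 0.17
        delta = (res.predict(bumped) - res.predict(base)).iloc[0]
        expected = res.params[name] * 0.17 * 100.0
        assert delta == pytest.approx(expected, rel=1e-9)

    def test_no_screened_features_raises(self):
        cohort = null_cohort(60, seed=10)
        rng = np.random.default_rng(10)
        fm = pd.DataFrame({"n1": rng.normal(size=60)},
                          index=cohort["patient_id"])
        # pure noise at tiny alpha: virtually never screened
        with pytest.raises(ValueError, match="screening"):
            iq.ITHScoreModel(fm, cohort).fit(alpha=1e-6)


class TestCutpoint:
    def test_separable_clusters_cut_between(self):
        rng = np.random.default_rng(0)
        n = 100
        scores = np.concatenate([rng.normal(0, 0.1, 50),
                                 rng.normal(10, 0.1, 50)])
        time = np.concatenate([rng.exponential(100, 50),
                               rng.exponential(10, 50)])
        cohort = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "time_months": time, "event": 1,
        })
        cut = iq.optimal_cutpoint(scores, cohort)
        assert 1.0 < cut.cutoff < 9.0
        assert cut.p_min < 1e-6

    def test_tied_scores_use_distinct_values(self):
        cohort = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(12)],
            "time_months": np.arange(1.0, 13.0), "event": 1,
        })
        scores = np.repeat([1.0, 2.0, 3.0], 4)
        cut = iq.optimal_cutpoint(scores, cohort, min_group_frac=0.2)
        assert set(np.round(cut.candidates, 6)) <= {1.5, 2.5}

    def test_no_feasible_candidate_raises(self):
        cohort = pd.DataFrame({
            "patient_id": ["a", "b", "c"],
            "time_months": [1.0, 2.0, 3.0], "event": 1,
        })
        with pytest.raises(ValueError, match="group-size"):
            iq.optimal_cutpoint(np.array([1.0, 1.0, 2.0]), cohort,
                                min_group_frac=0.5)

    def test_corrected_p_never_below_raw(self):
        for p in [1e-8, 1e-4, 0.01, 0.2, 0.9]:
            assert _miller_siegmund(p, 0.1, 0.1) >= p

    def test_dichotomize_boundary_goes_low(self):
        labels = iq.dichotomize(np.array([1.0, 2.0, 3.0]), 2.0)
        assert labels.tolist() == ["low", "low", "high"]

    def test_dichotomize_partition(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        labels = iq.dichotomize(s, float(np.median(s)))
        assert (labels == "high").sum() + (labels == "low").sum() == 40
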