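"""MCE selection/scoring, AUC, Cox fitting, concordance and KM stratification."""

import numpy as np
import pandas as pd
import pytest

from klse.prediction import (
    MCEModel,
    concordance_index,
    fit_cox,
    fit_mce,
    km_stratified,
    mce_score,
    prognostic_index,
    roc_auc,
)
from klse.synthetic import HazardSpec, simulate_conversion


def signal_features(rng, n=120, p=40, k=3, effect=1.5):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[y == 1, :k] += effect
    cols = [f"f{j:02d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestFitMce:
    def test_informative_features_selected(self):
        rng = np.random.default_rng(0)
        X, y = signal_features(rng)
        model = fit_mce(X, y, n_folds=5, seed=1)
        sel = set(model.selected_features)
        assert len(sel & {"f00", "f01", "f02"}) >= 2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X, y = signal_features(rng)
        a = fit_mce(X, y, n_folds=5, seed=3)
        b = fit_mce(X, y, n_folds=5, seed=3)
        assert a.coefficients == b.coefficients
        assert a.lambda_ == b.lambda_

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        X, _ = signal_features(rng)
        with pytest.raises(ValueError, match="2 classes"):
            fit_mce(X, np.zeros(len(X)), seed=0)

    def test_duplicating_subjects_keeps_selection(self):
        """Doubling every row leaves the selected set essentially unchanged."""
        rng = np.random.default_rng(3)
        X, y = signal_features(rng, n=80, p=20)
        a = fit_mce(X, y, n_folds=4, seed=5)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        b = fit_mce(X2, y2, n_folds=4, seed=5)
        assert set(a.selected_features) & set(b.selected_features)

    def test_pure_noise_selects_sparsely_under_one_se_rule(self):
        """With no informative features the one-SE rule keeps few or none."""
        sizes = []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            X = pd.DataFrame(
                rng.normal(size=(200, 100)), columns=[f"f{j:03d}" for j in range(100)]
            )
            y = np.repeat([0, 1], 100)
            model = fit_mce(X, y, n_folds=5, seed=rep, rule="1se")
            sizes.append(len(model.selected_features))
        assert np.median(sizes) <= 5

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X, y = signal_features(rng, n=60, p=10)
        model = fit_mce(X, y, n_folds=3, seed=7)
        path = tmp_path / "m.json"
        model.to_json(path)
        back = MCEModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.lambda_ == model.lambda_


class TestMceScore:
    def test_zero_coefficients_give_intercept(self):
        model = MCEModel(
            coefficients={}, intercept=0.7, means={}, sds={}, lambda_=0.1, n_folds=5, seed=0
        )
        X = pd.DataFrame({"a": [1.0, 2.0]})
        np.testing.assert_allclose(mce_score(model, X), 0.7)

    def test_unselected_features_ignored(self):
        model = MCEModel(
            coefficients={"a": 1.0}, intercept=0.0, means={"a": 0.0}, sds={"a": 1.0},
            lambda_=0.1, n_folds=5, seed=0,
        )
        X1 = pd.DataFrame({"a": [1.0], "b": [5.0]})
        X2 = pd.DataFrame({"a": [1.0], "b": [-5.0]})
        assert mce_score(model, X1).iloc[0] == mce_score(model, X2).iloc[0]

    def test_missing_feature_named_in_error(self):
        model = MCEModel(
            coefficients={"a": 1.0}, intercept=0.0, means={"a": 0.0}, sds={"a": 1.0},
            lambda_=0.1, n_folds=5, seed=0,
        )
        with pytest.raises(KeyError, match="a"):
            mce_score(model, pd.DataFrame({"b": [1.0]}))

    def test_hand_built_two_feature_model(self):
        model = MCEModel(
            coefficients={"a": 1.0, "b": -1.0}, intercept=0.25,
            means={"a": 0.0, "b": 0.0}, sds={"a": 1.0, "b": 1.0},
            lambda_=0.1, n_folds=5, seed=0,
        )
        X = pd.DataFrame({"a": [0.5], "b": [0.5]})
        assert mce_score(model, X).iloc[0] == pytest.approx(0.25)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000)
        assert 0.47 < roc_auc(s, y) < 0.53

    def test_agreement_with_pair_counting(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        pos, neg = s[y == 1], s[y == 0]
        brute = np.mean([(a > b) + 0.5 * (a == b) for a in pos for b in neg])
        assert roc_auc(s, y) == pytest.approx(brute, abs=1e-12)


def survival_frame(rng, n=300, loghr=np.log(2.0)):
    x = rng.normal(size=n)
    feats = pd.DataFrame({"x": x})
    hz = HazardSpec(beta={"x": loghr} if loghr else {}, baseline_rate=0.03, censor_time=36.0)
    surv = simulate_conversion(feats, hz, seed=rng.integers(2**31))
    return pd.DataFrame(
        {
            "subject_id": surv["subject_id"],
            "time": surv["time_months"],
            "event": surv["event"],
            "x": x,
        }
    )


class TestFitCox:
    def test_recovers_per_sd_log_hazard(self):
        rng = np.random.default_rng(7)
        df = survival_frame(rng, n=500)
        fit = fit_cox(df, ["x"], standardize=True)
        se = (np.log(fit.ci_upper["x"]) - np.log(fit.ci_lower["x"])) / (2 * 1.96)
        assert abs(fit.coefficients["x"] - np.log(2.0)) < 3 * se
        assert fit.ci_lower["x"] < fit.hazard_ratios["x"] < fit.ci_upper["x"]

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b"], "time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]}
        )
        with pytest.raises(ValueError, match="event"):
            fit_cox(df, ["x"])

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(8)
        df = survival_frame(rng, n=100)
        df["x2"] = df["x"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_cox(df, ["x", "x2"])


class TestPrognosticIndex:
    def test_monotone_in_single_covariate(self):
        rng = np.random.default_rng(9)
        df = survival_frame(rng, n=200)
        fit = fit_cox(df, ["x"], standardize=True)
        pi = prognostic_index(fit, df)
        sign = np.sign(fit.coefficients["x"])
        np.testing.assert_array_equal(
            np.argsort(sign * pi.to_numpy()), np.argsort(df["x"].to_numpy())
        )

    def test_location_shift_preserves_ranking(self):
        rng = np.random.default_rng(10)
        df = survival_frame(rng, n=100)
        fit = fit_cox(df, ["x"], standardize=True)
        pi_a = prognostic_index(fit, df)
        df2 = df.copy()
        df2["x"] = df2["x"] + 10.0
        pi_b = prognostic_index(fit, df2)
        np.testing.assert_allclose(np.diff(pi_b) - np.diff(pi_a), 0.0, atol=1e-9)

    def test_missing_covariate_rejected(self):
        rng = np.random.default_rng(11)
        df = survival_frame(rng, n=100)
        fit = fit_cox(df, ["x"], standardize=True)
        with pytest.raises(KeyError, match="x"):
            prognostic_index(fit, df.drop(columns=["x"]))


class TestConcordance:
    def test_perfect_ordering_no_censoring(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        pi = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(pi, t, np.ones(4)) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, size=2000)
        pi = rng.normal(size=2000)
        assert 0.47 < concordance_index(pi, t, np.ones(2000)) < 0.53

    def test_agreement_with_brute_force_with_censoring(self):
        rng = np.random.default_rng(13)
        n = 100
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.6
        pi = rng.normal(size=n)
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if e[i] and t[i] < t[j]:
                    den += 1
                    num += (pi[i] > pi[j]) + 0.5 * (pi[i] == pi[j])
        assert concordance_index(pi, t, e) == pytest.approx(num / den, abs=1e-12)

    def test_agreement_with_lifelines(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(14)
        n = 80
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.7
        pi = rng.normal(size=n)
        # lifelines orders by predicted survival time (higher = longer), so negate
        assert concordance_index(pi, t, e) == pytest.approx(
            ll_cindex(t, -pi, e), abs=1e-12
        )


class TestTruePiDominance:
    def test_true_linear_predictor_beats_single_components(self):
        """When hazard is driven by two features, the C-index of the true
        linear predictor exceeds that of either noisy component alone."""
        rng = np.random.default_rng(30)
        n = 500
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        lp = np.log(2.0) * x1 + np.log(2.0) * x2
        feats = pd.DataFrame({"x1": x1, "x2": x2})
        hz = HazardSpec(beta={"x1": np.log(2.0), "x2": np.log(2.0)}, baseline_rate=0.03, censor_time=36.0)
        surv = simulate_conversion(feats, hz, seed=31)
        t, e = surv["time_months"].to_numpy(), surv["event"].to_numpy()
        c_true = concordance_index(lp, t, e)
        assert c_true > concordance_index(x1, t, e)
        assert c_true > concordance_index(x2, t, e)


class TestKmStratified:
    def test_event_free_stratum_curve_constant(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "time": np.r_[np.full(10, 36.0), np.linspace(1, 20, 10)],
                "event": np.r_[np.zeros(10), np.ones(10)],
            }
        )
        pi = np.r_[np.zeros(10), np.ones(10)]
        res = km_stratified(pi, df)
        np.testing.assert_allclose(res.curves["low"].to_numpy(), 1.0)
        assert res.n_low == res.n_high == 10

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(15)
        df = survival_frame(rng, n=200, loghr=np.log(4.0))
        fit = fit_cox(df, ["x"], standardize=True)
        pi = prognostic_index(fit, df)
        res = km_stratified(pi.to_numpy(), df)
        assert res.logrank_p < 0.01
        assert res.hr_high_vs_low > 1.5

    def test_degenerate_stratum_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "time": [1.0, 2.0, 3.0], "event": [1, 1, 1]}
        )
        with pytest.raises(ValueError, match="stratum"):
            km_stratified(np.array([0.0, 0.0, 1.0]), df)
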