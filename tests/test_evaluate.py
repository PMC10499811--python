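import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit

from lewypanel.errors import DataError
from lewypanel.evaluate import (
    bootstrap_auc_ci,
    delong_test,
    external_validate,
    hanley_mcneil_se,
    partial_spearman_matrix,
    repeated_cv_auc,
    roc_auc,
    stage_trend_anova,
)
from lewypanel.panel import ridge_refit


def brute_force_auc(scores, labels):
    """All-pairs concordance counting oracle (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s1 in pos:
        for s0 in neg:
            total += 1.0 if s1 > s0 else (0.5 if s1 == s0 else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_worked_example(self):
        # concordant pairs: (0.35 vs 0.1), (0.8 vs 0.1), (0.8 vs 0.4); the
        # pair (0.35 vs 0.4) is discordant -> 3/4
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        auc, curve = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_constant_scores_half(self):
        auc, _ = roc_auc(np.ones(10), [0, 1] * 5)
        assert auc == 0.5

    def test_one_class_error(self):
        with pytest.raises(DataError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        _, curve = roc_auc(scores, labels)
        assert (curve.iloc[0] == [0.0, 0.0]).all()
        assert (curve.iloc[-1] == [1.0, 1.0]).all()
        assert (np.diff(curve["fpr"]) >= 0).all()
        assert (np.diff(curve["tpr"]) >= 0).all()

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        scores = np.round(rng.normal(size=n), 1)  # provoke ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(2.0 * scores) + 5, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestBootstrapCi:
    def test_perfect_separation_degenerate_ci(self):
        s = np.r_[np.zeros(30), np.ones(30)]
        y = s.copy()
        out = bootstrap_auc_ci(s, y, B=100, seed=0)
        assert out.ci_low == out.ci_high == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=80)
        y = (rng.random(80) < expit(s)).astype(float)
        y[:2] = [0, 1]
        a = bootstrap_auc_ci(s, y, B=100, seed=9)
        b = bootstrap_auc_ci(s, y, B=100, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_b_minimum(self):
        with pytest.raises(DataError):
            bootstrap_auc_ci([1, 2], [0, 1], B=10)

    def test_width_close_to_hanley_mcneil(self):
        rng = np.random.default_rng(2)
        n = 500
        y = np.r_[np.zeros(n), np.ones(n)]
        s = np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)]
        out = bootstrap_auc_ci(s, y, B=400, seed=3)
        se = hanley_mcneil_se(out.auc, n, n)
        analytic_width = 2 * 1.96 * se
        width = out.ci_high - out.ci_low
        assert abs(width - analytic_width) / analytic_width < 0.25

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=100)
        y = (rng.random(100) < expit(2 * s)).astype(float)
        y[:2] = [0, 1]
        out = bootstrap_auc_ci(s, y, B=200, seed=5)
        assert out.ci_low <= out.auc <= out.ci_high


class TestRepeatedCv:
    @pytest.fixture(scope="class")
    @staticmethod
    def marker_data():
        rng = np.random.default_rng(6)
        n = 120
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = pd.DataFrame(
            {
                "m1": y * 1.2 + rng.normal(0, 0.7, n),
                "m2": y * 0.8 + rng.normal(0, 0.7, n),
                "junk": rng.normal(size=n),
            }
        )
        return X, y

    def test_pure_noise_mean_auc_near_half(self):
        # averaged over independent null datasets (a single dataset's CV AUC
        # has sampling SD ~0.03-0.05 around 0.5)
        aucs = []
        for s in range(6):
            rng = np.random.default_rng(700 + s)
            n = 300
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
            aucs.append(repeated_cv_auc(X, y, repeats=8, seed=s).auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_single_repeat_reduces_to_kfold(self, marker_data):
        X, y = marker_data
        out = repeated_cv_auc(X, y, repeats=1, seed=1)
        assert out.n_resamples == 1
        assert out.ci_low == out.ci_high == out.auc

    def test_doubling_repeats_consistent(self, marker_data):
        X, y = marker_data
        half = repeated_cv_auc(X, y, repeats=25, seed=2)
        full = repeated_cv_auc(X, y, repeats=50, seed=2)
        assert half.ci_low - 0.02 <= full.auc <= half.ci_high + 0.02

    def test_fold_average_mode(self, marker_data):
        X, y = marker_data
        pooled = repeated_cv_auc(X, y, repeats=10, seed=3, pool_folds=True)
        averaged = repeated_cv_auc(X, y, repeats=10, seed=3, pool_folds=False)
        assert abs(pooled.auc - averaged.auc) < 0.05


class TestDelong:
    def _paired(self, seed=8, n=150, rho=0.6):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n), np.ones(n)]
        base = rng.normal(size=2 * n)
        s1 = y * 1.0 + base + rng.normal(0, 0.5, 2 * n)
        s2 = y * 0.5 + rho * base + rng.normal(0, 0.8, 2 * n)
        return s1, s2, y

    def test_identical_scores(self):
        s1, _, y = self._paired()
        auc1, auc2, z, p = delong_test(s1, s1, y)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_p_one(self):
        s1, _, y = self._paired()
        auc1, auc2, z, p = delong_test(s1, np.exp(s1), y)
        assert auc1 == pytest.approx(auc2)
        assert p == 1.0

    def test_detects_better_marker(self):
        s1, s2, y = self._paired()
        auc1, auc2, z, p = delong_test(s1, s2, y)
        assert auc1 > auc2
        assert p < 0.05

    def test_agrees_with_permutation_oracle(self):
        # permutation: swap the two scores per subject at random
        s1, s2, y = self._paired(seed=9, n=60)
        auc1, auc2, z, p = delong_test(s1, s2, y)
        rng = np.random.default_rng(10)
        obs = abs(auc1 - auc2)
        B = 10_000
        hits = 0
        a = np.column_stack([s1, s2])
        for _ in range(B):
            flip = rng.random(len(y)) < 0.5
            p1 = np.where(flip, a[:, 1], a[:, 0])
            p2 = np.where(flip, a[:, 0], a[:, 1])
            d = abs(roc_auc(p1, y)[0] - roc_auc(p2, y)[0])
            hits += d >= obs - 1e-12
        perm_p = hits / B
        assert abs(p - perm_p) < 0.02

    def test_se_close_to_hanley_mcneil(self):
        rng = np.random.default_rng(11)
        n = 250
        y = np.r_[np.zeros(n), np.ones(n)]
        s = np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)]
        # single-marker DeLong variance via the paired machinery vs analytic
        from lewypanel.evaluate import _placements

        v10, v01 = _placements(s, y)
        se_delong = np.sqrt(v10.var(ddof=1) / n + v01.var(ddof=1) / n)
        se_hm = hanley_mcneil_se(float(v10.mean()), n, n)
        assert abs(se_delong - se_hm) / se_hm < 0.2


class TestExternalValidate:
    def _fit(self, seed=12):
        rng = np.random.default_rng(seed)
        n = 160
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = pd.DataFrame({"m1": y + rng.normal(0, 0.8, n),
                          "m2": -y + rng.normal(0, 0.8, n)})
        model = ridge_refit(X, y, penalty=0.1)
        return model, X, y

    def test_training_data_reproduces_training_auc(self):
        model, X, y = self._fit()
        scores = model.linear_predictor(X)
        train_auc, _ = roc_auc(scores, y)
        out = external_validate(model, X, y, B=100, seed=0)
        assert out.auc == pytest.approx(train_auc, abs=1e-12)

    def test_same_design_new_cohort_within_ci(self):
        model, X, y = self._fit()
        train = external_validate(model, X, y, B=200, seed=1)
        inside = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 160
            y2 = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            X2 = pd.DataFrame({"m1": y2 + rng.normal(0, 0.8, n),
                               "m2": -y2 + rng.normal(0, 0.8, n)})
            auc, _ = roc_auc(model.linear_predictor(X2), y2)
            inside += train.ci_low - 0.02 <= auc <= train.ci_high + 0.02
        assert inside >= 16

    def test_halved_effects_lower_auc(self):
        model, X, y = self._fit()
        train_auc, _ = roc_auc(model.linear_predictor(X), y)
        aucs = []
        for s in range(30):
            rng = np.random.default_rng(200 + s)
            n = 160
            y2 = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            X2 = pd.DataFrame({"m1": 0.5 * y2 + rng.normal(0, 0.8, n),
                               "m2": -0.5 * y2 + rng.normal(0, 0.8, n)})
            aucs.append(roc_auc(model.linear_predictor(X2), y2)[0])
        assert np.mean(aucs) < train_auc

    def test_missing_marker_listed(self):
        model, X, y = self._fit()
        with pytest.raises(DataError, match="m2"):
            external_validate(model, X[["m1"]], y)


class TestPartialSpearman:
    def test_identity_pair(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x})
        r, _ = partial_spearman_matrix(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        r, _ = partial_spearman_matrix(df)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_confounded_pair_vanishes_after_conditioning(self):
        rng = np.random.default_rng(15)
        n = 2000
        z = rng.normal(size=n)
        df = pd.DataFrame({"x": z + rng.normal(0, 0.3, n),
                           "y": z + rng.normal(0, 0.3, n)})
        cov = pd.DataFrame({"z": z})
        r_raw, _ = partial_spearman_matrix(df)
        r_adj, _ = partial_spearman_matrix(df, cov)
        assert r_raw.loc["x", "y"] > 0.7
        assert abs(r_adj.loc["x", "y"]) < 0.1

    def test_too_few_cases_error(self):
        df = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0)})
        with pytest.raises(DataError, match="complete cases"):
            partial_spearman_matrix(df)

    def test_significance_tiers(self):
        rng = np.random.default_rng(16)
        n = 200
        x = rng.normal(size=n)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.4, n),
                           "c": rng.normal(size=n)})
        _, tiers = partial_spearman_matrix(df)
        assert tiers.loc["a", "b"] == 3  # q < 0.001
        assert tiers.loc["a", "c"] in (0, 1)


class TestStageAnova:
    def test_two_groups_equals_t_test(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=40)
        stage = np.repeat(["I", "II"], 20)
        p = stage_trend_anova(v, stage)
        t_p = stats.ttest_ind(v[:20], v[20:], equal_var=True).pvalue
        assert p == pytest.approx(t_p, abs=1e-12)

    def test_strong_trend_tiny_p(self):
        v = np.concatenate([np.full(20, m) + np.random.default_rng(18).normal(0, 0.1, 20)
                            for m in (0.0, 2.0, 4.0)])
        stage = np.repeat(["I", "II", "III"], 20)
        assert stage_trend_anova(v, stage) < 1e-6

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(19)
        ps = []
        for _ in range(400):
            v = rng.normal(size=60)
            stage = np.repeat(["I", "II", "III"], 20)
            ps.append(stage_trend_anova(v, stage))
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.03

    def test_single_stage_error(self):
        with pytest.raises(DataError):
            stage_trend_anova(np.arange(10.0), np.repeat("I", 10))
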