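import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from lewypanel.errors import DataError
from lewypanel.panel import (
    PanelCandidate,
    PanelModel,
    choose_model,
    cv_tune,
    enet_logistic_path,
    lambda_max,
    ridge_refit,
    selection_proportions,
    standardize,
    _design,
    _fit_enet_logistic,
)


@pytest.fixture(scope="module")
def logistic_data():
    """n=200, p=50; 3 informative features with strong effects."""
    rng = np.random.default_rng(42)
    n, p = 200, 50
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"P{j:02d}" for j in range(p)]
    )
    beta = np.zeros(p)
    beta[:3] = [1.5, -1.5, 1.2]
    y = (rng.random(n) < expit(X.to_numpy() @ beta)).astype(float)
    return X, y


def kkt_violation(X, y, covariates, cand):
    """Max KKT residual of a candidate on the average-loglik objective."""
    _, _, Xs = standardize(X)
    C, _ = _design(X, covariates)
    beta = np.zeros(X.shape[1])
    for a, v in cand.coefficients.items():
        beta[X.columns.get_loc(a)] = v
    free = np.r_[cand.intercept, [cand.covariate_coefs[c]
                                  for c in cand.covariate_coefs]]
    eta = C @ free + Xs @ beta
    prob = expit(eta)
    g = -Xs.T @ (y - prob) / len(y)
    lam, alpha = cand.lam, cand.alpha
    nz = beta != 0.0
    v_zero = np.maximum(np.abs(g[~nz]) - lam * alpha, 0.0)
    v_nz = np.abs(g[nz] + lam * alpha * np.sign(beta[nz]) + lam * (1 - alpha) * beta[nz])
    v_free = np.abs(C.T @ (y - prob) / len(y))
    return max(v_zero.max(initial=0), v_nz.max(initial=0), v_free.max())


class TestPath:
    def test_lambda_max_gives_null_model(self, logistic_data):
        X, y = logistic_data
        _, _, Xs = standardize(X)
        C, _ = _design(X, None)
        lmax = lambda_max(Xs, y, C, alpha=1.0)
        cands = enet_logistic_path(X, y, None, 1.0, lambda_grid=[lmax * 1.0001],
                                  cap=50)
        assert cands[0].n_markers == 0
        # just below lambda_max at least one coefficient activates
        cands = enet_logistic_path(X, y, None, 1.0, lambda_grid=[lmax * 0.95],
                                  cap=50)
        assert cands[0].n_markers >= 1

    def test_pure_ridge_all_nonzero(self, logistic_data):
        X, y = logistic_data
        cands = enet_logistic_path(X, y, None, 0.0, lambda_grid=[0.5],
                                  cap=X.shape[1])
        assert cands[0].n_markers == X.shape[1]

    def test_strong_feature_enters_first(self, logistic_data):
        X, y = logistic_data
        path = enet_logistic_path(X, y, None, 1.0, cap=10, n_lambda=80)
        first_nonempty = next(c for c in path if c.n_markers)
        assert set(first_nonempty.selected_assays) <= {"P00", "P01", "P02"}

    def test_cap_respected(self, logistic_data):
        X, y = logistic_data
        for cap in (3, 7):
            path = enet_logistic_path(X, y, None, 0.8, cap=cap, n_lambda=60)
            assert all(c.n_markers <= cap for c in path)

    def test_alpha_out_of_range(self, logistic_data):
        X, y = logistic_data
        with pytest.raises(DataError, match="alpha"):
            enet_logistic_path(X, y, None, 1.5)

    def test_kkt_conditions_hold_along_path(self, logistic_data):
        X, y = logistic_data
        for alpha in (0.3, 1.0):
            path = enet_logistic_path(X, y, None, alpha, cap=15, n_lambda=40)
            for cand in path[::5] + [path[-1]]:
                assert kkt_violation(X, y, None, cand) < 1e-6

    def test_kkt_with_covariates(self, logistic_data):
        X, y = logistic_data
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"age_centered": rng.normal(size=len(X)),
                            "sex_male": rng.integers(0, 2, len(X)).astype(float)})
        path = enet_logistic_path(X, y, cov, 0.7, cap=12, n_lambda=40)
        assert kkt_violation(X, y, cov, path[-1]) < 1e-6


class TestCvTune:
    def test_fold_stratification_and_determinism(self, logistic_data):
        X, y = logistic_data
        c1 = cv_tune(X, y, None, alpha_grid=[1.0], cap_grid=[5], k=5, seed=3,
                     n_lambda=40)
        c2 = cv_tune(X, y, None, alpha_grid=[1.0], cap_grid=[5], k=5, seed=3,
                     n_lambda=40)
        assert c1[0].lam == c2[0].lam
        assert c1[0].cv_auc == c2[0].cv_auc

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(11)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 30)),
                         columns=[f"N{j}" for j in range(30)])
        y = rng.integers(0, 2, n).astype(float)
        cands = cv_tune(X, y, None, alpha_grid=[1.0], cap_grid=[5], k=10,
                        seed=0, n_lambda=30)
        assert abs(cands[0].cv_auc - 0.5) <= 0.08

    def test_small_class_error(self, logistic_data):
        X, y = logistic_data
        y_rare = y.copy()
        y_rare[:] = 0
        y_rare[:4] = 1
        with pytest.raises(DataError, match="class"):
            cv_tune(X, y_rare, None, alpha_grid=[1.0], cap_grid=[5], k=10)

    def test_cap_respected_in_candidates(self, logistic_data):
        X, y = logistic_data
        cands = cv_tune(X, y, None, alpha_grid=[0.5, 1.0], cap_grid=[3, 5],
                        k=5, seed=0, n_lambda=40)
        assert all(c.n_markers <= c.cap for c in cands)


class TestChooseModel:
    def _cand(self, auc, n_markers, alpha=0.5):
        return PanelCandidate(
            alpha=alpha, lam=0.1, cap=21,
            selected_assays=[f"m{i}" for i in range(n_markers)],
            coefficients={f"m{i}": 1.0 for i in range(n_markers)},
            intercept=0.0, covariate_coefs={}, cv_auc=auc, cv_loglik=-0.5,
        )

    def test_tie_prefers_fewer_markers(self):
        a = self._cand(0.93, 7)
        b = self._cand(0.93, 12)
        assert choose_model([b, a]) is a

    def test_single_candidate(self):
        a = self._cand(0.8, 4)
        assert choose_model([a]) is a

    def test_auc_dominates(self):
        a = self._cand(0.95, 10)
        b = self._cand(0.90, 3)
        assert choose_model([a, b]) is a

    def test_tolerance_band(self):
        a = self._cand(0.930, 12)
        b = self._cand(0.927, 5)  # within 0.005 -> fewer markers wins
        assert choose_model([a, b]) is b

    def test_alpha_breaks_remaining_ties(self):
        a = self._cand(0.9, 5, alpha=0.9)
        b = self._cand(0.9, 5, alpha=0.3)
        assert choose_model([a, b]) is b


class TestSelectionProportions:
    def test_definition_and_range(self, logistic_data):
        X, y = logistic_data
        cands = cv_tune(X, y, None, alpha_grid=[1.0], cap_grid=[5], k=5,
                        seed=2, n_lambda=40)
        props = selection_proportions(X, y, None, cands[0], k=5, seed=2)
        assert ((props >= 0) & (props <= 1)).all()
        assert set(props.index) == set(X.columns)
        # proportions are multiples of 1/k
        np.testing.assert_allclose(props * 5, np.round(props * 5), atol=1e-12)

    def test_strong_marker_proportion_one(self, logistic_data):
        X, y = logistic_data
        cands = cv_tune(X, y, None, alpha_grid=[1.0], cap_grid=[5], k=5,
                        seed=2, n_lambda=40)
        props = selection_proportions(X, y, None, cands[0], k=5, seed=2)
        assert props["P00"] == 1.0
        assert props["P01"] == 1.0

    def test_never_selected_is_zero(self, logistic_data):
        X, y = logistic_data
        cands = cv_tune(X, y, None, alpha_grid=[1.0], cap_grid=[3], k=5,
                        seed=2, n_lambda=40)
        props = selection_proportions(X, y, None, cands[0], k=5, seed=2)
        assert (props == 0.0).sum() >= 30


class TestRidgeRefit:
    def test_large_penalty_shrinks_to_prevalence(self, logistic_data):
        X, y = logistic_data
        model = ridge_refit(X[["P00", "P01"]], y, penalty=1e6)
        assert max(abs(v) for v in model.marker_coefs.values()) < 1e-3
        prevalence_logit = np.log(y.mean() / (1 - y.mean()))
        # intercept on the original scale folds in the (tiny) marker terms
        eta0 = model.linear_predictor(
            pd.DataFrame({"P00": [X["P00"].mean()], "P01": [X["P01"].mean()]})
        )
        assert eta0[0] == pytest.approx(prevalence_logit, abs=1e-3)

    def test_shrinkage_monotone(self, logistic_data):
        X, y = logistic_data
        sub = X[["P00", "P01", "P02"]]
        m_mle = ridge_refit(sub, y, penalty=1e-8)
        m_ridge = ridge_refit(sub, y, penalty=0.1)
        norm = lambda m: np.linalg.norm(list(m.marker_coefs.values()))
        assert norm(m_ridge) < norm(m_mle)

    def test_separable_data_stays_finite(self):
        X = pd.DataFrame({"m": np.r_[np.linspace(-2, -1, 10),
                                     np.linspace(1, 2, 10)]})
        y = np.r_[np.zeros(10), np.ones(10)]
        model = ridge_refit(X, y, penalty=0.1)
        assert np.isfinite(model.marker_coefs["m"])
        assert abs(model.marker_coefs["m"]) < 100

    def test_zero_markers_error(self, logistic_data):
        X, y = logistic_data
        with pytest.raises(DataError):
            ridge_refit(X[[]], y)

    def test_back_transform_consistency(self, logistic_data):
        # standardized-scale prediction == original-scale prediction
        X, y = logistic_data
        sub = X[["P00", "P02"]]
        model = ridge_refit(sub, y, penalty=0.1)
        eta = model.linear_predictor(sub)
        means, sds, Xs = standardize(sub)
        assert (expit(eta) - model.predict_proba(sub) == 0).all()
        # zero raw input reproduces the stored intercept exactly
        zero = pd.DataFrame({"P00": [0.0], "P02": [0.0]})
        assert model.linear_predictor(zero)[0] == pytest.approx(model.intercept)


class TestPanelModelSerialization:
    def test_json_round_trip_exact(self, logistic_data):
        X, y = logistic_data
        cov = pd.DataFrame({"age_centered": np.linspace(-10, 10, len(X))})
        model = ridge_refit(X[["P00", "P01"]], y, cov, penalty=0.1,
                            training_contrast="DLB_vs_AD", seed=5)
        restored = PanelModel.from_json(model.to_json())
        assert restored == model
        eta1 = model.linear_predictor(X[["P00", "P01"]], cov)
        eta2 = restored.linear_predictor(X[["P00", "P01"]], cov)
        np.testing.assert_array_equal(eta1, eta2)

    def test_file_round_trip(self, logistic_data, tmp_path):
        X, y = logistic_data
        model = ridge_refit(X[["P00"]], y, penalty=0.1)
        model.to_json(tmp_path / "m.json")
        restored = PanelModel.from_json(tmp_path / "m.json")
        assert restored == model

    def test_missing_marker_errors(self, logistic_data):
        X, y = logistic_data
        model = ridge_refit(X[["P00", "P01"]], y, penalty=0.1)
        with pytest.raises(DataError, match="P01"):
            model.linear_predictor(X[["P00"]])
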