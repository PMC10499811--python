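"""Elastic-net logistic panel selection with stability analysis and ridge refit.

The classification signature is built in four stages:

1. :func:`enet_logistic_path` -- penalized logistic regression over a
   decreasing penalty path, with the elastic-net penalty applied to the
   (standardized) protein coefficients only; intercept and clinical
   covariates are unpenalized.  Candidates whose nonzero count exceeds the
   marker cap are discarded.
2. :func:`cv_tune` -- stratified (balanced) k-fold cross-validation of the
   held-out binomial log-likelihood over a dual grid of mixing parameter
   and marker-count cap.
3. :func:`selection_proportions` -- refit the tuned model on each training
   fold and record, per assay, the fraction of folds selecting it.
4. :func:`ridge_refit` -- final logistic fit of the stable markers under a
   ridge penalty (default 0.1), back-transformed to the original scale.

The solver is a proximal-Newton / coordinate-descent scheme on the
objective ``-(1/n) loglik + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)``
(glmnet parameterization), warm-started along the path, with an explicit
KKT check at every solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from lewypanel.errors import DataError

_WMIN = 1e-9
_PCLIP = 1e-9
_DIVERGE = 1e3


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def _fit_enet_logistic(
    Xs: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    alpha: float,
    lam: float,
    beta0: np.ndarray | None = None,
    free0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_outer: int = 200,
    max_inner: int = 400,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One penalized logistic fit at fixed (alpha, lambda).

    Xs: standardized penalized block; C: unpenalized columns (first is the
    intercept).  Returns (free_coefs, beta, diverged).
    """
    n, p = Xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    free = np.zeros(C.shape[1]) if free0 is None else free0.copy()
    active = set(np.flatnonzero(beta != 0.0).tolist())
    diverged = False

    for _ in range(max_outer):
        eta = C @ free + Xs @ beta
        prob = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        w = np.maximum(prob * (1 - prob), _WMIN)
        z = eta + (y - prob) / w

        # ---- penalized weighted least squares via coordinate descent ----
        r = z - C @ free - Xs @ beta
        for _ in range(max_inner):
            # unpenalized block jointly
            cw = C * w[:, None]
            free_new = np.linalg.solve(C.T @ cw, cw.T @ (r + C @ free))
            r += C @ (free - free_new)
            free = free_new
            max_delta = 0.0
            for j in list(active):
                xj = Xs[:, j]
                bj = beta[j]
                rho = (w * xj * (r + xj * bj)).sum() / n
                denom = (w * xj * xj).sum() / n + lam * (1 - alpha)
                bj_new = _soft(rho, lam * alpha) / denom
                if bj_new != bj:
                    r += xj * (bj - bj_new)
                    beta[j] = bj_new
                    max_delta = max(max_delta, abs(bj_new - bj))
                if beta[j] == 0.0:
                    active.discard(j)
            if max_delta < tol:
                # scan all coordinates for KKT violations on the quadratic
                grad = (Xs * (w * r)[:, None]).sum(axis=0) / n
                viol = np.flatnonzero(
                    (beta == 0.0) & (np.abs(grad) > lam * alpha + 1e-12)
                )
                new = [j for j in viol if j not in active]
                if not new:
                    break
                active.update(new)

        eta_new = C @ free + Xs @ beta
        if np.abs(beta).max(initial=0.0) > _DIVERGE or np.abs(free).max() > _DIVERGE:
            diverged = True
            break
        if np.max(np.abs(eta_new - eta)) < 1e-8:
            # verify KKT on the true logistic gradient before declaring done
            prob = np.clip(expit(eta_new), _PCLIP, 1 - _PCLIP)
            g = -Xs.T @ (y - prob) / n
            ok_zero = np.all(np.abs(g[beta == 0.0]) <= lam * alpha + 1e-7)
            nz = beta != 0.0
            ok_nz = np.all(
                np.abs(g[nz] + lam * alpha * np.sign(beta[nz])
                       + lam * (1 - alpha) * beta[nz]) <= 1e-7
            )
            gc = -C.T @ (y - prob) / n
            if ok_zero and ok_nz and np.all(np.abs(gc) <= 1e-7):
                break
            active.update(np.flatnonzero(np.abs(g) > lam * alpha).tolist())
    return free, beta, diverged


def lambda_max(
    Xs: np.ndarray, y: np.ndarray, C: np.ndarray, alpha: float
) -> float:
    """Smallest penalty with all protein coefficients zero (KKT at the null fit)."""
    free, _, _ = _fit_enet_logistic(
        np.zeros((len(y), 0)), y, C, alpha=1.0, lam=1.0
    )
    prob = np.clip(expit(C @ free), _PCLIP, 1 - _PCLIP)
    g = np.abs(Xs.T @ (y - prob)) / len(y)
    return float(g.max() / max(alpha, 1e-3))


def standardize(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column means, SDs (ddof 0), and the standardized array."""
    arr = X.to_numpy(dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0)
    if (sds == 0).any():
        bad = X.columns[sds == 0].tolist()
        raise DataError(f"constant assay columns cannot be standardized: {bad}")
    return means, sds, (arr - means) / sds


def _design(
    X: pd.DataFrame, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    n = len(X)
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    C = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    return C, ["intercept"] + list(covariates.columns)


@dataclass
class PanelCandidate:
    """One fitted point of the penalty path, optionally with CV scores."""

    alpha: float
    lam: float
    cap: int
    selected_assays: list[str]
    coefficients: dict[str, float]          # standardized scale, nonzero only
    intercept: float
    covariate_coefs: dict[str, float]
    cv_loglik: float = float("nan")          # mean held-out per-obs loglik
    cv_auc: float = float("nan")
    diverged: bool = False
    seed: int | None = None

    @property
    def n_markers(self) -> int:
        return len(self.selected_assays)


def enet_logistic_path(
    X: pd.DataFrame,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    alpha: float,
    lambda_grid: Sequence[float] | None = None,
    cap: int = 21,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> list[PanelCandidate]:
    """Fit the penalty path at fixed mixing parameter ``alpha``.

    ``X`` is the raw protein matrix (standardized internally; coefficients
    are reported on the standardized scale).  The path stops once the
    nonzero count exceeds ``cap``; a divergent fit (separation at small
    lambda) truncates the path with the candidate flagged.
    """
    if not 0 <= alpha <= 1:
        raise DataError(f"alpha must lie in [0, 1], got {alpha}")
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
        raise DataError("y must be binary with both classes present")
    if np.isnan(X.to_numpy(dtype=float)).any():
        raise DataError("X contains missing values; filter assays first")
    _, _, Xs = standardize(X)
    C, cov_names = _design(X, covariates)

    if lambda_grid is None:
        lmax = lambda_max(Xs, y, C, alpha)
        lambda_grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    out: list[PanelCandidate] = []
    beta = None
    free = None
    for lam in lambda_grid:
        free, beta, diverged = _fit_enet_logistic(
            Xs, y, C, alpha, float(lam), beta0=beta, free0=free
        )
        nz = np.flatnonzero(beta != 0.0)
        if len(nz) > cap:
            break
        out.append(
            PanelCandidate(
                alpha=alpha,
                lam=float(lam),
                cap=cap,
                selected_assays=[X.columns[j] for j in nz],
                coefficients={X.columns[j]: float(beta[j]) for j in nz},
                intercept=float(free[0]),
                covariate_coefs=dict(zip(cov_names[1:], map(float, free[1:]))),
                diverged=diverged,
            )
        )
        if diverged:
            break
    return out


# ---------------------------------------------------------------------------
# cross-validated tuning
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, k: int, seed: int):
    counts = np.bincount(y.astype(int))
    if counts.min() < k:
        raise DataError(f"each class needs >= k={k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _heldout_loglik(prob: np.ndarray, y: np.ndarray) -> float:
    prob = np.clip(prob, _PCLIP, 1 - _PCLIP)
    return float(np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _path_fits(
    X: pd.DataFrame,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    alpha: float,
    lambda_grid: np.ndarray,
    dfmax: int,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Raw (free, beta, means, sds) per lambda; truncated at dfmax nonzeros."""
    means, sds, Xs = standardize(X)
    C, _ = _design(X, covariates)
    fits = []
    beta = free = None
    for lam in lambda_grid:
        free, beta, diverged = _fit_enet_logistic(
            Xs, y, C, alpha, float(lam), beta0=beta, free0=free
        )
        if (beta != 0.0).sum() > dfmax or diverged:
            break
        fits.append((free.copy(), beta.copy(), means, sds))
    return fits


def cv_tune(
    X: pd.DataFrame,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    alpha_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
    cap_grid: Sequence[int] = (3, 5, 7, 10, 15, 21),
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    one_se: bool = False,
) -> list[PanelCandidate]:
    """Balanced 10-fold CV of the held-out likelihood over (alpha, cap) cells.

    For each cell, lambda maximizes the mean held-out per-observation
    binomial log-likelihood among path points whose full-data fit respects
    the cap (with ``one_se``, the largest lambda within one SE of that
    maximum).  Returns the full-data refit per cell with its CV scores.
    """
    from lewypanel.evaluate import roc_auc

    y = np.asarray(y, dtype=float)
    folds = _stratified_folds(y, k, seed)
    cap_grid = sorted(cap_grid)
    dfmax = max(cap_grid)
    results: list[PanelCandidate] = []
    for alpha in alpha_grid:
        _, _, Xs_full = standardize(X)
        C_full, _ = _design(X, covariates)
        lmax = lambda_max(Xs_full, y, C_full, alpha)
        grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
        full_path = enet_logistic_path(
            X, y, covariates, alpha, lambda_grid=grid, cap=dfmax
        )
        n_full = len(full_path)
        # fold fits on the shared grid
        loglik = np.full((k, n_full), np.nan)
        probs = [np.full(len(y), np.nan) for _ in range(n_full)]
        for f, (tr, te) in enumerate(folds):
            fits = _path_fits(
                X.iloc[tr], y[tr],
                None if covariates is None else covariates.iloc[tr],
                alpha, grid[:n_full], dfmax + 5,
            )
            C_te, _ = _design(X.iloc[te], None if covariates is None
                              else covariates.iloc[te])
            X_te = X.iloc[te].to_numpy(dtype=float)
            for li, (free, beta, means, sds) in enumerate(fits):
                eta = C_te @ free + ((X_te - means) / sds) @ beta
                pr = expit(eta)
                loglik[f, li] = _heldout_loglik(pr, y[te])
                probs[li][te] = pr
        mean_ll = np.nanmean(loglik, axis=0)
        n_folds_ok = (~np.isnan(loglik)).sum(axis=0)
        nzs = np.array([c.n_markers for c in full_path])
        for cap in cap_grid:
            eligible = np.flatnonzero((nzs <= cap) & (n_folds_ok == k))
            if eligible.size == 0:
                continue
            best = eligible[np.argmax(mean_ll[eligible])]
            if one_se:
                se = np.nanstd(loglik[:, best], ddof=1) / np.sqrt(k)
                within = eligible[mean_ll[eligible] >= mean_ll[best] - se]
                best = within[0]  # largest lambda within one SE
            cand = full_path[best]
            pr = probs[best]
            cand = PanelCandidate(
                alpha=float(alpha), lam=cand.lam, cap=int(cap),
                selected_assays=list(cand.selected_assays),
                coefficients=dict(cand.coefficients),
                intercept=cand.intercept,
                covariate_coefs=dict(cand.covariate_coefs),
                cv_loglik=float(mean_ll[best]),
                cv_auc=float(roc_auc(pr, y)[0]) if not np.isnan(pr).any()
                else float("nan"),
                diverged=cand.diverged,
                seed=seed,
            )
            results.append(cand)
    if not results:
        raise DataError("no candidate respected the cap on any path")
    return results


def choose_model(
    candidates: Sequence[PanelCandidate], auc_tol: float = 0.005
) -> PanelCandidate:
    """Highest CV AUC (to ``auc_tol``), then fewest markers, then smaller alpha."""
    cands = [c for c in candidates if not np.isnan(c.cv_auc)]
    if not cands:
        raise DataError("no candidates with a CV AUC")
    best_auc = max(c.cv_auc for c in cands)
    near = [c for c in cands if c.cv_auc >= best_auc - auc_tol]
    near.sort(key=lambda c: (c.n_markers, c.alpha, -c.cv_auc))
    return near[0]


def selection_proportions(
    X: pd.DataFrame,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    candidate: PanelCandidate,
    k: int = 10,
    seed: int = 0,
    n_lambda_warm: int = 25,
) -> pd.Series:
    """Fraction of CV training folds in which each assay is selected.

    Refits the tuned (alpha, lambda) model on each of the k training folds
    (warm-started along a short path down to the tuned lambda) and counts
    nonzero coefficients.
    """
    y = np.asarray(y, dtype=float)
    folds = _stratified_folds(y, k, seed)
    hits = pd.Series(0.0, index=X.columns)
    for tr, _ in folds:
        X_tr = X.iloc[tr]
        cov_tr = None if covariates is None else covariates.iloc[tr]
        _, _, Xs = standardize(X_tr)
        C, _ = _design(X_tr, cov_tr)
        lmax = lambda_max(Xs, y[tr], C, candidate.alpha)
        lmax = max(lmax, candidate.lam * 1.0001)
        grid = np.geomspace(lmax, candidate.lam, n_lambda_warm)
        beta = free = None
        for lam in grid:
            free, beta, _ = _fit_enet_logistic(
                Xs, y[tr], C, candidate.alpha, float(lam), beta0=beta, free0=free
            )
        hits[beta != 0.0] += 1.0
    return hits / k


# ---------------------------------------------------------------------------
# ridge refit & panel model
# ---------------------------------------------------------------------------

@dataclass
class PanelModel:
    """Final logistic signature on the original NPX scale.

    ``marker_coefs``/``intercept`` are back-transformed from the
    standardized-scale ridge fit, so the linear predictor is
    ``intercept + sum_j coef_j * npx_j + sum_c cov_coef_c * cov_c``.
    """

    markers: list[str]
    intercept: float
    marker_coefs: dict[str, float]
    covariate_names: list[str]
    covariate_coefs: dict[str, float]
    standardization: dict[str, dict[str, float]]  # {"means": {...}, "sds": {...}}
    ridge_penalty: float
    training_contrast: str = ""
    seed: int | None = None

    def linear_predictor(
        self,
        X: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
    ) -> np.ndarray:
        missing = [a for a in self.markers if a not in X.columns]
        if missing:
            raise DataError(f"matrix lacks panel markers: {missing}")
        eta = np.full(len(X), self.intercept, dtype=float)
        for a in self.markers:
            eta += self.marker_coefs[a] * X[a].to_numpy(dtype=float)
        for c in self.covariate_names:
            if covariates is None or c not in covariates.columns:
                raise DataError(f"missing covariate column {c!r}")
            eta += self.covariate_coefs[c] * covariates[c].to_numpy(dtype=float)
        return eta

    def predict_proba(
        self, X: pd.DataFrame, covariates: pd.DataFrame | None = None
    ) -> np.ndarray:
        return expit(self.linear_predictor(X, covariates))

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PanelModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(**d)


def ridge_refit(
    X: pd.DataFrame,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    penalty: float = 0.1,
    training_contrast: str = "",
    seed: int | None = None,
) -> PanelModel:
    """Logistic ridge (alpha=0) fit of the selected markers.

    The penalty applies to the standardized marker coefficients;
    covariates and the intercept are unpenalized.  Coefficients are
    back-transformed to the original NPX scale.
    """
    if X.shape[1] < 1:
        raise DataError("ridge refit needs at least one marker")
    y = np.asarray(y, dtype=float)
    means, sds, Xs = standardize(X)
    C, cov_names = _design(X, covariates)
    free, beta_std, diverged = _fit_enet_logistic(
        Xs, y, C, alpha=0.0, lam=penalty
    )
    if diverged:
        raise DataError("ridge refit diverged")
    coef_orig = beta_std / sds
    intercept = float(free[0] - np.sum(beta_std * means / sds))
    return PanelModel(
        markers=list(X.columns),
        intercept=intercept,
        marker_coefs=dict(zip(X.columns, map(float, coef_orig))),
        covariate_names=cov_names[1:],
        covariate_coefs=dict(zip(cov_names[1:], map(float, free[1:]))),
        standardization={
            "means": dict(zip(X.columns, map(float, means))),
            "sds": dict(zip(X.columns, map(float, sds))),
        },
        ridge_penalty=float(penalty),
        training_contrast=training_contrast,
        seed=seed,
    )
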