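"""ROC/AUC machinery, resampling confidence intervals, DeLong comparison,
external validation, covariate-conditioned correlations and stage ANOVA."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lewypanel.errors import DataError
from lewypanel.panel import PanelModel, ridge_refit, _stratified_folds


@dataclass
class ROCSummary:
    """AUC with a resampling 95% confidence interval and the ROC curve."""

    auc: float
    ci_low: float
    ci_high: float
    method: str                       # bootstrap_percentile | repeated_cv_percentile
    n_resamples: int
    seed: int | None
    curve: pd.DataFrame = field(default=None)  # type: ignore[assignment]  # FPR/TPR

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "method": self.method, "n_resamples": self.n_resamples,
            "seed": self.seed,
        }


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if not ((labels == 0) | (labels == 1)).all():
        raise DataError("labels must be 0/1")
    if labels.min() == labels.max():
        raise DataError("both classes must be present")
    return labels


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2).

    Returns ``(auc, curve)`` where the curve is a threshold-sweep
    (FPR, TPR) table starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    order = np.argsort(-scores, kind="mergesort")
    sl = labels[order]
    ss = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tps = np.cumsum(sl)[distinct]
    fps = np.cumsum(1 - sl)[distinct]
    curve = pd.DataFrame(
        {"fpr": np.r_[0.0, fps / n0], "tpr": np.r_[0.0, tps / n1]}
    )
    return float(auc), curve


def bootstrap_auc_ci(
    scores, labels, B: int = 100, seed: int = 0
) -> ROCSummary:
    """Percentile bootstrap CI with resampling stratified within each class."""
    if B < 50:
        raise DataError("need B >= 50 bootstrap resamples")
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    aucs = np.empty(B)
    for b in range(B):
        take = np.r_[rng.choice(idx0, size=len(idx0), replace=True),
                     rng.choice(idx1, size=len(idx1), replace=True)]
        aucs[b], _ = roc_auc(scores[take], labels[take])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    auc, curve = roc_auc(scores, labels)
    return ROCSummary(
        auc=auc, ci_low=float(lo), ci_high=float(hi),
        method="bootstrap_percentile", n_resamples=B, seed=seed, curve=curve,
    )


def repeated_cv_auc(
    X: pd.DataFrame,
    y,
    covariates: pd.DataFrame | None = None,
    ridge_penalty: float = 0.1,
    k: int = 5,
    repeats: int = 1000,
    seed: int = 0,
    pool_folds: bool = True,
) -> ROCSummary:
    """Repeated stratified k-fold CV of the ridge-refit panel model.

    The full model pipeline (standardization + ridge refit) runs inside
    every training fold.  Per repeat, held-out predictions are pooled over
    the k folds into one AUC (``pool_folds=False`` averages fold AUCs
    instead); the summary is the mean AUC with a percentile CI over repeats.
    """
    y = _check_labels(y)
    aucs = np.empty(repeats)
    for r in range(repeats):
        folds = _stratified_folds(y, k, seed + r)
        pooled = np.full(len(y), np.nan)
        fold_aucs = []
        for tr, te in folds:
            model = ridge_refit(
                X.iloc[tr], y[tr],
                None if covariates is None else covariates.iloc[tr],
                penalty=ridge_penalty,
            )
            pr = model.predict_proba(
                X.iloc[te],
                None if covariates is None else covariates.iloc[te],
            )
            pooled[te] = pr
            if len(np.unique(y[te])) == 2:
                fold_aucs.append(roc_auc(pr, y[te])[0])
        aucs[r] = (
            roc_auc(pooled, y)[0] if pool_folds else float(np.mean(fold_aucs))
        )
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return ROCSummary(
        auc=float(np.mean(aucs)), ci_low=float(lo), ci_high=float(hi),
        method="repeated_cv_percentile", n_resamples=repeats, seed=seed,
    )


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """Per-case and per-control placement values (DeLong V10/V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    v10 = np.empty(n1)
    for i, s in enumerate(pos):
        v10[i] = ((s > neg).sum() + 0.5 * (s == neg).sum()) / n0
    v01 = np.empty(n0)
    for i, s in enumerate(neg):
        v01[i] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / n1
    return v10, v01


def delong_test(scores_1, scores_2, labels) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUCs on the same samples.

    Returns ``(auc_1, auc_2, z, p_two_sided)``.  A zero-variance
    difference with equal AUCs reports p = 1.
    """
    labels = _check_labels(labels)
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if len(s1) != len(labels) or len(s2) != len(labels):
        raise DataError("scores and labels must be paired (same length)")
    v10_1, v01_1 = _placements(s1, labels)
    v10_2, v01_2 = _placements(s2, labels)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    n1, n0 = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0:
        if np.isclose(auc1, auc2):
            return auc1, auc2, 0.0, 1.0
        raise DataError("zero variance of the AUC difference with unequal AUCs")
    z = (auc1 - auc2) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return auc1, auc2, float(z), p


def hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    """Analytic AUC standard error (binormal-free approximation)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

def external_validate(
    model: PanelModel,
    X_new: pd.DataFrame,
    labels_new,
    covariates_new: pd.DataFrame | None = None,
    B: int = 100,
    seed: int = 0,
) -> ROCSummary:
    """Apply a frozen panel model to a new cohort -- no refitting.

    Coefficients (already carrying the training standardization) are
    applied verbatim; performance is summarized with a stratified
    bootstrap CI.
    """
    scores = model.linear_predictor(X_new, covariates_new)
    return bootstrap_auc_ci(scores, labels_new, B=B, seed=seed)


# ---------------------------------------------------------------------------
# correlations & stage trends
# ---------------------------------------------------------------------------

def partial_spearman_matrix(
    variables: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    tiers: tuple[float, ...] = (0.05, 0.01, 0.001),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations conditioned on covariates.

    Each variable is rank-transformed, the ranks are residualized on the
    covariates (plus intercept), and Pearson correlations of the residuals
    are returned together with a BH-q significance tier matrix
    (0 = not significant, i = passes ``tiers[i-1]``) computed over the
    upper triangle.  Constant variables yield missing correlations.
    """
    cols = list(variables.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    pvals = []
    for i, j in pairs:
        sub = variables[[cols[i], cols[j]]]
        if covariates is not None:
            sub = pd.concat([sub, covariates], axis=1)
        sub = sub.dropna()
        if len(sub) < 10:
            raise DataError(
                f"need >=10 complete cases for pair ({cols[i]}, {cols[j]})"
            )
        x = sub[cols[i]].to_numpy(dtype=float)
        yv = sub[cols[j]].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(yv) == 0:
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            pvals.append(1.0)
            continue
        rx = stats.rankdata(x)
        ry = stats.rankdata(yv)
        n_cov = 0
        if covariates is not None:
            # rank the covariates too (Spearman convention) so monotone
            # confounder relationships are removed, not just linear ones
            C = np.column_stack(
                [np.ones(len(sub))]
                + [stats.rankdata(sub[c].to_numpy(dtype=float))
                   for c in covariates.columns]
            )
            n_cov = C.shape[1] - 1
            rx = rx - C @ np.linalg.lstsq(C, rx, rcond=None)[0]
            ry = ry - C @ np.linalg.lstsq(C, ry, rcond=None)[0]
        else:
            rx = rx - rx.mean()
            ry = ry - ry.mean()
        denom = np.sqrt((rx @ rx) * (ry @ ry))
        rho = float(rx @ ry / denom) if denom > 0 else np.nan
        r.iloc[i, j] = r.iloc[j, i] = rho
        df = len(sub) - 2 - n_cov
        if np.isnan(rho) or abs(rho) >= 1 or df <= 0:
            p = 0.0 if not np.isnan(rho) and abs(rho) >= 1 else 1.0
        else:
            t = rho * np.sqrt(df / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df))
        pvals.append(p)
    from lewypanel.diff import bh_fdr

    qvals = bh_fdr(np.array(pvals)) if pvals else np.array([])
    for (i, j), q in zip(pairs, qvals):
        tier = sum(q < t for t in sorted(tiers, reverse=True))
        pmat.iloc[i, j] = pmat.iloc[j, i] = tier
    return r, pmat.astype(int)


def stage_trend_anova(values, ordered_stage) -> float:
    """One-way fixed-effects ANOVA F-test p-value across ordinal stages."""
    values = np.asarray(values, dtype=float)
    stage = np.asarray(ordered_stage)
    keep = ~np.isnan(values)
    values, stage = values[keep], stage[keep]
    groups = [values[stage == s] for s in pd.unique(stage)]
    if len(groups) < 2:
        raise DataError("stage ANOVA needs at least two stages")
    if any(len(g) < 2 for g in groups):
        raise DataError("every stage needs >= 2 observations")
    return float(stats.f_oneway(*groups).pvalue)
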