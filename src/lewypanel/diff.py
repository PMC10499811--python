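"""Nested-linear-model differential abundance with BH-FDR.

For each protein, abundance is modeled as the response in
``npx ~ intercept + age + sex + group`` and compared against the
covariate-only base model with an exact F-test; the group coefficient is the
log2 fold-change.  A logistic variant (protein added to a diagnosis model,
likelihood-ratio test) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lewypanel.errors import DataError
from lewypanel.npx import NPXMatrix, SampleMetadata


@dataclass
class ContrastResult:
    """Per-protein result for one pairwise group contrast."""

    assay_id: str
    beta: float
    se: float
    p: float
    q: float
    fold_change: float
    n_used: int


def fold_change(beta: float) -> float:
    """Linear fold-change implied by a log2-scale coefficient."""
    return float(2.0 ** beta)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns with (near-)zero pivots in a pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() or 1.0)
        bad = [names[i] for i in np.flatnonzero(diag <= tol)]
        raise DataError(f"rank-deficient design; collinear columns: {bad or names}")


def nested_lm_test(
    y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """Exact F-test for adding a binary group term to a covariate base model.

    Returns ``(beta, se, p)`` where ``beta`` is the group coefficient
    (log2 fold-change of the non-reference group) from the full OLS fit.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    keep = ~np.isnan(y)
    y, group = y[keep], group[keep]
    names = ["intercept"]
    cols = [np.ones_like(y)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = C[keep]
        if isinstance(covariates, pd.DataFrame):
            names += list(covariates.columns)
        else:
            names += [f"cov{i}" for i in range(C.shape[1])]
        cols.append(C)
    n0, n1 = int((group == 0).sum()), int((group == 1).sum())
    if n0 + n1 != len(group):
        raise DataError("group must be a 0/1 indicator")
    if min(n0, n1) < 3:
        raise DataError(f"need >=3 samples per group, got {n0}/{n1}")
    if n0 == 0 or n1 == 0:
        raise DataError("group indicator is constant")
    X_red = np.column_stack(cols)
    X_full = np.column_stack(cols + [group])
    _check_design(X_full, names + ["group"])

    beta_full, rss_full = _ols_rss(X_full, y)
    _, rss_red = _ols_rss(X_red, y)
    df_full = len(y) - X_full.shape[1]
    if df_full <= 0:
        raise DataError("not enough residual degrees of freedom")
    F = (rss_red - rss_full) / (rss_full / df_full)
    p = float(stats.f.sf(max(F, 0.0), 1, df_full))
    sigma2 = rss_full / df_full
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    return float(beta_full[-1]), se, p


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def nested_logistic_test(
    y_protein: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Sensitivity-analysis variant: protein added to a diagnosis model.

    Fits ``group ~ intercept + covariates (+ protein)`` by maximum
    likelihood and reports the protein coefficient, its SE, and the
    likelihood-ratio chi-square p-value.  Note the coefficient is NOT a
    log2 fold-change in this direction.
    """
    import statsmodels.api as sm

    y_protein = np.asarray(y_protein, dtype=float)
    group = np.asarray(group, dtype=float)
    keep = ~np.isnan(y_protein)
    y_protein, group = y_protein[keep], group[keep]
    base = np.ones((len(group), 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        base = np.column_stack([base, C[keep]])
    full = np.column_stack([base, y_protein])
    fit_full = sm.Logit(group, full).fit(disp=0)
    fit_red = sm.Logit(group, base).fit(disp=0)
    lr = 2 * (fit_full.llf - fit_red.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), 1))
    return float(fit_full.params[-1]), float(fit_full.bse[-1]), p


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _covariate_columns(meta_rows: pd.DataFrame) -> pd.DataFrame:
    """Age (centered) and sex (male=1) design columns."""
    age = meta_rows["age"].astype(float)
    return pd.DataFrame(
        {
            "age_centered": age - age.mean(),
            "sex_male": (meta_rows["sex"].astype(str) == "M").astype(float),
        },
        index=meta_rows.index,
    )


def contrast_table(
    m: NPXMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    adjust_covariates: bool = True,
    alpha_q: float = 0.05,
    alpha_p: float = 0.05,
) -> pd.DataFrame:
    """Per-assay nested-model contrast ``group_b`` vs ``group_a`` (reference).

    Positive beta means higher abundance in ``group_b``.  BH adjustment is
    applied over the assays of this contrast only.  Per-assay fit failures
    become rows with missing statistics and a ``reason`` code.

    Returns a DataFrame with columns assay_id, beta, se, p, q, fold_change,
    n_used, sig_q05, sig_p05, reason.
    """
    table = meta.aligned_to(m)
    mask = table["diagnosis"].isin([group_a, group_b])
    if "is_bridge" in table.columns:
        mask &= ~table["is_bridge"].astype(bool)
    sub = table.loc[mask]
    if (sub["diagnosis"] == group_a).sum() == 0 or (sub["diagnosis"] == group_b).sum() == 0:
        raise DataError(f"both groups {group_a!r} and {group_b!r} must be present")
    y_mat = m.values.loc[sub.index].to_numpy()
    group = (sub["diagnosis"] == group_b).to_numpy(dtype=float)
    cov = _covariate_columns(sub) if adjust_covariates else None

    rows = []
    complete = ~np.isnan(y_mat).any(axis=0)
    # fast path: shared design for all fully observed assays
    if complete.any():
        betas, ses, ps = _vectorized_nested_lm(
            y_mat[:, complete],
            group,
            cov.to_numpy() if cov is not None else None,
        )
    idx_complete = np.flatnonzero(complete)
    pos = {j: k for k, j in enumerate(idx_complete)}
    for j, assay in enumerate(m.assay_ids):
        if complete[j]:
            k = pos[j]
            rows.append(
                {"assay_id": assay, "beta": betas[k], "se": ses[k], "p": ps[k],
                 "n_used": len(group), "reason": ""}
            )
        else:
            try:
                yj = y_mat[:, j]
                keep = ~np.isnan(yj)
                b, s, p = nested_lm_test(
                    yj[keep], group[keep],
                    cov.to_numpy()[keep] if cov is not None else None,
                )
                rows.append(
                    {"assay_id": assay, "beta": b, "se": s, "p": p,
                     "n_used": int(keep.sum()), "reason": ""}
                )
            except DataError as exc:
                rows.append(
                    {"assay_id": assay, "beta": np.nan, "se": np.nan,
                     "p": np.nan, "n_used": 0, "reason": str(exc)}
                )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    out["fold_change"] = 2.0 ** out["beta"]
    out["sig_q05"] = (out["q"] < alpha_q).fillna(False)
    out["sig_p05"] = (out["p"] < alpha_p).fillna(False)
    return out[
        ["assay_id", "beta", "se", "p", "q", "fold_change", "n_used",
         "sig_q05", "sig_p05", "reason"]
    ]


def _vectorized_nested_lm(
    Y: np.ndarray, group: np.ndarray, C: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """F-tests for many responses sharing one design (no missing values)."""
    n = len(group)
    ones = np.ones((n, 1))
    X_red = ones if C is None else np.column_stack([ones, C])
    X_full = np.column_stack([X_red, group])
    _check_design(X_full, [f"c{i}" for i in range(X_full.shape[1])])
    coef_full, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    coef_red, *_ = np.linalg.lstsq(X_red, Y, rcond=None)
    rss_full = ((Y - X_full @ coef_full) ** 2).sum(axis=0)
    rss_red = ((Y - X_red @ coef_red) ** 2).sum(axis=0)
    df_full = n - X_full.shape[1]
    if df_full <= 0:
        raise DataError("not enough residual degrees of freedom")
    F = np.maximum(rss_red - rss_full, 0.0) / (rss_full / df_full)
    p = stats.f.sf(F, 1, df_full)
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    se = np.sqrt(rss_full / df_full * xtx_inv[-1, -1])
    return coef_full[-1], se, p
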