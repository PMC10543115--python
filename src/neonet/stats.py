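"""Group statistics: paired tests, ANCOVA, FDR, partial correlation.

Longitudinal contrasts (preterm at birth vs the same infants at
term-equivalent age) use the paired t-test; the cross-sectional contrast
(preterm at term-equivalent age vs term-born controls) uses ANCOVA —
ordinary least squares of the metric on a group indicator plus covariates
(age at scan, head circumference, number of gestation embryos, optionally
head motion). Families of p-values are corrected by Benjamini–Hochberg FDR
at q = 0.05. Metric–FA associations use partial correlation on covariate
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "paired_t",
    "ancova_group_effect",
    "fdr_bh",
    "partial_correlation",
    "hemispheric_asymmetry",
]


@dataclass
class StatResult:
    effect: float          # group mean difference / adjusted difference, metric units
    statistic: float       # t (or F) value
    p: float               # two-sided p
    q: float | None = None  # BH-adjusted value, filled once a family is corrected
    significant: bool | None = None
    df: float | None = None


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Classical paired t-test on x - y, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return StatResult(effect=0.0, statistic=0.0, p=1.0, df=n - 1)
        raise ValueError("zero variance of nonzero differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return StatResult(effect=float(d.mean()), statistic=float(t), p=float(p), df=n - 1)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares returning (beta, residuals, residual df); raises on rank deficiency."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the collinear columns
        _, r = np.linalg.qr(X)
        dep = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max()))
        raise ValueError(f"design matrix is rank deficient (collinear columns {dep.tolist()})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid, float(n - k)


def ancova_group_effect(y: np.ndarray, group: np.ndarray,
                        covariates: np.ndarray | None = None) -> StatResult:
    """Covariate-adjusted two-group comparison via OLS.

    ``group`` is any two-level vector; the effect is the coefficient of the
    group indicator in y ~ 1 + group + covariates, tested by its t
    statistic (equivalent to the one-way ANCOVA F for two groups).
    """
    y = np.asarray(y, dtype=float)
    levels = np.unique(np.asarray(group))
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    g = (np.asarray(group) == levels[1]).astype(float)
    cols = [np.ones_like(y), g]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    beta, resid, df = _ols(y, X)
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    # a numerically perfect fit (e.g. constant outcome) carries no evidence
    y_scale = max(1.0, float(np.abs(y - y.mean()).max()))
    if se <= 1e-12 * y_scale:
        return StatResult(effect=float(beta[1]), statistic=0.0, p=1.0, df=df)
    t = beta[1] / se
    p = 2 * sps.t.sf(abs(t), df=df)
    return StatResult(effect=float(beta[1]), statistic=float(t), p=float(p), df=df)


def fdr_bh(p_values: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (reject flags, monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return reject, q


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    p-value from the t transform with n - 2 - n_cov degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        n_cov = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        n_cov = C.shape[1]
        X = np.column_stack([np.ones(n), C])
        _, rx, _ = _ols(x, X)
        _, ry, _ = _ols(y, X)
    if n <= n_cov + 2:
        raise ValueError("not enough observations for the requested covariates")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - n_cov
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * sps.t.sf(abs(t), df=df))
    return r, p


def hemispheric_asymmetry(left: dict[str, np.ndarray], right: dict[str, np.ndarray],
                          q_level: float = 0.05) -> dict[str, StatResult]:
    """Paired t of left vs right per metric, FDR-corrected across metrics.

    ``left`` and ``right`` map metric name -> per-subject values.
    """
    if set(left) != set(right):
        raise ValueError("left and right metric sets differ")
    names = sorted(left)
    results = {m: paired_t(left[m], right[m]) for m in names}
    reject, q = fdr_bh(np.array([results[m].p for m in names]), q_level=q_level)
    for m, rej, qv in zip(names, reject, q):
        results[m].q = float(qv)
        results[m].significant = bool(rej)
    return results
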