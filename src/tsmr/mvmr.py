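"""Multivariable MR: each exposure's direct effect conditional on the others.

Estimators: weighted least squares without intercept (MVMR-IVW, with
multiplicative random-effects SE scaling), the same fit with an intercept
after sign orientation (MVMR-Egger), weighted median (L1) regression with
bootstrap SEs, and a lasso variant that gives every SNP its own penalized
intercept — SNPs whose intercept is shrunk exactly to zero form the valid
set, the penalty is chosen as the largest valid set whose heterogeneity Q
stays below the chi-square 0.05 critical value, and the final estimate is a
post-lasso IVW refit on that set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    InsufficientInstrumentsError,
    LassoDegenerateError,
)
from .summary_data import HarmonizedSet
from .uvmr import MRResult


@dataclass
class MVMRResult:
    """Per-exposure direct-effect estimates from one multivariable fit."""

    method: str
    exposure_ids: list[str]
    estimates: list[MRResult]  # one per exposure, same order
    conditional_q: tuple[float, int, float]  # (Q_A, df = k - M, p)
    conditional_f: pd.Series | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    lasso_valid_set: list[str] | None = None
    lambda_: float | None = None

    def __post_init__(self):
        if len(self.estimates) != len(self.exposure_ids):
            raise ConfigurationError("one estimate per exposure required")


def _design(h: HarmonizedSet):
    x = h.beta_X
    y = h.beta_Y
    w = h.se_Y**-2
    return x, y, w


def _check_rank(x: np.ndarray, exposure_ids):
    xs = x / np.linalg.norm(x, axis=0, keepdims=True)
    corr = xs.T @ xs
    m = x.shape[1]
    for i in range(m):
        for j in range(i + 1, m):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise CollinearityError(
                    f"exposure effect columns '{exposure_ids[i]}' and "
                    f"'{exposure_ids[j]}' are collinear"
                )
    if np.linalg.matrix_rank(x) < m:
        raise CollinearityError("exposure effect matrix is rank deficient")


def _wls(x, y, w):
    """Weighted LS solve; returns (coef, unscaled covariance, weighted RSS)."""
    xtw = x.T * w
    xtwx = xtw @ x
    coef = np.linalg.solve(xtwx, xtw @ y)
    resid = y - x @ coef
    return coef, np.linalg.inv(xtwx), float(np.sum(w * resid**2))


def conditional_f_statistics(h: HarmonizedSet) -> pd.Series:
    """Mean instrument strength of each exposure after residualizing its
    effects on the other exposures (reported, never filtered on).

    For exposure m: regress its effect column on the remaining columns with
    weights se_X[:, m]^-2 and average resid_j^2 / se_X[j, m]^2.
    """
    x = h.beta_X
    out = {}
    for m, tid in enumerate(h.exposure_ids):
        others = np.delete(x, m, axis=1)
        target = x[:, m]
        se = h.se_X[:, m]
        if others.shape[1] == 0:
            resid = target
        else:
            coef, _, _ = _wls(others, target, se**-2)
            resid = target - others @ coef
        out[tid] = float(np.mean(resid**2 / se**2))
    return pd.Series(out, name="conditional_f")


def mvmr_ivw(h: HarmonizedSet) -> MVMRResult:
    """Multivariable IVW: WLS of beta_Y on the exposure-effect matrix without
    intercept, weights se_Y^-2; SEs scaled by max(1, sqrt(Q_A/(k-M)))."""
    x, y, w = _design(h)
    k, m = x.shape
    if m < 1 or k < m + 2:
        raise InsufficientInstrumentsError(f"MVMR-IVW requires k >= M + 2 (k={k}, M={m})")
    _check_rank(x, h.exposure_ids)
    coef, cov, q_a = _wls(x, y, w)
    df = k - m
    scale = max(1.0, np.sqrt(q_a / df))
    ses = np.sqrt(np.diag(cov)) * scale
    estimates = [
        MRResult.from_beta("mvmr_ivw", k, coef[j], ses[j]) for j in range(m)
    ]
    return MVMRResult(
        method="mvmr_ivw",
        exposure_ids=list(h.exposure_ids),
        estimates=estimates,
        conditional_q=(q_a, df, float(sps.chi2.sf(q_a, df))),
        conditional_f=conditional_f_statistics(h),
    )


def mvmr_egger(h: HarmonizedSet, orient_by: int = 0) -> MVMRResult:
    """MVMR-Egger: the IVW fit plus an intercept column, after flipping each
    SNP row's signs so the ``orient_by`` exposure's effects are non-negative."""
    x, y, w = _design(h)
    k, m = x.shape
    if not (0 <= orient_by < m):
        raise ConfigurationError(f"orient_by={orient_by} out of range for M={m}")
    if k < m + 3:
        raise InsufficientInstrumentsError(f"MVMR-Egger requires k >= M + 3 (k={k}, M={m})")
    _check_rank(x, h.exposure_ids)
    flip = np.sign(x[:, orient_by])
    flip[flip == 0] = 1.0
    xo = x * flip[:, None]
    yo = y * flip
    design = np.column_stack([np.ones(k), xo])
    coef, cov, q_a = _wls(design, yo, w)
    df = k - m - 1
    scale = max(1.0, np.sqrt(q_a / df))
    ses = np.sqrt(np.diag(cov)) * scale
    estimates = [
        MRResult.from_beta("mvmr_egger", k, coef[1 + j], ses[1 + j]) for j in range(m)
    ]
    int_p = float(2 * sps.norm.sf(abs(coef[0] / ses[0]))) if ses[0] > 0 else 1.0
    return MVMRResult(
        method="mvmr_egger",
        exposure_ids=list(h.exposure_ids),
        estimates=estimates,
        conditional_q=(q_a, df, float(sps.chi2.sf(q_a, df))),
        conditional_f=conditional_f_statistics(h),
        intercept=float(coef[0]),
        intercept_se=float(ses[0]),
        intercept_p=int_p,
    )


def _weighted_l1_fit(x, y, w):
    """Median (0.5-quantile) regression with weights, no intercept.

    The check loss is positively homogeneous, so scaling row j by w_j turns
    sum_j w_j rho(y_j - x_j b) into the plain loss on (w*y, w*x); statsmodels'
    QuantReg then solves the weighted problem directly.
    """
    from statsmodels.regression.quantile_regression import QuantReg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = QuantReg(y * w, x * w[:, None])
        return np.asarray(model.fit(q=0.5, max_iter=2000).params, dtype=float)


def mvmr_weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MVMRResult:
    """Weighted median (L1) regression of beta_Y on the exposure matrix with
    weights se_Y^-2 and no intercept; SEs by seeded parametric bootstrap."""
    x, y, w = _design(h)
    k, m = x.shape
    if k < m + 3:
        raise InsufficientInstrumentsError(
            f"MVMR weighted median requires k >= M + 3 (k={k}, M={m})"
        )
    _check_rank(x, h.exposure_ids)
    coef = _weighted_l1_fit(x, y, w)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, m))
    for b in range(n_boot):
        xs = rng.normal(x, h.se_X)
        ys = rng.normal(y, h.se_Y)
        boots[b] = _weighted_l1_fit(xs, ys, w)
    ses = boots.std(axis=0, ddof=1)
    resid = y - x @ coef
    q = float(np.sum(w * resid**2))
    df = k - m
    estimates = [
        MRResult.from_beta("mvmr_weighted_median", k, coef[j], ses[j])
        for j in range(m)
    ]
    return MVMRResult(
        method="mvmr_weighted_median",
        exposure_ids=list(h.exposure_ids),
        estimates=estimates,
        conditional_q=(q, df, float(sps.chi2.sf(q, df))),
        conditional_f=conditional_f_statistics(h),
    )


def _lasso_path_fit(x, y, w, lam, tol=1e-12, max_iter=1000, warm=None):
    """Minimize sum_j w_j (y_j - a_j - x_j theta)^2 + lam * sum_j |a_j|.

    Jointly convex; alternate the closed-form WLS solve for theta with the
    per-SNP soft-threshold update a_j = soft(y_j - x_j theta, lam/(2 w_j)).
    ``warm`` optionally seeds (theta, alpha) from a neighbouring penalty.
    """
    k, m = x.shape
    if warm is not None:
        theta, alpha = warm[0].copy(), warm[1].copy()
    else:
        alpha = np.zeros(k)
        theta, _, _ = _wls(x, y, w)
    for _ in range(max_iter):
        r = y - x @ theta
        thresh = lam / (2.0 * w)
        alpha_new = np.sign(r) * np.maximum(np.abs(r) - thresh, 0.0)
        theta_new, _, _ = _wls(x, y - alpha_new, w)
        if np.max(np.abs(alpha_new - alpha)) < tol and np.max(np.abs(theta_new - theta)) < tol:
            alpha, theta = alpha_new, theta_new
            break
        alpha, theta = alpha_new, theta_new
    return theta, alpha


def mr_lasso(h: HarmonizedSet, lambda_grid=None, n_lambda: int = 50) -> MVMRResult:
    """Lasso-based invalid-instrument selection with post-lasso IVW refit.

    Each SNP gets its own intercept penalized by lambda * |a_j|; SNPs whose
    intercept is exactly zero at a given lambda form the candidate valid set.
    The selected lambda yields the largest valid set whose IVW heterogeneity
    Q is below the chi-square 0.95 quantile (df = set size - M); the reported
    estimates are the IVW refit on that set.  Works for M = 1 as well.
    """
    x, y, w = _design(h)
    k, m = x.shape
    if k < m + 3:
        raise InsufficientInstrumentsError(f"MR-lasso requires k >= M + 3 (k={k}, M={m})")
    _check_rank(x, h.exposure_ids)

    if lambda_grid is None:
        theta0, _, _ = _wls(x, y, w)
        r0 = y - x @ theta0
        lam_max = float(np.max(2.0 * w * np.abs(r0))) * (1 + 1e-9)
        if lam_max <= 0:
            lam_max = 1.0
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    best = None  # (size, lam, valid_mask)
    warm = None
    for lam in lambda_grid:
        theta, alpha = _lasso_path_fit(x, y, w, lam, warm=warm)
        warm = (theta, alpha)
        valid = np.abs(alpha) < 1e-8
        size = int(valid.sum())
        if size < m + 2:  # too small for a stable post-lasso refit
            continue
        sub = h.subset(valid)
        coef, _, q = _wls(sub.beta_X, sub.beta_Y, sub.se_Y**-2)
        if q < sps.chi2.ppf(0.95, size - m):
            if best is None or size > best[0]:
                best = (size, float(lam), valid)
    if best is None:
        raise LassoDegenerateError(
            "no penalty yields a homogeneous valid set larger than M; "
            "report the IVW estimate instead"
        )
    size, lam, valid = best
    refit = mvmr_ivw(h.subset(valid))
    for est in refit.estimates:
        est.method = "mr_lasso"
    return MVMRResult(
        method="mr_lasso",
        exposure_ids=list(h.exposure_ids),
        estimates=refit.estimates,
        conditional_q=refit.conditional_q,
        conditional_f=refit.conditional_f,
        lasso_valid_set=list(h.snp_ids[valid]),
        lambda_=lam,
    )
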