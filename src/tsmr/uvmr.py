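"""Univariable two-sample MR estimators.

Five estimators over a harmonized single-exposure set:

* inverse-variance weighted (IVW) — weighted regression of outcome on
  exposure effects through the origin, with fixed or multiplicative
  random-effects standard errors;
* MR-Egger — the same regression with an intercept (the intercept estimates
  average directional pleiotropy);
* weighted median — the 0.5 point of the weight-standardized cumulative
  distribution of per-SNP Wald ratios;
* simple and weighted mode — the argmax of a normal-kernel density over the
  Wald ratios.

Median and mode standard errors come from a seeded parametric bootstrap
(effects resampled from normal(beta, se)).  All p-values are two-sided
normal, and odds-scale conversion uses exp(beta -/+ 1.959964 * se).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .summary_data import HarmonizedSet

Z975 = float(sps.norm.ppf(0.975))

MODE_GRID_SIZE = 2048


@dataclass
class MRResult:
    """One estimator's causal estimate on the log scale plus the odds scale."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @classmethod
    def from_beta(cls, method, n_snp, beta, se, **kw) -> "MRResult":
        or_, lo, hi = to_odds_scale(beta, se)
        return cls(
            method=method,
            n_snp=int(n_snp),
            beta=float(beta),
            se=float(se),
            pval=_norm_p(beta, se),
            or_=or_,
            ci_low=lo,
            ci_high=hi,
            **kw,
        )


def _norm_p(beta, se) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 1e-300
    # floor avoids exact-zero underflow at extreme z (p must stay in (0, 1])
    return float(max(2 * sps.norm.sf(abs(beta / se)), 1e-300))


def to_odds_scale(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, ci_low, ci_high) = exp(beta), exp(beta -/+ z_0.975 * se)."""
    if se < 0:
        raise ConfigurationError("se must be >= 0")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z975 * se)),
        float(np.exp(beta + Z975 * se)),
    )


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates theta_j = beta_Y/beta_X and first-order
    standard errors sigma_j = se_Y/|beta_X|."""
    bx, _, by, sy = h.single()
    if (bx == 0).any():
        raise DegenerateInstrumentError("beta_X contains zeros")
    return by / bx, sy / np.abs(bx)


# ---------------------------------------------------------------------------
# IVW


def _ivw_point(bx, by, w):
    sxx = np.sum(w * bx * bx)
    return np.sum(w * bx * by) / sxx, sxx


def ivw(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance weighted estimate (weights se_Y^-2).

    ``multiplicative_random`` scales the fixed-effects SE by
    max(1, sqrt(Q/(k-1))) where Q is Cochran's Q — never more precise than
    the fixed-effects fit.
    """
    bx, _, by, sy = h.single()
    k = h.k
    if k < 2:
        raise InsufficientInstrumentsError(f"IVW requires k >= 2, got {k}")
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown effects_model '{effects_model}'")
    w = sy**-2
    theta, sxx = _ivw_point(bx, by, w)
    se = sxx**-0.5
    if effects_model == "multiplicative_random":
        q = np.sum(w * (by - theta * bx) ** 2)
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return MRResult.from_beta("ivw_" + effects_model, k, theta, se)


# ---------------------------------------------------------------------------
# MR-Egger


def _egger_fit(bx, by, w):
    """Weighted LS of by on [1, bx] after orienting bx >= 0.

    Returns (intercept, slope, se_int, se_slope, q_prime) with SEs scaled by
    max(1, sqrt(Q'/(k-2))).
    """
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    sw = np.sum(w)
    swx = np.sum(w * x)
    swxx = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ConfigurationError("degenerate design in Egger regression")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    q_prime = float(np.sum(w * resid**2))
    k = len(x)
    scale = max(1.0, np.sqrt(q_prime / (k - 2))) if k > 2 else 1.0
    se_slope = np.sqrt(sw / det) * scale
    se_int = np.sqrt(swxx / det) * scale
    return intercept, slope, se_int, se_slope, q_prime


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: slope = causal estimate, intercept = average
    directional pleiotropy; SNPs oriented to non-negative exposure effects."""
    bx, _, by, sy = h.single()
    if h.k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires k >= 3, got {h.k}")
    w = sy**-2
    intercept, slope, se_int, se_slope, _ = _egger_fit(bx, by, w)
    return MRResult.from_beta(
        "mr_egger",
        h.k,
        slope,
        se_slope,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=_norm_p(intercept, se_int),
    )


# ---------------------------------------------------------------------------
# weighted median


def weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    With normalized weights w'_j in ascending theta order and cumulative sums
    S_j, the standardized positions are p_j = S_j - w'_j/2; the estimate
    linearly interpolates theta against p at 0.5.
    """
    order = np.argsort(theta, kind="stable")
    t = np.asarray(theta, dtype=float)[order]
    wn = np.asarray(w, dtype=float)[order]
    wn = wn / wn.sum()
    p = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, p, t))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    k = len(bx)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        est[b] = point_fn(bxs, bys)
    return float(np.std(est, ddof=1))


def weighted_median(
    h: HarmonizedSet,
    weights: str = "inverse_variance",
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted (or simple, with equal weights) median of Wald ratios; SE by
    seeded parametric bootstrap."""
    bx, sx, by, sy = h.single()
    if h.k < 3:
        raise InsufficientInstrumentsError(f"weighted median requires k >= 3, got {h.k}")
    if weights not in ("inverse_variance", "equal"):
        raise ConfigurationError(f"unknown weights '{weights}'")

    def point(bxs, bys):
        t = bys / bxs
        if weights == "inverse_variance":
            wj = (np.abs(bxs) / sy) ** 2  # 1 / var(ratio)
        else:
            wj = np.ones_like(t)
        return weighted_median_point(t, wj)

    est = point(bx, by)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    label = "weighted_median" if weights == "inverse_variance" else "simple_median"
    return MRResult.from_beta(label, h.k, est, se)


# ---------------------------------------------------------------------------
# mode estimators


def _mode_point(theta, w, phi, grid_size=MODE_GRID_SIZE):
    t = np.asarray(theta, dtype=float)
    if np.allclose(t, t[0]):
        return float(t[0])
    mad = np.median(np.abs(t - np.median(t)))
    if mad == 0:
        # a strict majority of ratios ties exactly at the median: that point
        # mass is the mode in the zero-bandwidth limit
        return float(np.median(t))
    scale = 1.4826 * mad
    k = len(t)
    h_bw = phi * scale * (4.0 / (3.0 * k)) ** 0.2
    grid = np.linspace(t.min() - 3 * h_bw, t.max() + 3 * h_bw, grid_size)
    wn = np.asarray(w, dtype=float)
    wn = wn / wn.sum()
    dens = wn @ np.exp(-0.5 * ((grid[None, :] - t[:, None]) / h_bw) ** 2)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    h: HarmonizedSet,
    weighting: str = "simple",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode-based estimate: normal-kernel density over Wald ratios with
    bandwidth phi * 1.4826 * MAD * (4/(3k))^(1/5) on a 2048-point grid
    spanning [min - 3h, max + 3h]; the estimate is the grid argmax.

    ``simple`` uses equal weights, ``weighted`` inverse-variance weights of
    the ratios.  SE by seeded parametric bootstrap.  A zero MAD with distinct
    ratios falls back to an SD-based bandwidth.
    """
    bx, sx, by, sy = h.single()
    if h.k < 3:
        raise InsufficientInstrumentsError(f"mode estimator requires k >= 3, got {h.k}")
    if weighting not in ("simple", "weighted"):
        raise ConfigurationError(f"unknown weighting '{weighting}'")

    def point(bxs, bys):
        t = bys / bxs
        if weighting == "weighted":
            wj = (np.abs(bxs) / sy) ** 2
        else:
            wj = np.ones_like(t)
        return _mode_point(t, wj, phi)

    est = point(bx, by)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return MRResult.from_beta(f"{weighting}_mode", h.k, est, se)


def point_estimates(h: HarmonizedSet, phi: float = 1.0) -> dict[str, float]:
    """Point estimates of all five estimators without bootstrap SEs.

    Intended for simulation studies where only the estimates are needed and
    the bootstrap would dominate the run time.
    """
    bx, _, by, sy = h.single()
    w = sy**-2
    theta_ivw, _ = _ivw_point(bx, by, w)
    _, slope, *_ = _egger_fit(bx, by, w)
    t = by / bx
    wj = (np.abs(bx) / sy) ** 2
    return {
        "ivw": float(theta_ivw),
        "mr_egger": float(slope),
        "weighted_median": weighted_median_point(t, wj),
        "simple_mode": _mode_point(t, np.ones_like(t), phi),
        "weighted_mode": _mode_point(t, wj, phi),
    }


ALL_ESTIMATORS = ("ivw", "mr_egger", "weighted_median", "simple_mode", "weighted_mode")


def run_all_estimators(
    h: HarmonizedSet, n_boot: int = 1000, phi: float = 1.0, seed: int = 0
) -> list[MRResult]:
    """The study's five univariable estimators, in reporting order."""
    return [
        ivw(h),
        mr_egger(h),
        weighted_median(h, n_boot=n_boot, seed=seed),
        mode_estimate(h, "simple", phi=phi, n_boot=n_boot, seed=seed + 1),
        mode_estimate(h, "weighted", phi=phi, n_boot=n_boot, seed=seed + 2),
    ]
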