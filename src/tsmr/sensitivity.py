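"""Heterogeneity, pleiotropy, influence and outlier diagnostics.

Cochran's Q (against the IVW or Egger fit), the Egger intercept test,
leave-one-out IVW series, and the simulation-based global/outlier test with
removal-and-refit (the MR-PRESSO procedure, without the distortion test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientInstrumentsError, ConfigurationError
from .summary_data import HarmonizedSet
from .uvmr import MRResult, _egger_fit, _ivw_point, ivw, _norm_p


def cochran_q(h: HarmonizedSet, model: str = "ivw") -> tuple[float, int, float]:
    """Cochran's Q = sum w_j (beta_Y_j - fitted_j)^2 with w_j = se_Y_j^-2.

    ``model`` picks the fitted values: the IVW regression through the origin
    (df = k - 1) or the Egger regression with intercept (df = k - 2).
    Returns (Q, df, upper-tail chi-square p).
    """
    bx, _, by, sy = h.single()
    k = h.k
    w = sy**-2
    if model == "ivw":
        if k < 2:
            raise InsufficientInstrumentsError("Q (ivw) requires k >= 2")
        theta, _ = _ivw_point(bx, by, w)
        q = float(np.sum(w * (by - theta * bx) ** 2))
        df = k - 1
    elif model == "egger":
        if k < 3:
            raise InsufficientInstrumentsError("Q (egger) requires k >= 3")
        *_, q = _egger_fit(bx, by, w)
        df = k - 2
    else:
        raise ConfigurationError(f"unknown Q model '{model}'")
    return q, df, float(sps.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(estimate, se, two-sided p) for the Egger intercept (null: zero
    average directional pleiotropy)."""
    bx, _, by, sy = h.single()
    if h.k < 3:
        raise InsufficientInstrumentsError("Egger intercept requires k >= 3")
    intercept, _, se_int, _, _ = _egger_fit(bx, by, sy**-2)
    return float(intercept), float(se_int), _norm_p(intercept, se_int)


def _loo_slopes(bx, by, w):
    """IVW slope with each SNP removed, vectorized over SNPs."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def leave_one_out(h: HarmonizedSet, flag_se_multiple: float = 1.0) -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn.

    A SNP is flagged when its exclusion flips the sign of the estimate or
    moves it by more than ``flag_se_multiple`` times the SE of the reduced
    (leave-one-out) fit.  The reduced-set SE is the right yardstick under
    heterogeneity: a full-set random-effects SE is inflated by the very
    outlier being probed (self-masking), while the fixed-effects SE
    over-flags every SNP once any outlier is present.
    Columns: excluded_snp, beta, se, pval, flagged.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("leave-one-out requires k >= 3")
    full = ivw(h)
    rows = []
    mask = np.ones(h.k, dtype=bool)
    for j in range(h.k):
        mask[j] = False
        res = ivw(h.subset(mask))
        mask[j] = True
        flagged = (np.sign(res.beta) != np.sign(full.beta)) or (
            abs(res.beta - full.beta) > flag_se_multiple * res.se
        )
        rows.append(
            {
                "excluded_snp": h.snp_ids[j],
                "beta": res.beta,
                "se": res.se,
                "pval": res.pval,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PressoResult:
    """Global heterogeneity test and per-SNP outlier test with refit."""

    rss_obs: float
    global_p: float
    outlier_ids: list[str]
    outlier_pvals: pd.Series  # Bonferroni-adjusted per-SNP p-values
    refit: MRResult | None


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Simulation-based residual-sum-of-squares outlier detection.

    The observed RSS uses leave-one-out IVW slopes:
    RSS = sum_j w_j (beta_Y_j - theta_{-j} beta_X_j)^2, w_j = se_Y_j^-2.
    The null distribution comes from ``n_sim`` parametric draws
    beta_X' ~ N(beta_X, se_X), beta_Y'_j ~ N(theta_{-j} beta_X_j, se_Y_j),
    with leave-one-out slopes recomputed per draw.  Empirical p-values carry
    the +1/(n+1) correction; per-SNP outlier p-values are Bonferroni-adjusted
    by k, and SNPs below ``outlier_alpha`` are removed before an IVW refit
    (refit is None when no outlier is found).
    """
    bx, sx, by, sy = h.single()
    k = h.k
    if k < 4:
        raise InsufficientInstrumentsError("the outlier test requires k >= 4")
    if n_sim < 100:
        raise ConfigurationError("n_sim must be >= 100")
    w = sy**-2
    theta_loo = _loo_slopes(bx, by, w)
    obs_terms = w * (by - theta_loo * bx) ** 2
    rss_obs = float(obs_terms.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    sxy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    loo_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim * bx_sim)
    sim_terms = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = sim_terms.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(sim_terms >= obs_terms[None, :], axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_snp * k)
    outlier_mask = p_adj < outlier_alpha
    outlier_ids = list(h.snp_ids[outlier_mask])
    refit = ivw(h.subset(~outlier_mask)) if outlier_mask.any() else None
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_ids=outlier_ids,
        outlier_pvals=pd.Series(p_adj, index=h.snp_ids),
        refit=refit,
    )


@dataclass
class SensitivityReport:
    """Bundle of the study's sensitivity analyses for one exposure-outcome pair."""

    q_ivw: tuple[float, int, float]
    q_egger: tuple[float, int, float]
    egger_intercept: tuple[float, float, float]
    loo: pd.DataFrame
    presso: PressoResult | None = None

    @property
    def heterogeneous(self) -> bool:
        """True when the IVW Q test rejects at 0.05 (the pipeline then labels
        the IVW fit random-effects for the main analysis)."""
        return self.q_ivw[2] < 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"test": "cochran_q_ivw", "statistic": self.q_ivw[0], "df": self.q_ivw[1], "pval": self.q_ivw[2]},
            {"test": "cochran_q_egger", "statistic": self.q_egger[0], "df": self.q_egger[1], "pval": self.q_egger[2]},
            {"test": "egger_intercept", "statistic": self.egger_intercept[0], "df": np.nan, "pval": self.egger_intercept[2]},
        ]
        if self.presso is not None:
            rows.append(
                {
                    "test": "presso_global",
                    "statistic": self.presso.rss_obs,
                    "df": np.nan,
                    "pval": self.presso.global_p,
                }
            )
        return pd.DataFrame(rows)


def sensitivity_report(
    h: HarmonizedSet, n_sim: int = 1000, seed: int = 0, run_presso: bool = True
) -> SensitivityReport:
    """Run the full sensitivity suite on a single-exposure harmonized set."""
    return SensitivityReport(
        q_ivw=cochran_q(h, "ivw"),
        q_egger=cochran_q(h, "egger"),
        egger_intercept=egger_intercept_test(h),
        loo=leave_one_out(h),
        presso=mr_presso(h, n_sim=n_sim, seed=seed) if run_presso and h.k >= 4 else None,
    )
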