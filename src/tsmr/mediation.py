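"""Two-step MR mediation: product of coefficients with delta-method CIs.

Given three estimated log-scale effects — total (exposure -> outcome),
step 1 (exposure -> mediator) and step 2 (mediator -> outcome) — the
indirect effect is the product of the two step coefficients, its standard
error comes from the first-order delta method assuming the two steps are
estimated in independent samples, the direct effect is total minus indirect,
and the mediated proportion is indirect over total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigurationError, UndefinedProportionError
from .multiple_testing import bh_adjust
from .uvmr import Z975, to_odds_scale, _norm_p


def indirect_effect(step1: tuple[float, float], step2: tuple[float, float]):
    """Product-of-coefficients indirect effect and delta-method SE.

    beta_IE = b1 * b2;  se_IE = sqrt(b2^2 se1^2 + b1^2 se2^2)
    (first-order, independent samples).
    """
    b1, s1 = step1
    b2, s2 = step2
    if s1 <= 0 or s2 <= 0:
        raise ConfigurationError("step standard errors must be > 0")
    beta_ie = b1 * b2
    se_ie = float(np.sqrt(b2**2 * s1**2 + b1**2 * s2**2))
    return float(beta_ie), se_ie


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with the mediated proportion.

    The log-scale identity beta_TE = beta_DE + beta_IE holds by construction,
    so on the odds scale or_ie * or_de = or_te.
    """

    te: tuple[float, float]
    step1: tuple[float, float]
    step2: tuple[float, float]
    ie: tuple[float, float]
    de: tuple[float, float]
    ie_pval: float
    prop: float
    prop_ci: tuple[float, float]
    prop_ci_method: str
    or_te: tuple[float, float, float]
    or_de: tuple[float, float, float]
    or_ie: tuple[float, float, float]

    @property
    def mediating(self) -> bool:
        """The study's reporting rule: a mediator counts as mediating when
        the normal test of the indirect effect has p < 0.05."""
        return self.ie_pval < 0.05


def mediation_decompose(
    te: tuple[float, float],
    step1: tuple[float, float],
    step2: tuple[float, float],
    prop_ci_method: str = "ie_ci_over_te",
) -> MediationResult:
    """Decompose a total effect into direct and mediated parts.

    Parameters
    ----------
    te, step1, step2 : (beta, se)
        Total exposure->outcome, exposure->mediator, mediator->outcome
        estimates on the log scale.
    prop_ci_method : {"ie_ci_over_te", "full_delta"}
        ``ie_ci_over_te`` divides the indirect-effect CI by the total effect
        (treating the total as fixed); ``full_delta`` propagates the total
        effect's uncertainty as well:
        prop -/+ z * sqrt(se_IE^2/TE^2 + IE^2 se_TE^2 / TE^4).

    The direct-effect SE uses sqrt(se_TE^2 + se_IE^2); this treats the total
    and indirect estimates as independent, which overstates the variance when
    the same outcome sample enters both (documented caveat).
    """
    b_te, se_te = float(te[0]), float(te[1])
    if b_te == 0:
        raise UndefinedProportionError("mediated proportion undefined for TE = 0")
    if prop_ci_method not in ("ie_ci_over_te", "full_delta"):
        raise ConfigurationError(f"unknown prop_ci_method '{prop_ci_method}'")
    b_ie, se_ie = indirect_effect(step1, step2)
    b_de = b_te - b_ie
    se_de = float(np.sqrt(se_te**2 + se_ie**2))
    prop = b_ie / b_te
    if prop_ci_method == "ie_ci_over_te":
        lo = (b_ie - Z975 * se_ie) / b_te
        hi = (b_ie + Z975 * se_ie) / b_te
    else:
        half = Z975 * np.sqrt(se_ie**2 / b_te**2 + b_ie**2 * se_te**2 / b_te**4)
        lo, hi = prop - half, prop + half
    lo, hi = (min(lo, hi), max(lo, hi))
    return MediationResult(
        te=(b_te, se_te),
        step1=(float(step1[0]), float(step1[1])),
        step2=(float(step2[0]), float(step2[1])),
        ie=(b_ie, se_ie),
        de=(b_de, se_de),
        ie_pval=_norm_p(b_ie, se_ie),
        prop=float(prop),
        prop_ci=(float(lo), float(hi)),
        prop_ci_method=prop_ci_method,
        or_te=to_odds_scale(b_te, se_te),
        or_de=to_odds_scale(b_de, se_de),
        or_ie=to_odds_scale(b_ie, se_ie),
    )


def mediator_screen(results, alpha: float = 0.05, adjust: str = "none") -> list[str]:
    """Retain mediators whose mediator->outcome effect is (adjusted-)significant.

    ``results`` is a list of (label, MRResult) pairs; ``adjust`` is ``none``
    (raw p < alpha) or ``bh_fdr`` (Benjamini-Hochberg adjusted p < alpha).
    Ordering is preserved.
    """
    if not results:
        raise ConfigurationError("mediator_screen needs at least one result")
    if adjust not in ("none", "bh_fdr"):
        raise ConfigurationError(f"unknown adjust '{adjust}'")
    labels = [lab for lab, _ in results]
    pvals = np.array([r.pval for _, r in results])
    if adjust == "bh_fdr":
        pvals = bh_adjust(pvals, monotone=True).adjusted
    return [lab for lab, p in zip(labels, pvals) if p < alpha]
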