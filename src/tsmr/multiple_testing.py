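"""Benjamini-Hochberg FDR adjustment and significance-tier labeling.

Two conventions are offered.  The default (``monotone=False``) is the
rank-scaled form adj_j = p_j * m / rank_j (ties share the largest rank), the
convention behind this analysis's reported adjusted values.  ``monotone=True``
is the standard step-up estimator with the cummin pass from the largest rank
down (identical to R's ``p.adjust(method="BH")`` and statsmodels ``fdr_bh``);
the two differ only where a rank-scaled value exceeds a later one.

Tiers follow the study's rule: ``significant`` when adjusted < 0.05,
``suggestive`` when raw < 0.05 but adjusted >= 0.05, else ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NULL = "null"


@dataclass
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    tier: list[str]

    def __len__(self) -> int:
        return len(self.raw)


def bh_adjust(pvals, alpha: float = 0.05, monotone: bool = False) -> AdjustedPValues:
    """FDR-adjust a family of p-values (input order preserved).

    Parameters
    ----------
    pvals : array-like of p-values in (0, 1].
    alpha : tier threshold (default 0.05).
    monotone : bool
        False (default): rank-scaled adjustment p * m / rank.
        True: standard step-up with monotonicity enforced (delegates to
        statsmodels), guaranteeing adjusted values non-decreasing in raw rank.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ConfigurationError("pvals must be a non-empty 1-D collection")
    if (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    m = len(p)
    if monotone:
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests(p, method="fdr_bh")[1]
    else:
        # rank by count of p-values <= p_j, so ties share the largest rank
        rank = np.searchsorted(np.sort(p), p, side="right")
        adjusted = np.minimum(1.0, p * m / rank)
    tier = [
        TIER_SIGNIFICANT
        if a < alpha
        else (TIER_SUGGESTIVE if r < alpha else TIER_NULL)
        for r, a in zip(p, adjusted)
    ]
    return AdjustedPValues(raw=p, adjusted=np.asarray(adjusted, dtype=float), tier=tier)
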