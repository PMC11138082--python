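"""Instrument selection: significance filtering, LD clumping, F statistics.

Selection applies, in order: a genome-wide significance filter (strict
``pval < threshold``), greedy LD clumping against a user-supplied LD matrix
(smallest p-value first; ties broken lexicographically by SNP id so the
result is independent of row order), a per-SNP instrument-strength filter
(F = beta^2 / se^2, keep F >= threshold), and removal of SNPs on an explicit
exclusion list (e.g. variants known to act through confounders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInstrumentError, MissingLDError
from .summary_data import SummaryStats

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_MAX = 0.001
DEFAULT_WINDOW_KB = 10_000.0
DEFAULT_F_THRESHOLD = 10.0


@dataclass
class LDMatrix:
    """Pairwise r-squared between candidate SNPs, with optional positions.

    ``positions``, when present, is a DataFrame indexed by snp id with
    columns ``chrom`` and ``pos`` (base pairs) used by the distance-window
    pruning rule.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: pd.DataFrame | None = None

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ConfigurationError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ConfigurationError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as e:
            raise MissingLDError(f"SNP {e} absent from LD matrix") from None

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, positions=None) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), positions)


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP F statistics and filter provenance.

    ``provenance`` has one row per candidate SNP with columns
    ``snp, pval, f_stat, status`` where status is ``retained`` or
    ``removed_<step>``.
    """

    snp_ids: list[str]
    f_stats: pd.Series
    provenance: pd.DataFrame

    def __len__(self) -> int:
        return len(self.snp_ids)


def f_statistic(beta, se):
    """Per-SNP instrument strength F = beta^2 / se^2 (se must be > 0)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ConfigurationError("se must be > 0 in f_statistic")
    return beta**2 / se**2


def select_by_pvalue(stats: SummaryStats, threshold: float = DEFAULT_P_THRESHOLD):
    """Subset of ``stats`` with pval strictly below ``threshold`` (order kept).

    Returns a DataFrame (possibly empty) rather than SummaryStats so empty
    results are representable.
    """
    if not (0 < threshold < 1):
        raise ConfigurationError("p-value threshold must lie in (0, 1)")
    return stats.data[stats.data["pval"] < threshold].reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> list[str]:
    """Greedy clumping: repeatedly take the remaining SNP with the smallest
    p-value as an index SNP and discard remaining SNPs with r^2 > r2_max
    against it or within ``window_kb`` on the same chromosome.

    ``candidates`` must carry ``snp`` and ``pval`` columns.  Every candidate
    must be present in the LD matrix (silent retention would bias the panel
    toward dependence).  Returns the index SNPs in selection order.
    """
    snps = list(candidates["snp"])
    missing = [s for s in snps if s not in ld._index]
    if missing:
        raise MissingLDError(f"SNPs missing from LD matrix: {missing[:5]}")
    order = candidates[["snp", "pval"]].sort_values(
        ["pval", "snp"], kind="mergesort"
    )
    remaining = list(order["snp"])
    pos = ld.positions
    selected: list[str] = []
    while remaining:
        index_snp = remaining.pop(0)
        selected.append(index_snp)
        keep = []
        for s in remaining:
            if ld.r2_between(index_snp, s) > r2_max:
                continue
            if pos is not None and index_snp in pos.index and s in pos.index:
                a, b = pos.loc[index_snp], pos.loc[s]
                if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= window_kb * 1000:
                    continue
            keep.append(s)
        remaining = keep
    return selected


def build_instrument_set(
    stats: SummaryStats,
    ld: LDMatrix | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    exclusion_list=(),
) -> InstrumentSet:
    """Full selection cascade: p-value filter -> clumping -> F filter ->
    exclusion-list removal, with per-SNP provenance.

    Clumping is skipped (with a logged warning) when ``ld`` is None, for
    pre-clumped input.  Raises :class:`EmptyInstrumentError` naming the first
    step that empties the candidate set.
    """
    df = stats.data.copy()
    df["f_stat"] = f_statistic(df["beta"].to_numpy(), df["se"].to_numpy())
    status = pd.Series("retained", index=df["snp"].to_numpy(), dtype=object)

    sig = df[df["pval"] < p_threshold]
    status[~status.index.isin(sig["snp"])] = "removed_pvalue"
    if len(sig) == 0:
        raise EmptyInstrumentError("pvalue")

    if ld is not None:
        kept = clump(sig, ld, r2_max=r2_max, window_kb=window_kb)
        clumped = sig[sig["snp"].isin(kept)]
        status[sig.loc[~sig["snp"].isin(kept), "snp"]] = "removed_clump"
        if len(clumped) == 0:  # pragma: no cover - clumping always keeps >= 1
            raise EmptyInstrumentError("clump")
    else:
        logger.warning(
            "no LD matrix supplied: clumping skipped, input assumed pre-clumped"
        )
        clumped = sig

    strong = clumped[clumped["f_stat"] >= f_threshold]
    status[clumped.loc[clumped["f_stat"] < f_threshold, "snp"]] = "removed_f"
    if len(strong) == 0:
        raise EmptyInstrumentError("f_statistic")

    exclusion = set(exclusion_list)
    final = strong[~strong["snp"].isin(exclusion)]
    status[strong.loc[strong["snp"].isin(exclusion), "snp"]] = "removed_exclusion"
    if len(final) == 0:
        raise EmptyInstrumentError("exclusion")

    provenance = pd.DataFrame(
        {
            "snp": df["snp"].to_numpy(),
            "pval": df["pval"].to_numpy(),
            "f_stat": df["f_stat"].to_numpy(),
            "status": status.loc[df["snp"]].to_numpy(),
        }
    )
    return InstrumentSet(
        snp_ids=final["snp"].tolist(),
        f_stats=final.set_index("snp")["f_stat"],
        provenance=provenance,
    )


def read_exclusion_list(path) -> list[str]:
    """One snp_id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
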