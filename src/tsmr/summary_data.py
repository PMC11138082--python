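"""GWAS summary statistics: data model, I/O, and allele harmonization.

The two core containers are :class:`SummaryStats` (one trait's per-SNP
association table) and :class:`HarmonizedSet` (exposure and outcome effects
aligned to a shared effect allele for a common SNP set — the substrate every
MR estimator consumes).

Harmonization follows the standard two-sample convention: every dataset is
aligned to the *first exposure's* effect allele, flipping the sign of beta
(and eaf -> 1 - eaf) when the effect/other alleles are swapped, with optional
strand-complement matching.  Strand-ambiguous (A/T, C/G) SNPs are either
dropped or oriented by allele frequency, controlled by ``palindrome_policy``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

#: canonical column order of a SummaryStats table
COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

_MANDATORY = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

_VALID_ALLELES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class SummaryStats:
    """Per-SNP association statistics for a single trait.

    ``data`` holds one row per SNP with the canonical columns
    ``snp, effect_allele, other_allele, eaf, beta, se, pval, n``
    (``eaf`` and ``n`` may be NaN).  Betas are per-effect-allele effects:
    log odds ratios for binary traits, SD or native units for continuous
    traits.
    """

    trait_id: str
    data: pd.DataFrame
    n_dropped_rows: int = 0

    def __post_init__(self):
        df = self.data
        missing = [c for c in _MANDATORY if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing mandatory columns: {missing}")
        df = df.copy()
        for c in ("eaf", "n"):
            if c not in df.columns:
                df[c] = np.nan
        df = df[COLUMNS].reset_index(drop=True)
        if len(df) == 0:
            raise EmptyInputError(f"no records for trait '{self.trait_id}'")
        if df["snp"].duplicated().any():
            dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
            raise ConfigurationError(f"duplicate snp_id '{dup}' in '{self.trait_id}'")
        if not (df["se"] > 0).all():
            raise ConfigurationError("all SE must be > 0")
        if not ((df["pval"] > 0) & (df["pval"] <= 1)).all():
            raise ConfigurationError("all p-values must lie in (0, 1]")
        bad = ~df["effect_allele"].isin(_VALID_ALLELES) | ~df["other_allele"].isin(
            _VALID_ALLELES
        )
        if bad.any():
            raise ConfigurationError("alleles must be single characters in A/C/G/T")
        if (df["effect_allele"] == df["other_allele"]).any():
            raise ConfigurationError("effect and other allele must differ")
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> list[str]:
        return self.data["snp"].tolist()

    def subset(self, snp_ids) -> "SummaryStats":
        """Rows for ``snp_ids``, preserving this table's row order."""
        keep = self.data["snp"].isin(set(snp_ids))
        return SummaryStats(self.trait_id, self.data[keep])


def read_summary_stats(
    path,
    trait_id: str | None = None,
    column_map: dict[str, str] | None = None,
    delimiter: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    trait_id : str, optional
        Label for the trait; defaults to the file stem.
    column_map : dict, optional
        Maps canonical names (``snp``, ``effect_allele``, ``other_allele``,
        ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the file's column
        names.  Unmapped canonical names are looked up verbatim.
    delimiter : str
        Field separator (default tab).

    Rows with non-positive SE, out-of-range p-values, or malformed alleles
    are dropped and counted in ``n_dropped_rows``; row order is preserved.
    """
    column_map = column_map or {}
    raw = pd.read_csv(path, sep=delimiter, dtype={column_map.get("snp", "snp"): str})
    rename = {}
    for canonical in COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical in _MANDATORY:
            raise ConfigurationError(
                f"column '{src}' (for '{canonical}') not found in {path}"
            )
    df = raw.rename(columns=rename)
    for c in ("eaf", "n"):
        if c not in df.columns:
            df[c] = np.nan
    df = df[COLUMNS]

    for a in ("effect_allele", "other_allele"):
        df[a] = df[a].astype(str).str.upper().str.strip()
    ok = (
        (pd.to_numeric(df["se"], errors="coerce") > 0)
        & (pd.to_numeric(df["pval"], errors="coerce") > 0)
        & (pd.to_numeric(df["pval"], errors="coerce") <= 1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["snp"].notna()
        & ~df["snp"].duplicated()
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d malformed rows", path, n_dropped)
    df = df[ok]
    if len(df) == 0:
        raise EmptyInputError(f"no valid rows in {path}")
    if trait_id is None:
        import os

        trait_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SummaryStats(trait_id, df, n_dropped_rows=n_dropped)


def write_summary_stats(stats: SummaryStats, path, delimiter: str = "\t") -> None:
    """Write the canonical table as delimited text (round-trips with the reader)."""
    stats.data.to_csv(path, sep=delimiter, index=False)


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure(s) + outcome effects on a shared SNP set.

    beta_X / se_X are (k, M) with one column per exposure; beta_Y / se_Y are
    length-k.  ``dropped`` records every shared SNP the harmonizer discarded,
    as (snp_id, reason) pairs.
    """

    exposure_ids: list[str]
    outcome_id: str
    snp_ids: np.ndarray
    beta_X: np.ndarray
    se_X: np.ndarray
    beta_Y: np.ndarray
    se_Y: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.beta_X = np.atleast_2d(np.asarray(self.beta_X, dtype=float))
        self.se_X = np.atleast_2d(np.asarray(self.se_X, dtype=float))
        if self.beta_X.shape[0] == 1 and len(self.snp_ids) != 1:
            self.beta_X = self.beta_X.T
            self.se_X = self.se_X.T
        self.beta_Y = np.asarray(self.beta_Y, dtype=float)
        self.se_Y = np.asarray(self.se_Y, dtype=float)
        k = len(self.snp_ids)
        if k < 1:
            raise EmptyInputError("harmonized set has no SNPs")
        if not (
            self.beta_X.shape == self.se_X.shape == (k, len(self.exposure_ids))
            and self.beta_Y.shape == self.se_Y.shape == (k,)
        ):
            raise ConfigurationError("harmonized arrays have inconsistent shapes")
        if not ((self.se_X > 0).all() and (self.se_Y > 0).all()):
            raise ConfigurationError("all standard errors must be > 0")
        retained = set(self.snp_ids)
        if any(s in retained for s, _ in self.dropped):
            raise ConfigurationError("a SNP appears both retained and dropped")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    def single(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_X, se_X, beta_Y, se_Y) 1-D views for a single-exposure set."""
        if self.n_exposures != 1:
            raise ConfigurationError(
                f"single-exposure operation on {self.n_exposures} exposures"
            )
        return self.beta_X[:, 0], self.se_X[:, 0], self.beta_Y, self.se_Y

    def subset(self, mask) -> "HarmonizedSet":
        """Row subset by boolean mask or index array (dropped list not carried)."""
        return HarmonizedSet(
            self.exposure_ids,
            self.outcome_id,
            self.snp_ids[mask],
            self.beta_X[mask],
            self.se_X[mask],
            self.beta_Y[mask],
            self.se_Y[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per SNP with beta_X.<trait>, se_X.<trait>, beta_Y, se_Y."""
        out = {"snp": self.snp_ids}
        for m, tid in enumerate(self.exposure_ids):
            out[f"beta_X.{tid}"] = self.beta_X[:, m]
            out[f"se_X.{tid}"] = self.se_X[:, m]
        out["beta_Y"] = self.beta_Y
        out["se_Y"] = self.se_Y
        return pd.DataFrame(out)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def _orient(ref_ea, ref_oa, ea, oa):
    """Return 'same', 'flip', or None (incompatible), allowing strand complements."""
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "flip"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return "same"
    if (cea, coa) == (ref_oa, ref_ea):
        return "flip"
    return None


def harmonize(
    exposures: list[SummaryStats] | SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "drop",
    eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome (and secondary-exposure) effects to the first exposure's
    effect allele over the shared SNP set.

    Parameters
    ----------
    exposures : SummaryStats or list thereof
        First entry defines the reference effect allele per SNP.
    outcome : SummaryStats
    palindrome_policy : {"drop", "infer_by_eaf"}
        Strand-ambiguous (A/T, C/G) SNPs are dropped, or oriented by effect
        allele frequency when both frequencies lie outside
        [0.5 - eaf_window, 0.5 + eaf_window].
    eaf_window : float
        Half-width of the ambiguous frequency band around 0.5.

    Every shared SNP is either retained or listed in ``dropped`` with a
    reason, so ``k + len(dropped)`` equals the intersection size.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ConfigurationError(f"unknown palindrome_policy '{palindrome_policy}'")
    datasets = list(exposures) + [outcome]
    shared = set(datasets[0].data["snp"])
    for ds in datasets[1:]:
        shared &= set(ds.data["snp"])
    if not shared:
        raise EmptyInputError("no SNP shared by all exposures and the outcome")

    ref = exposures[0].data.set_index("snp")
    # preserve the reference exposure's row order
    order = [s for s in exposures[0].data["snp"] if s in shared]
    tables = [ds.data.set_index("snp") for ds in datasets]

    kept_rows: list[list[tuple[float, float]]] = []  # per SNP: [(beta, se) per dataset]
    kept_ids: list[str] = []
    dropped: list[tuple[str, str]] = []
    for snp in order:
        ref_ea = ref.at[snp, "effect_allele"]
        ref_oa = ref.at[snp, "other_allele"]
        ref_eaf = ref.at[snp, "eaf"]
        palindromic = _is_palindromic(ref_ea, ref_oa)
        if palindromic and palindrome_policy == "drop":
            dropped.append((snp, "palindromic"))
            continue
        row: list[tuple[float, float]] = []
        reason = None
        for tab in tables:
            ea, oa = tab.at[snp, "effect_allele"], tab.at[snp, "other_allele"]
            beta, se = float(tab.at[snp, "beta"]), float(tab.at[snp, "se"])
            eaf = tab.at[snp, "eaf"]
            if palindromic:
                # letters cannot resolve strand; orient by allele frequency
                if frozenset((ea, oa)) != frozenset((ref_ea, ref_oa)):
                    reason = "allele mismatch"
                    break
                if (
                    pd.isna(eaf)
                    or pd.isna(ref_eaf)
                    or abs(eaf - 0.5) <= eaf_window
                    or abs(ref_eaf - 0.5) <= eaf_window
                ):
                    reason = "palindromic ambiguous eaf"
                    break
                if (eaf - 0.5) * (ref_eaf - 0.5) > 0:
                    row.append((beta, se))
                else:
                    row.append((-beta, se))
            else:
                action = _orient(ref_ea, ref_oa, ea, oa)
                if action is None:
                    reason = "allele mismatch"
                    break
                row.append((beta, se) if action == "same" else (-beta, se))
        if reason is not None:
            dropped.append((snp, reason))
        else:
            kept_ids.append(snp)
            kept_rows.append(row)

    if not kept_ids:
        raise EmptyInputError("harmonization dropped every shared SNP")
    arr = np.array(kept_rows)  # (k, n_datasets, 2)
    m = len(exposures)
    return HarmonizedSet(
        exposure_ids=[e.trait_id for e in exposures],
        outcome_id=outcome.trait_id,
        snp_ids=np.array(kept_ids, dtype=object),
        beta_X=arr[:, :m, 0],
        se_X=arr[:, :m, 1],
        beta_Y=arr[:, m, 0],
        se_Y=arr[:, m, 1],
        dropped=dropped,
    )
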