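"""Synthetic two-sample GWAS summary statistics with known ground truth.

Statistics are generated directly at the summary level (no individual-level
genotypes): per-SNP instrument effects gamma_j are drawn half-normal so the
effect allele is the exposure-increasing allele (the reference orientation
that makes directional pleiotropy directional), standard errors follow the
standardized-trait approximation se = 1/sqrt(2 maf (1-maf) n), and observed
effects are normal draws around their truth.  Pleiotropy regimes: none,
balanced (zero-mean), directional (mean mu), and correlated (alpha_j =
delta * gamma_j + noise, violating the InSiDE assumption), applied to a
random ``prop_invalid`` fraction of SNPs.

An optional exposure -> mediator -> outcome structure sets
E[beta_M] = b_EM * gamma + eta and
E[beta_Y] = (theta_dir + b_EM * b_MY) * gamma + b_MY * eta + alpha,
where eta are mediator-specific instrument effects (zero by default; a
nonzero scale makes the exposure and mediator effect columns linearly
independent, which multivariable fits need for identification).

File-level allele orientation is randomized per dataset so the harmonizer
always has real work; the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .instruments import LDMatrix
from .summary_data import SummaryStats

# non-palindromic allele pairs only, so default harmonization keeps every SNP
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class PleiotropyConfig:
    """Horizontal-pleiotropy regime for the invalid SNP subset.

    kind: "none" | "balanced" | "directional" | "correlated";
    mu is the directional mean, tau the spread, delta the slope on gamma in
    the correlated (InSiDE-violating) regime.
    """

    kind: str = "none"
    mu: float = 0.0
    tau: float = 0.0
    delta: float = 0.0


@dataclass
class MediationConfig:
    """Three-variable causal structure: exposure -> mediator -> outcome.

    b_em: exposure->mediator effect; b_my: mediator->outcome effect;
    theta_dir: direct exposure->outcome effect; gamma_sd_mediator: scale of
    mediator-specific instrument effects (0 = all mediator signal flows
    through the exposure).
    """

    b_em: float
    b_my: float
    theta_dir: float
    gamma_sd_mediator: float = 0.0

    @property
    def theta_total(self) -> float:
        return self.theta_dir + self.b_em * self.b_my

    @property
    def expected_proportion(self) -> float:
        return self.b_em * self.b_my / self.theta_total


@dataclass
class SimConfig:
    """Study conditions for one synthetic two-sample dataset.

    Defaults emulate the scale of the UK Biobank-sized GWAS this kind of
    analysis draws on: ~100 independent instruments from a ~450k-sample
    continuous exposure against a ~400k-sample binary outcome (log-odds
    effects), with instrument strengths spanning roughly F = 30-700 after
    genome-wide-significance selection.
    """

    k: int = 100
    n_exposure: int = 450_000
    n_outcome: int = 400_000
    n_mediator: int = 450_000
    theta: float = 0.14
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    prop_invalid: float = 0.0
    mediation: MediationConfig | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.03
    ld_blocks: tuple[int, float] | None = None  # (block size, within-block r2)
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if min(self.n_exposure, self.n_outcome, self.n_mediator) < 1:
            raise ConfigurationError("sample sizes must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be within (0, 0.5]")
        if not (0 <= self.prop_invalid <= 1):
            raise ConfigurationError("prop_invalid must lie in [0, 1]")
        if self.gamma_sd <= 0:
            raise ConfigurationError("gamma_sd must be > 0")
        if self.pleiotropy.kind not in ("none", "balanced", "directional", "correlated"):
            raise ConfigurationError(f"unknown pleiotropy kind '{self.pleiotropy.kind}'")
        if self.ld_blocks is not None:
            size, r2 = self.ld_blocks
            if size < 1 or not (0 <= r2 <= 1):
                raise ConfigurationError("ld_blocks must be (size >= 1, r2 in [0,1])")


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    theta_total: float
    gamma: np.ndarray
    alpha: np.ndarray
    eta: np.ndarray | None = None
    expected_proportion: float | None = None


@dataclass
class SimResult:
    exposure: SummaryStats
    outcome: SummaryStats
    mediator: SummaryStats | None
    truth: SimTruth
    ld: LDMatrix | None


def _se_approx(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats as sps

    return np.clip(2.0 * sps.norm.sf(np.abs(beta / se)), 1e-300, 1.0)


def _as_table(rng, snp_ids, pairs, maf, beta, se, n) -> pd.DataFrame:
    """Assemble one dataset's table with a random per-SNP allele orientation."""
    flip = rng.random(len(snp_ids)) < 0.5
    ea = np.where(flip, [p[1] for p in pairs], [p[0] for p in pairs])
    oa = np.where(flip, [p[0] for p in pairs], [p[1] for p in pairs])
    return pd.DataFrame(
        {
            "snp": snp_ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": np.where(flip, 1.0 - maf, maf),
            "beta": np.where(flip, -beta, beta),
            "se": se,
            "pval": _pvals(beta, se),
            "n": n,
        }
    )


def simulate_summary_stats(cfg: SimConfig) -> SimResult:
    """Generate exposure/outcome (and optional mediator) summary statistics.

    The exposure file keeps the reference orientation (effect allele =
    exposure-increasing allele); outcome and mediator files randomize
    orientation per SNP.  Identical configs (including seed) give
    bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    snp_ids = np.array([f"rs{i + 1}" for i in range(k)], dtype=object)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=k)]
    maf = rng.uniform(*cfg.maf_range, size=k)
    gamma = np.abs(rng.normal(0.0, cfg.gamma_sd, size=k))
    se_x = _se_approx(maf, cfg.n_exposure)
    se_y = _se_approx(maf, cfg.n_outcome)
    beta_x = rng.normal(gamma, se_x)

    n_invalid = int(round(cfg.prop_invalid * k))
    alpha = np.zeros(k)
    if n_invalid and cfg.pleiotropy.kind != "none":
        idx = rng.choice(k, size=n_invalid, replace=False)
        pc = cfg.pleiotropy
        if pc.kind == "balanced":
            alpha[idx] = rng.normal(0.0, pc.tau, size=n_invalid)
        elif pc.kind == "directional":
            alpha[idx] = rng.normal(pc.mu, pc.tau, size=n_invalid)
        else:  # correlated: alpha depends on instrument strength (InSiDE violated)
            alpha[idx] = pc.delta * gamma[idx] + rng.normal(0.0, pc.tau, size=n_invalid)

    mediator_stats = None
    eta = None
    if cfg.mediation is not None:
        med = cfg.mediation
        se_m = _se_approx(maf, cfg.n_mediator)
        # sign-symmetric: mediator-specific effects have no preferred
        # direction relative to the exposure-increasing allele, otherwise
        # E[gamma*eta] != 0 and they act as directional pleiotropy on the
        # exposure->outcome regression through the origin
        eta = (
            rng.normal(0.0, med.gamma_sd_mediator, size=k)
            if med.gamma_sd_mediator > 0
            else np.zeros(k)
        )
        beta_m = rng.normal(med.b_em * gamma + eta, se_m)
        theta_total = med.theta_total
        mean_y = theta_total * gamma + med.b_my * eta + alpha
        expected_prop = med.expected_proportion
    else:
        theta_total = cfg.theta
        mean_y = cfg.theta * gamma + alpha
        expected_prop = None
    beta_y = rng.normal(mean_y, se_y)

    exposure = SummaryStats(
        "exposure",
        pd.DataFrame(
            {
                "snp": snp_ids,
                "effect_allele": [p[0] for p in pairs],
                "other_allele": [p[1] for p in pairs],
                "eaf": maf,
                "beta": beta_x,
                "se": se_x,
                "pval": _pvals(beta_x, se_x),
                "n": cfg.n_exposure,
            }
        ),
    )
    outcome = SummaryStats(
        "outcome", _as_table(rng, snp_ids, pairs, maf, beta_y, se_y, cfg.n_outcome)
    )
    if cfg.mediation is not None:
        mediator_stats = SummaryStats(
            "mediator", _as_table(rng, snp_ids, pairs, maf, beta_m, se_m, cfg.n_mediator)
        )

    truth = SimTruth(
        theta_total=float(theta_total),
        gamma=gamma,
        alpha=alpha,
        eta=eta,
        expected_proportion=expected_prop,
    )
    ld = make_ld_matrix(cfg) if cfg.ld_blocks is not None else None
    return SimResult(exposure, outcome, mediator_stats, truth, ld)


@dataclass
class MediationStudy:
    """Three-trait summary statistics with disjoint instrument panels.

    ``exposure``/``mediator``/``outcome`` each cover the union of both
    panels, mirroring real GWAS sources where every variant is reported in
    every study but each trait has its own genome-wide-significant set.
    """

    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    truth: SimTruth


def simulate_mediation_study(
    k_exposure: int = 60,
    k_mediator: int = 60,
    b_em: float = 0.018,
    b_my: float = 0.61,
    theta_dir: float = 0.28,
    n_exposure: int = 450_000,
    n_mediator: int = 450_000,
    n_outcome: int = 400_000,
    gamma_sd: float = 0.03,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> MediationStudy:
    """Compose a full two-step mediation study from two summary-level runs.

    Panel A carries the exposure's instruments (with downstream mediator and
    outcome effects via b_EM and theta_dir + b_EM*b_MY); panel B carries the
    mediator's own instruments (outcome effects via b_MY) with null exposure
    effects.  Concatenating the panels gives one file per trait in which each
    trait's genome-wide-significant set is (essentially) disjoint from the
    other's — the structure two-step MR assumes.
    """
    med = MediationConfig(b_em=b_em, b_my=b_my, theta_dir=theta_dir)
    cfg_a = SimConfig(
        k=k_exposure,
        n_exposure=n_exposure,
        n_outcome=n_outcome,
        n_mediator=n_mediator,
        mediation=med,
        gamma_sd=gamma_sd,
        maf_range=maf_range,
        seed=seed,
    )
    sim_a = simulate_summary_stats(cfg_a)
    cfg_b = SimConfig(
        k=k_mediator,
        n_exposure=n_mediator,  # panel B's "exposure" sample is the mediator GWAS
        n_outcome=n_outcome,
        theta=b_my,
        gamma_sd=gamma_sd,
        maf_range=maf_range,
        seed=seed + 1,
    )
    sim_b = simulate_summary_stats(cfg_b)

    offset = k_exposure

    def _shift(df):
        df = df.copy()
        df["snp"] = [f"rs{int(s[2:]) + offset}" for s in df["snp"]]
        return df

    med_b = _shift(sim_b.exposure.data)  # panel B mediator effects
    out_b = _shift(sim_b.outcome.data)
    # panel B variants have null exposure effects, observed with the
    # exposure GWAS's sampling noise
    rng = np.random.default_rng(seed + 2)
    exp_b = med_b.copy()
    maf_b = np.where(exp_b["eaf"] > 0.5, 1 - exp_b["eaf"], exp_b["eaf"]).astype(float)
    se_b = _se_approx(np.clip(maf_b, 1e-3, 0.5), n_exposure)
    exp_b["beta"] = rng.normal(0.0, se_b)
    exp_b["se"] = se_b
    exp_b["pval"] = _pvals(exp_b["beta"].to_numpy(), se_b)
    exp_b["n"] = n_exposure

    def _cat(tid, a, b):
        return SummaryStats(tid, pd.concat([a, b], ignore_index=True))

    truth = SimTruth(
        theta_total=med.theta_total,
        gamma=np.concatenate([sim_a.truth.gamma, np.zeros(k_mediator)]),
        alpha=np.zeros(k_exposure + k_mediator),
        expected_proportion=med.expected_proportion,
    )
    return MediationStudy(
        exposure=_cat("exposure", sim_a.exposure.data, exp_b),
        mediator=_cat("mediator", sim_a.mediator.data, med_b),
        outcome=_cat("outcome", sim_a.outcome.data, out_b),
        truth=truth,
    )


def make_ld_matrix(cfg: SimConfig) -> LDMatrix:
    """Block-diagonal r-squared matrix with unit diagonal.

    Each block sits on its own chromosome with 500 kb spacing between
    consecutive SNPs, so the distance-window pruning rule has work to do
    within blocks without coupling blocks to each other.
    """
    if cfg.ld_blocks is None:
        raise ConfigurationError("ld_blocks must be set to build an LD matrix")
    size, r2 = cfg.ld_blocks
    k = cfg.k
    snp_ids = [f"rs{i + 1}" for i in range(k)]
    mat = np.zeros((k, k))
    chroms, pos = [], []
    for start in range(0, k, size):
        stop = min(start + size, k)
        mat[start:stop, start:stop] = r2
        block_no = start // size + 1
        for j in range(start, stop):
            chroms.append(f"chr{block_no}")
            pos.append(1_000_000 + (j - start) * 500_000)
    np.fill_diagonal(mat, 1.0)
    positions = pd.DataFrame({"chrom": chroms, "pos": pos}, index=snp_ids)
    return LDMatrix(snp_ids, mat, positions)
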