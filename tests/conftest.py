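"""Shared fixtures and simulation scenarios.

The scenario builders centralize the study conditions used by the
statistical tests: strong instruments (half-normal effect scale 0.1) from
large GWAS (exposure n = 2M, outcome n = 500k) so finite-sample estimator
bias is negligible against Monte-Carlo error at the replication counts used.
"""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tsmr import (
    HarmonizedSet,
    MediationConfig,
    PleiotropyConfig,
    SimConfig,
    build_instrument_set,
    harmonize,
    simulate_summary_stats,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

# simulation loops legitimately skip clumping; don't spam the test log
logging.getLogger("tsmr.instruments").setLevel(logging.ERROR)


THETA_CAL = 0.14  # true causal effect in the calibration scenario


def calibration_config(seed: int, k: int = 100, **overrides) -> SimConfig:
    """Scenario 'none': strong instruments, large samples, no pleiotropy."""
    kw = dict(
        k=k,
        n_exposure=2_000_000,
        n_outcome=500_000,
        theta=THETA_CAL,
        gamma_sd=0.1,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def harmonized_from(cfg: SimConfig) -> HarmonizedSet:
    sim = simulate_summary_stats(cfg)
    return harmonize(sim.exposure, sim.outcome)


def harmonized_selected(cfg: SimConfig) -> HarmonizedSet:
    """Generator output passed through the study's instrument criteria
    (p < 5e-8, F >= 10) before harmonization — the conditions every
    estimator sees in the real design."""
    sim = simulate_summary_stats(cfg)
    iset = build_instrument_set(sim.exposure, ld=None)
    return harmonize(sim.exposure.subset(iset.snp_ids), sim.outcome)


def toy_harmonized(bx, by, sy, sx=None, **kw) -> HarmonizedSet:
    """Single-exposure set from explicit arrays (se_X defaults tiny)."""
    bx = np.asarray(bx, dtype=float)
    k = len(bx)
    sx = np.full(k, 1e-6) if sx is None else np.asarray(sx, dtype=float)
    return HarmonizedSet(
        exposure_ids=["X"],
        outcome_id="Y",
        snp_ids=np.array([f"rs{i}" for i in range(1, k + 1)], dtype=object),
        beta_X=bx.reshape(-1, 1),
        se_X=sx.reshape(-1, 1),
        beta_Y=np.asarray(by, dtype=float),
        se_Y=np.asarray(sy, dtype=float),
        **kw,
    )


@pytest.fixture
def proportional_h() -> HarmonizedSet:
    """Perfectly proportional effects: theta = 0.5 exactly, Q = 0."""
    return toy_harmonized(
        bx=[0.1, 0.2, 0.4], by=[0.05, 0.10, 0.20], sy=[0.01, 0.01, 0.01]
    )


@pytest.fixture
def random_h() -> HarmonizedSet:
    """A generic well-behaved random instance (k = 25)."""
    return harmonized_from(calibration_config(seed=42, k=25))


def stats_frame(rows) -> pd.DataFrame:
    """Build a summary-stats DataFrame from (snp, ea, oa, eaf, beta, se, pval) rows."""
    cols = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"]
    df = pd.DataFrame(rows, columns=cols)
    df["n"] = 10_000
    return df
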