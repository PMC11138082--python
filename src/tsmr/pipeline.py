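"""Config-driven orchestration of the full study design.

A YAML study config declares trait files and roles, instrument-selection
settings, estimator settings (seeds mandatory), the FDR family, MVMR models
and mediation triples.  ``run_uvmr_suite`` runs, for every exposure x outcome
pair: instrument selection -> harmonization -> the five univariable
estimators -> the sensitivity suite (with outlier removal-and-refit) -> FDR
across the declared family.  ``run_mvmr_suite`` and ``run_mediation_suite``
cover the multivariable and two-step stages.  Outputs are TSV tables shaped
like the study's result tables, a machine-readable JSON bundle, and a
manifest of inputs and seeds; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .instruments import (
    LDMatrix,
    build_instrument_set,
    read_exclusion_list,
)
from .mediation import mediation_decompose, mediator_screen
from .multiple_testing import bh_adjust
from .mvmr import mr_lasso, mvmr_egger, mvmr_ivw, mvmr_weighted_median
from .sensitivity import sensitivity_report
from .summary_data import SummaryStats, harmonize, read_summary_stats
from .uvmr import MRResult, ivw, run_all_estimators

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Validated study configuration (see ``load_config``)."""

    traits: dict  # name -> {path, role, column_map?, delimiter?}
    instruments: dict
    estimators: dict
    uvmr_pairs: list[tuple[str, str]]
    mvmr_models: list[dict]
    mediation_triples: list[dict]
    output_dir: str
    base_dir: str = "."

    _DEFAULT_INSTRUMENTS = {
        "p_threshold": 5e-8,
        "r2_max": 0.001,
        "window_kb": 10_000,
        "f_threshold": 10.0,
        "ld_matrix": None,
        "exclusion_lists": {},
    }
    _DEFAULT_ESTIMATORS = {
        "n_boot": 1000,
        "n_sim": 1000,
        "phi": 1.0,
        "seed": 0,
        "palindrome_policy": "drop",
        "eaf_window": 0.08,
    }

    def __post_init__(self):
        self.instruments = {**self._DEFAULT_INSTRUMENTS, **(self.instruments or {})}
        self.estimators = {**self._DEFAULT_ESTIMATORS, **(self.estimators or {})}
        for name, spec in self.traits.items():
            if "path" not in spec or "role" not in spec:
                raise ConfigurationError(f"trait '{name}' needs 'path' and 'role'")
            path = self._resolve(spec["path"])
            if not os.path.exists(path):
                raise ConfigurationError(f"trait file not found: {path}")
        for pair in self.uvmr_pairs:
            for t in pair:
                if t not in self.traits:
                    raise ConfigurationError(f"uvmr pair references unknown trait '{t}'")

    def _resolve(self, path: str) -> str:
        return path if os.path.isabs(path) else os.path.join(self.base_dir, path)

    def load_trait(self, name: str) -> SummaryStats:
        spec = self.traits[name]
        return read_summary_stats(
            self._resolve(spec["path"]),
            trait_id=name,
            column_map=spec.get("column_map"),
            delimiter=spec.get("delimiter", "\t"),
        )

    def load_ld(self) -> LDMatrix | None:
        path = self.instruments.get("ld_matrix")
        return LDMatrix.from_tsv(self._resolve(path)) if path else None

    def exclusion_for(self, name: str) -> list[str]:
        path = (self.instruments.get("exclusion_lists") or {}).get(name)
        return read_exclusion_list(self._resolve(path)) if path else []


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return StudyConfig(
        traits=raw["traits"],
        instruments=raw.get("instruments", {}),
        estimators=raw.get("estimators", {}),
        uvmr_pairs=[tuple(p) for p in raw.get("uvmr", {}).get("pairs", [])],
        mvmr_models=raw.get("mvmr", []),
        mediation_triples=raw.get("mediation", []),
        output_dir=raw.get("output_dir", "tsmr_out"),
        base_dir=os.path.dirname(os.path.abspath(path)),
    )


def _select_and_harmonize(cfg: StudyConfig, exposure_names, outcome_name, ld=None):
    """Instrument selection on each exposure, then harmonization of the union.

    Returns (HarmonizedSet, attrition log dict).
    """
    inst = cfg.instruments
    est = cfg.estimators
    exposures = [cfg.load_trait(n) for n in exposure_names]
    outcome = cfg.load_trait(outcome_name)
    union: list[str] = []
    attrition = {}
    for name, stats in zip(exposure_names, exposures):
        iset = build_instrument_set(
            stats,
            ld=ld,
            p_threshold=inst["p_threshold"],
            r2_max=inst["r2_max"],
            window_kb=inst["window_kb"],
            f_threshold=inst["f_threshold"],
            exclusion_list=cfg.exclusion_for(name),
        )
        attrition[name] = (
            iset.provenance["status"].value_counts().to_dict()
        )
        union.extend(s for s in iset.snp_ids if s not in union)
    subsets = [e.subset(union) for e in exposures]
    h = harmonize(
        subsets,
        outcome,
        palindrome_policy=est["palindrome_policy"],
        eaf_window=est["eaf_window"],
    )
    logger.info(
        "%s -> %s: %d instruments harmonized (%d dropped)",
        "+".join(exposure_names),
        outcome_name,
        h.k,
        len(h.dropped),
    )
    return h, attrition


def _mr_row(outcome, exposure, r: MRResult, extra=None) -> dict:
    row = {
        "outcome": outcome,
        "exposure": exposure,
        "method": r.method,
        "n_snp": r.n_snp,
        "beta": round(r.beta, 6),
        "se": round(r.se, 6),
        "or": round(r.or_, 3),
        "ci_low": round(r.ci_low, 3),
        "ci_high": round(r.ci_high, 3),
        "pval": float(f"{r.pval:.6g}"),
    }
    if extra:
        row.update(extra)
    return row


@dataclass
class SuiteOutcome:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    bundle: dict = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _write_outputs(cfg: StudyConfig, outcome: SuiteOutcome, stem: str) -> None:
    out = cfg._resolve(cfg.output_dir)
    os.makedirs(out, exist_ok=True)
    for name, table in outcome.tables.items():
        table.to_csv(os.path.join(out, f"{stem}_{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(out, f"{stem}_results.json"), "w") as fh:
        json.dump(outcome.bundle, fh, indent=2, sort_keys=True, default=str)
    manifest = {
        "stem": stem,
        "tsmr_version": __version__,
        "seed": cfg.estimators["seed"],
        "inputs": {n: cfg._resolve(s["path"]) for n, s in cfg.traits.items()},
        "instrument_settings": {
            k: v for k, v in cfg.instruments.items() if k != "exclusion_lists"
        },
        "errors": outcome.errors,
    }
    with open(os.path.join(out, f"{stem}_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def run_uvmr_suite(cfg: StudyConfig, write: bool = True) -> SuiteOutcome:
    """Univariable MR + sensitivity for every configured exposure-outcome pair,
    with BH-FDR across the family of IVW p-values."""
    est = cfg.estimators
    ld = cfg.load_ld()
    res = SuiteOutcome()
    main_rows, sens_rows, loo_frames = [], [], []
    ivw_pvals, ivw_keys = [], []
    for exposure, outcome in cfg.uvmr_pairs:
        key = f"{exposure}->{outcome}"
        try:
            h, attrition = _select_and_harmonize(cfg, [exposure], outcome, ld)
            estimates = run_all_estimators(
                h, n_boot=est["n_boot"], phi=est["phi"], seed=est["seed"]
            )
            report = sensitivity_report(h, n_sim=est["n_sim"], seed=est["seed"])
            for r in estimates:
                main_rows.append(_mr_row(outcome, exposure, r))
            ivw_res = estimates[0]
            ivw_pvals.append(ivw_res.pval)
            ivw_keys.append(len(main_rows) - 5)  # row index of this pair's IVW row
            sens = report.to_frame()
            sens.insert(0, "exposure", exposure)
            sens.insert(1, "outcome", outcome)
            sens_rows.append(sens)
            loo = report.loo.copy()
            loo.insert(0, "exposure", exposure)
            loo.insert(1, "outcome", outcome)
            loo_frames.append(loo)
            pair_bundle = {
                "attrition": attrition,
                "n_snp": h.k,
                "ivw_model": "random_effects" if report.heterogeneous else "fixed_like",
                "estimates": [dataclasses.asdict(r) for r in estimates],
                "egger_intercept": report.egger_intercept,
                "q_ivw": report.q_ivw,
                "q_egger": report.q_egger,
            }
            if report.presso is not None:
                pair_bundle["presso"] = {
                    "rss_obs": report.presso.rss_obs,
                    "global_p": report.presso.global_p,
                    "outliers": report.presso.outlier_ids,
                    "refit": dataclasses.asdict(report.presso.refit)
                    if report.presso.refit
                    else None,
                }
                if report.presso.refit is not None:
                    main_rows.append(
                        _mr_row(
                            outcome,
                            exposure,
                            report.presso.refit,
                            {"method": "ivw_post_outlier_removal"},
                        )
                    )
            res.bundle[key] = pair_bundle
        except Exception as exc:  # record and continue with remaining pairs
            logger.exception("UVMR pair %s failed", key)
            res.errors[key] = f"{type(exc).__name__}: {exc}"
    if main_rows:
        table = pd.DataFrame(main_rows)
        if ivw_pvals:
            adj = bh_adjust(np.array(ivw_pvals))
            table["p_fdr"] = np.nan
            table["fdr_tier"] = ""
            for row_idx, a, t in zip(ivw_keys, adj.adjusted, adj.tier):
                table.loc[row_idx, "p_fdr"] = float(f"{a:.6g}")
                table.loc[row_idx, "fdr_tier"] = t
        res.tables["estimates"] = table
    if sens_rows:
        res.tables["sensitivity"] = pd.concat(sens_rows, ignore_index=True)
    if loo_frames:
        res.tables["leave_one_out"] = pd.concat(loo_frames, ignore_index=True)
    if write:
        _write_outputs(cfg, res, "uvmr")
    return res


def run_mvmr_suite(cfg: StudyConfig, write: bool = True) -> SuiteOutcome:
    """Multivariable MR (IVW, Egger, weighted median, lasso) per configured model."""
    est = cfg.estimators
    ld = cfg.load_ld()
    res = SuiteOutcome()
    rows = []
    for model in cfg.mvmr_models:
        exposures = list(model["exposures"])
        outcome = model["outcome"]
        key = f"{'+'.join(exposures)}->{outcome}"
        try:
            h, attrition = _select_and_harmonize(cfg, exposures, outcome, ld)
            fits = [
                mvmr_ivw(h),
                mvmr_egger(h),
                mvmr_weighted_median(h, n_boot=est["n_boot"], seed=est["seed"]),
                mr_lasso(h),
            ]
            res.bundle[key] = {"attrition": attrition, "n_snp": h.k, "methods": {}}
            for fit in fits:
                extra = {}
                if fit.lambda_ is not None:
                    extra = {
                        "lambda": round(fit.lambda_, 6),
                        "valid_set_size": len(fit.lasso_valid_set),
                    }
                for tid, r in zip(fit.exposure_ids, fit.estimates):
                    rows.append(_mr_row(outcome, tid, r, extra))
                res.bundle[key]["methods"][fit.method] = {
                    "estimates": [dataclasses.asdict(r) for r in fit.estimates],
                    "conditional_q": fit.conditional_q,
                    "conditional_f": fit.conditional_f.to_dict()
                    if fit.conditional_f is not None
                    else None,
                    "intercept": fit.intercept,
                    "lambda": fit.lambda_,
                    "valid_set_size": len(fit.lasso_valid_set)
                    if fit.lasso_valid_set is not None
                    else None,
                }
        except Exception as exc:
            logger.exception("MVMR model %s failed", key)
            res.errors[key] = f"{type(exc).__name__}: {exc}"
    if rows:
        res.tables["estimates"] = pd.DataFrame(rows)
    if write:
        _write_outputs(cfg, res, "mvmr")
    return res


def run_mediation_suite(
    cfg: StudyConfig, write: bool = True, screen_alpha: float = 0.05
) -> SuiteOutcome:
    """Two-step mediation per configured (exposure, mediator, outcome) triple.

    Each triple runs three univariable IVW fits — total effect, exposure ->
    mediator, mediator -> outcome — and decomposes with the product of
    coefficients.  Mediators failing the mediator -> outcome screen at
    ``screen_alpha`` are reported but marked not screened-in.
    """
    est = cfg.estimators
    ld = cfg.load_ld()
    res = SuiteOutcome()
    rows = []
    screened: list[tuple[str, MRResult]] = []
    for triple in cfg.mediation_triples:
        exposure, mediator, outcome = (
            triple["exposure"],
            triple["mediator"],
            triple["outcome"],
        )
        key = f"{exposure}-{mediator}->{outcome}"
        try:
            h_te, _ = _select_and_harmonize(cfg, [exposure], outcome, ld)
            h_em, _ = _select_and_harmonize(cfg, [exposure], mediator, ld)
            h_my, _ = _select_and_harmonize(cfg, [mediator], outcome, ld)
            te = ivw(h_te)
            step1 = ivw(h_em)
            step2 = ivw(h_my)
            screened.append((mediator, step2))
            dec = mediation_decompose(
                (te.beta, te.se), (step1.beta, step1.se), (step2.beta, step2.se)
            )
            rows.append(
                {
                    "exposure": exposure,
                    "mediator": mediator,
                    "outcome": outcome,
                    "or_te": f"{dec.or_te[0]:.3f} ({dec.or_te[1]:.3f}-{dec.or_te[2]:.3f})",
                    "or_de": f"{dec.or_de[0]:.3f} ({dec.or_de[1]:.3f}-{dec.or_de[2]:.3f})",
                    "or_ie": f"{dec.or_ie[0]:.3f} ({dec.or_ie[1]:.3f}-{dec.or_ie[2]:.3f})",
                    "proportion": round(dec.prop, 4),
                    "prop_ci_low": round(dec.prop_ci[0], 4),
                    "prop_ci_high": round(dec.prop_ci[1], 4),
                    "ie_pval": float(f"{dec.ie_pval:.4g}"),
                    "mediating": dec.mediating,
                }
            )
            res.bundle[key] = {
                "te": (te.beta, te.se),
                "step1": (step1.beta, step1.se),
                "step2": (step2.beta, step2.se),
                "ie": dec.ie,
                "de": dec.de,
                "proportion": dec.prop,
                "prop_ci": dec.prop_ci,
                "ie_pval": dec.ie_pval,
                "mediating": dec.mediating,
            }
        except Exception as exc:
            logger.exception("mediation triple %s failed", key)
            res.errors[key] = f"{type(exc).__name__}: {exc}"
    if screened:
        retained = mediator_screen(screened, alpha=screen_alpha)
        res.bundle["screen_retained"] = retained
        for row in rows:
            row["screened_in"] = row["mediator"] in retained
    if rows:
        res.tables["mediation"] = pd.DataFrame(rows)
    if write:
        _write_outputs(cfg, res, "mediation")
    return res
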