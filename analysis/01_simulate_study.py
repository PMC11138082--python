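#!/usr/bin/env python
"""Generate the synthetic GWAS study all downstream analyses consume.

Writes, under results/data/:
  * exposure.tsv / mediator.tsv / outcome.tsv — summary statistics for a
    lean-mass-like exposure, a BMI-like mediator, and a knee-OA-like binary
    outcome, built from two instrument panels (one per trait) so the
    two-step design has genuinely disjoint instruments;
  * panel.tsv + ld.tsv — a candidate panel with LD blocks, to exercise
    clumping in the instrument-selection step;
  * truth.json — the generating parameters and implied quantities;
  * study.yaml — the pipeline configuration the later scripts run.

True effects mirror the scale of the worked analysis: exposure -> mediator
0.018, mediator -> outcome 0.61 (log-odds), direct effect 0.173, hence a
total effect of 0.184 and an expected mediated proportion of ~0.0597.
"""

import argparse
import json
import os

import yaml

from tsmr import SimConfig, simulate_mediation_study, simulate_summary_stats
from tsmr.summary_data import write_summary_stats

TRUE = dict(b_em=0.018, b_my=0.61, theta_dir=0.173)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    data_dir = os.path.join(args.out, "data")
    os.makedirs(data_dir, exist_ok=True)

    study = simulate_mediation_study(
        k_exposure=120,
        k_mediator=120,
        n_exposure=450_000,
        n_mediator=450_000,
        n_outcome=400_000,
        gamma_sd=0.03,
        seed=args.seed,
        **TRUE,
    )
    for name, stats in (
        ("exposure", study.exposure),
        ("mediator", study.mediator),
        ("outcome", study.outcome),
    ):
        write_summary_stats(stats, os.path.join(data_dir, f"{name}.tsv"))

    # a small correlated candidate panel for the clumping demonstration
    panel_cfg = SimConfig(k=40, seed=args.seed + 7, ld_blocks=(4, 0.8), gamma_sd=0.03)
    panel = simulate_summary_stats(panel_cfg)
    write_summary_stats(panel.exposure, os.path.join(data_dir, "panel.tsv"))
    panel.ld.to_tsv(os.path.join(data_dir, "ld.tsv"))

    truth = {
        **TRUE,
        "theta_total": study.truth.theta_total,
        "expected_mediated_proportion": study.truth.expected_proportion,
        "seed": args.seed,
    }
    with open(os.path.join(data_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    config = {
        "traits": {
            "alm": {"path": "data/exposure.tsv", "role": "exposure"},
            "bmi": {"path": "data/mediator.tsv", "role": "mediator"},
            "koa": {"path": "data/outcome.tsv", "role": "outcome"},
        },
        "estimators": {"n_boot": 1000, "n_sim": 1000, "seed": args.seed},
        "uvmr": {"pairs": [["alm", "koa"], ["bmi", "koa"]]},
        "mvmr": [{"exposures": ["alm", "bmi"], "outcome": "koa"}],
        "mediation": [{"exposure": "alm", "mediator": "bmi", "outcome": "koa"}],
        "output_dir": "tables",
    }
    with open(os.path.join(args.out, "study.yaml"), "w") as fh:
        yaml.safe_dump(config, fh)

    print(f"wrote synthetic study to {data_dir} (seed {args.seed})")
    print(
        f"true total effect {truth['theta_total']:.4f}, "
        f"expected mediated proportion {truth['expected_mediated_proportion']:.4f}"
    )


if __name__ == "__main__":
    main()
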