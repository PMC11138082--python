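#!/usr/bin/env python
"""Multivariable MR: direct effects of the exposure adjusted for the mediator.

Fits MVMR-IVW, MVMR-Egger, the weighted median regression, and the lasso
variant (per-SNP penalized intercepts, heterogeneity-guided penalty choice,
post-lasso IVW refit) on the union of both traits' instruments, and reports
conditional instrument strength.  Tables under results/tables/.
"""

import argparse
import os

from tsmr.pipeline import load_config, run_mvmr_suite


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    cfg = load_config(os.path.join(args.out, "study.yaml"))
    res = run_mvmr_suite(cfg)
    if not res.ok:
        raise SystemExit(f"failures: {res.errors}")
    table = res.tables["estimates"]
    print("direct effects (adjusted for the other trait):")
    for _, r in table.iterrows():
        extra = ""
        if r["method"] == "mr_lasso" and "valid_set_size" in r:
            extra = f" [valid set {int(r['valid_set_size'])}]"
        print(
            f"  {r['method']:>20s} {r['exposure']:>4s}: OR {r['or']:.3f} "
            f"({r['ci_low']:.3f}-{r['ci_high']:.3f}), p={r['pval']:.3g}{extra}"
        )
    for key, payload in res.bundle.items():
        cf = payload["methods"]["mvmr_ivw"]["conditional_f"]
        print(f"conditional instrument strength {key}: "
              + ", ".join(f"{t}={v:.1f}" for t, v in cf.items()))
    print(f"tables under {cfg._resolve(cfg.output_dir)}")


if __name__ == "__main__":
    main()
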