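#!/usr/bin/env python
"""Sensitivity analyses and the binary-outcome (disease) analogue.

Runs the full pipeline on a 10%-prevalence binary outcome measured in two outcome
studies: per-study MR/MVMR on the log-OR scale, MR-Egger intercepts (directional
pleiotropy, flagged at p < 0.01), Steiger filtering, and the fixed-effect
meta-analysis across the two studies, reported as odds ratios."""

from _shared import CONFIG_T2D, publish, workdir

import pandas as pd

from lifemr.pipeline import run_pipeline, validate_config


def main() -> None:
    cfg = validate_config(CONFIG_T2D)
    out = workdir("t2d")
    run_pipeline(cfg, out)

    res = pd.read_csv(out / "mr_results.tsv", sep="\t")
    ors = res[res["scale"] == "or"]

    def show(method, exposure):
        sel = ors[(ors["method"] == method) & (ors["exposure"] == exposure)]
        for _, r in sel.iterrows():
            print(f"  {method:12s} {exposure:9s} -> {r['outcome']:28s} "
                  f"OR = {r['estimate']:.3f} [{r['ci_low']:.3f}, {r['ci_high']:.3f}] p={r['p']:.2g}")

    print("binary outcome (prevalence 10%), two outcome studies:")
    for m in ("IVW", "MVMR", "meta-IVW", "meta-MVMR"):
        for e in ("child_bmi", "adult_bmi"):
            show(m, e)

    egger = pd.read_csv(out / "egger_intercepts.tsv", sep="\t")
    print(f"Egger intercepts flagged at p<0.01: {int(egger['flagged'].sum())} of {len(egger)}")
    steiger = pd.read_csv(out / "steiger_exclusions.tsv", sep="\t")
    frac = steiger["retained"].mean()
    print(f"Steiger filtering retained {frac:.1%} of instrument rows "
          "(exposure variance explained >= outcome variance explained)")

    publish(out / "mr_results.tsv", rename="mr_results_t2d.tsv")
    publish(out / "egger_intercepts.tsv", rename="egger_intercepts_t2d.tsv")
    publish(out / "steiger_exclusions.tsv", rename="steiger_exclusions_t2d.tsv")
    print("sensitivity tables copied to results/")


if __name__ == "__main__":
    main()
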