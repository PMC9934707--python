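#!/usr/bin/env python
"""Validate the genetic risk scores in the independent cohort.

Builds the childhood- and adulthood-BMI GRS from the clumped instruments and
reports regression R^2, the closed-form variance explained 2 beta^2 MAF(1-MAF),
ROC AUC and per-SD odds ratio for predicting a > 1 SD trait extreme, and the
instrument F-statistic.  The timepoint cross-prediction asymmetry (each score
predicts its own timepoint best) is the key qualitative check."""

import json

from _shared import load_config, publish, workdir

from lifemr.pipeline import run_stage


def main() -> None:
    cfg = load_config()
    out = workdir()
    run_stage("grs", cfg, out)
    rep = json.loads((out / "grs_report.json").read_text())

    for score in ("child_bmi", "adult_bmi"):
        own_target = "child_bmi_true" if score == "child_bmi" else "adult_bmi"
        cross_target = "adult_bmi" if score == "child_bmi" else "child_bmi_true"
        own = rep[f"grs_{score}__vs__{own_target}"]
        cross = rep[f"grs_{score}__vs__{cross_target}"]
        print(f"{score} GRS ({own['n_variants']} variants):")
        print(f"  own timepoint:  R2 = {own['r2_regression']:.3%}  "
              f"AUC = {own['auc']:.3f}  OR/SD = {own['odds_ratio_per_sd']:.2f} "
              f"[{own['or_ci_low']:.2f}, {own['or_ci_high']:.2f}]  F = {own['f_statistic']:.0f}")
        print(f"  cross timepoint: R2 = {cross['r2_regression']:.3%}  AUC = {cross['auc']:.3f}")
        assert own["r2_regression"] > cross["r2_regression"], "cross-prediction asymmetry violated"
    publish(out / "grs_report.json")
    print("asymmetry holds: each score predicts its own timepoint best")


if __name__ == "__main__":
    main()
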