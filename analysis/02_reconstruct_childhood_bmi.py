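#!/usr/bin/env python
"""Reconstruct a continuous childhood BMI from the 3-level recall category.

Anchored truncated sampling from the external reference distribution, then
rank-inverse-normalisation.  Reports the fidelity of the reconstruction against
the (simulated, hence known) true childhood BMI: the Spearman correlation should
sit at the between-category information bound, and the category-conditional means
must be strictly increasing."""

from _shared import load_config, publish, workdir

import numpy as np
import pandas as pd
from scipy import stats

from lifemr.pipeline import run_stage


def main() -> None:
    cfg = load_config()
    out = workdir()
    run_stage("reconstruct", cfg, out)
    pheno = pd.read_csv(out / "exposure_phenotypes_reconstructed.tsv", sep="\t")

    rho = stats.spearmanr(pheno["child_bmi_true"], pheno["child_bmi_recon"]).statistic
    props = np.array(cfg.simulation.recall_proportions)
    q = np.concatenate([[0.0], np.cumsum(props)])
    bound = float(np.sum(props * ((q[:-1] + q[1:]) / 2 - 0.5) ** 2) / (1 / 12))
    print(f"Spearman(reconstructed, true childhood BMI) = {rho:.3f} "
          f"(between-category information bound {bound:.3f})")
    means = pheno.groupby("recall")["child_bmi_recon"].mean()
    print("category-conditional means (kg/m^2):",
          {k: round(means[k], 2) for k in ("thinner", "same", "plumper")})
    print(f"rank-inverse-normalised column mean = {pheno['child_bmi_rint'].mean():.2e}")

    summary = pd.DataFrame(
        {
            "metric": ["spearman_recon_vs_true", "information_bound",
                       "mean_thinner", "mean_same", "mean_plumper"],
            "value": [rho, bound, means["thinner"], means["same"], means["plumper"]],
        }
    )
    path = publish_summary(summary)
    print(f"wrote {path}")


def publish_summary(df: pd.DataFrame):
    from _shared import RESULTS

    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / "reconstruction_fidelity.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


if __name__ == "__main__":
    main()
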