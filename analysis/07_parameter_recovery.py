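#!/usr/bin/env python
"""Monte-Carlo parameter recovery at the headline study conditions.

Replicates the two-sample design (gamma=0.5, delta_child=0, delta_adult=0.6,
75+75 instruments, cohorts of 20,000) and summarises: the univariable childhood
estimate should centre on the path product 0.30, MVMR should separate the null
childhood direct effect from the adulthood one.  Uses 50 replicates here (the
acceptance script runs 200)."""

from _shared import RESULTS

import json

import lifemr.experiments as ex


def main() -> None:
    df = ex.parameter_recovery(n_replicates=50, seed=2028)
    s = ex.summarise_recovery(df)
    print(f"univariable childhood estimate: mean {s['uni_child_mean']:.3f} "
          f"(SD {s['uni_child_sd']:.3f}; path-product truth 0.30)")
    print(f"MVMR childhood direct:  mean {s['mvmr_child_mean']:+.4f}, "
          f"95% CI covers 0 in {s['mvmr_child_coverage']:.0%} of replicates")
    print(f"MVMR adulthood direct:  mean {s['mvmr_adult_mean']:.3f}, "
          f"95% CI covers 0.6 in {s['mvmr_adult_coverage']:.0%} of replicates")
    print("note: non-null MVMR coverage runs below nominal — exposure-side GWAS "
          "noise induces a small systematic attenuation (see docs/methods.md)")

    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "parameter_recovery_replicates.tsv", sep="\t",
              index=False, float_format="%.6g")
    (RESULTS / "parameter_recovery_summary.json").write_text(
        json.dumps(s, indent=2, sort_keys=True) + "\n"
    )
    print(f"wrote {RESULTS / 'parameter_recovery_replicates.tsv'}")


if __name__ == "__main__":
    main()
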