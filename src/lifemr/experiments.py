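"""Monte-Carlo experiments over the synthetic two-sample design.

These are the package's study-level computations: the parameter-recovery experiment
that mirrors the central lifecourse design (does MVMR separate a null childhood
direct effect from a real adulthood direct effect when the univariable childhood
analysis sees the full path product?), the MR-Egger intercept calibration study,
and a Steiger-filter sign-consistency study.  Each is deterministic given its seed
and returns a tidy per-replicate DataFrame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import run_gwas
from .config import SimulationConfig
from .mr import harmonise, mr_egger, mr_ivw, mvmr, steiger_filter
from .simulate import make_two_sample_studies


def recovery_config(seed: int, **overrides) -> SimulationConfig:
    """The parameter-recovery study conditions: 75 child-specific + 75 adult-specific
    variants, gamma = 0.5, no direct childhood effect, adulthood direct effect 0.6,
    two cohorts of 20,000."""
    base = dict(
        seed=seed,
        n_variants_child_specific=75,
        n_variants_adult_specific=75,
        n_variants_shared=0,
        effect_sd_child=0.11,
        effect_sd_adult=0.11,
        gamma_child_to_adult=0.5,
        delta_child_direct=0.0,
        delta_adult_direct=0.6,
        confounder_strength=0.3,
        n_exposure_cohort=20_000,
        n_outcome_cohort=20_000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def recovery_replicate(config: SimulationConfig) -> dict:
    """One replicate: simulate both cohorts, GWAS the three traits, then estimate the
    univariable childhood effect (child-predicting instruments only) and the MVMR
    direct effects on the full variant union."""
    exposure, outcome = make_two_sample_studies(config)
    child = run_gwas(
        exposure.genotypes, exposure.phenotypes["child_bmi_true"],
        exposure.phenotypes, trait_id="child_bmi",
    )
    adult = run_gwas(
        exposure.genotypes, exposure.phenotypes["adult_bmi"],
        exposure.phenotypes, trait_id="adult_bmi",
    )
    outc = run_gwas(
        outcome.genotypes, outcome.phenotypes["outcome"],
        outcome.phenotypes, trait_id="outcome",
    )
    from .simulate import draw_effects

    roles = draw_effects(config).roles
    child_mask = np.isin(roles, ["child", "shared"])
    child_inst = child.loc[child_mask].reset_index(drop=True)
    child_inst.attrs.update(child.attrs)

    h_uni = harmonise(child_inst, outc)
    uni = mr_ivw(h_uni)
    h_mv = harmonise([child, adult], outc)
    mv_child, mv_adult = mvmr(h_mv)
    return {
        "uni_child_estimate": uni.estimate,
        "uni_child_se": uni.se,
        "uni_child_f": uni.f_statistic,
        "mvmr_child_estimate": mv_child.estimate,
        "mvmr_child_ci_low": mv_child.ci_low,
        "mvmr_child_ci_high": mv_child.ci_high,
        "mvmr_adult_estimate": mv_adult.estimate,
        "mvmr_adult_ci_low": mv_adult.ci_low,
        "mvmr_adult_ci_high": mv_adult.ci_high,
        "n_variants_mvmr": mv_child.n_variants,
    }


def parameter_recovery(n_replicates: int = 200, seed: int = 1, **overrides) -> pd.DataFrame:
    """Run ``n_replicates`` independent replicates of the recovery design."""
    rows = []
    for r in range(n_replicates):
        cfg = recovery_config(seed=int(np.random.SeedSequence((seed, r)).generate_state(1)[0] % 2**31), **overrides)
        rows.append(recovery_replicate(cfg))
    df = pd.DataFrame(rows)
    df["mvmr_child_covers_zero"] = (df["mvmr_child_ci_low"] <= 0) & (df["mvmr_child_ci_high"] >= 0)
    df["mvmr_adult_covers_truth"] = (
        (df["mvmr_adult_ci_low"] <= 0.6) & (df["mvmr_adult_ci_high"] >= 0.6)
    )
    return df


def summarise_recovery(df: pd.DataFrame) -> dict:
    return {
        "uni_child_mean": float(df["uni_child_estimate"].mean()),
        "uni_child_sd": float(df["uni_child_estimate"].std(ddof=1)),
        "path_product_truth": 0.3,
        "mvmr_child_coverage": float(df["mvmr_child_covers_zero"].mean()),
        "mvmr_adult_coverage": float(df["mvmr_adult_covers_truth"].mean()),
        "mvmr_child_mean": float(df["mvmr_child_estimate"].mean()),
        "mvmr_adult_mean": float(df["mvmr_adult_estimate"].mean()),
        "n_replicates": int(len(df)),
    }


def egger_calibration(
    n_sims: int = 1000,
    seed: int = 2,
    k: int = 100,
    slope: float = 0.2,
    pleiotropy: float = 0.0,
) -> pd.DataFrame:
    """Summary-level Egger intercept study: by_j = slope*bx_j + pleiotropy + N(0, sy_j^2).

    Under pleiotropy = 0 the intercept test should reject at its nominal 5% level;
    with a constant injected pleiotropy the intercept should estimate it.
    """
    from .mr import HarmonisedSet

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_sims):
        bx = np.abs(rng.normal(0.08, 0.04, size=k))
        sx = np.full(k, 0.01)
        sy = rng.uniform(0.01, 0.03, size=k)
        by = slope * bx + pleiotropy + rng.normal(0, sy)
        table = pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(k)],
                "EA": "A", "OA": "G", "EAF": 0.3, "PROXY": ".",
                "BX_x": bx, "SX_x": sx, "NX_x": 10_000,
                "BY": by, "SY": sy, "NY": 10_000,
            }
        )
        h = HarmonisedSet(table, ["x"], "y")
        egger = mr_egger(h)
        rows.append(
            {
                "intercept": egger.intercept,
                "intercept_se": egger.intercept_se,
                "intercept_p": egger.intercept_p,
                "slope": egger.slope.estimate,
            }
        )
    return pd.DataFrame(rows)


def steiger_sign_consistency(
    n_replicates: int = 200, seed: int = 3, k: int = 50, slope: float = 0.3
) -> pd.DataFrame:
    """Without reverse causation, Steiger filtering should essentially never flip the
    sign of a true nonzero effect."""
    from .mr import HarmonisedSet

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        bx = rng.normal(0.0, 0.08, size=k)
        sy = rng.uniform(0.01, 0.04, size=k)
        by = slope * bx + rng.normal(0, sy)
        table = pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(k)],
                "EA": "A", "OA": "G", "EAF": rng.uniform(0.05, 0.5, size=k), "PROXY": ".",
                "BX_x": bx, "SX_x": 0.01, "NX_x": 10_000,
                "BY": by, "SY": sy, "NY": 10_000,
            }
        )
        h = HarmonisedSet(table, ["x"], "y")
        before = mr_ivw(h)
        kept, _ = steiger_filter(h)
        after = mr_ivw(kept) if kept.n_variants >= 1 else None
        rows.append(
            {
                "estimate_before": before.estimate,
                "estimate_after": after.estimate if after else np.nan,
                "n_before": h.n_variants,
                "n_after": kept.n_variants,
                "sign_consistent": bool(after and np.sign(after.estimate) == np.sign(slope)),
            }
        )
    return pd.DataFrame(rows)
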