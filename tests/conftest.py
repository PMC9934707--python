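import numpy as np
import pandas as pd
import pytest

from lifemr import SimulationConfig, make_two_sample_studies


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale two-sample study with discoverable instruments at n = 2,000."""
    return SimulationConfig(
        seed=11,
        n_variants_child_specific=8,
        n_variants_adult_specific=8,
        n_variants_shared=4,
        effect_sd_child=0.28,
        effect_sd_adult=0.28,
        gamma_child_to_adult=0.5,
        delta_child_direct=0.0,
        delta_adult_direct=0.5,
        n_exposure_cohort=2000,
        n_outcome_cohort=2000,
    )


@pytest.fixture(scope="session")
def small_studies(small_config):
    return make_two_sample_studies(small_config)


def make_sumstats(
    snps,
    betas,
    ses,
    *,
    eafs=None,
    ea="A",
    oa="G",
    chrom=1,
    positions=None,
    n=10_000,
    trait_id="trait",
    trait_kind="quantitative",
) -> pd.DataFrame:
    """Hand-rolled summary-stat table for estimator tests."""
    from scipy.stats import norm

    k = len(snps)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    eafs = np.full(k, 0.3) if eafs is None else np.asarray(eafs, float)
    df = pd.DataFrame(
        {
            "SNP": snps,
            "CHR": chrom,
            "BP": positions if positions is not None else 1 + np.arange(k) * 1_000_000,
            "EA": [ea] * k if isinstance(ea, str) else ea,
            "OA": [oa] * k if isinstance(oa, str) else oa,
            "EAF": eafs,
            "BETA": betas,
            "SE": ses,
            "P": 2 * norm.sf(np.abs(betas / ses)),
            "N": n,
        }
    )
    df.attrs["trait_id"] = trait_id
    df.attrs["trait_kind"] = trait_kind
    return df
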