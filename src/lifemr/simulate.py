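"""Synthetic genotype/phenotype cohorts under the assumed lifecourse causal diagram.

The generative model (per individual i, variant j with effect-allele dosage G_ij):

    child_i   = sum_j G_ij b_child_j  + c U_i + eps_i
    adult_i   = gamma child_i + sum_j G_ij b_adult_j + c U_i + eps'_i
    outcome_i = d_child child_i + d_adult adult_i + sum_j G_ij b_pleio_j + c U_i + eps''_i

with U a hidden standard-normal confounder and c = ``confounder_strength``.  Residual
variances are solved analytically from the drawn effects so every trait has population
variance exactly 1: path coefficients are therefore exact SD/SD estimands, and genetic
effects are in SD units per effect allele.  A binary outcome replaces the last equation
by a logistic draw on the same linear predictor, with the intercept solved numerically
for the target prevalence.

Variants are simulated without LD (independent binomial dosages); a dedicated
haplotype-copy LD panel generator is provided separately for exercising clumping and
proxy search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import (
    RECALL_LEVELS,
    STREAM_EFFECTS,
    STREAM_EXPOSURE_GENO,
    STREAM_EXPOSURE_PHENO,
    STREAM_OUTCOME_GENO,
    STREAM_OUTCOME_PHENO,
    STREAM_PANEL,
    STREAM_RECALL,
    SimulationConfig,
    substream,
)
from .errors import ConfigurationError

VARIANT_SPACING = 1_000_000  # bp between simulated independent variants
CHROM_SIZE = 50  # variants per simulated chromosome

PHENOTYPE_COLUMNS = ["iid", "child_bmi_true", "adult_bmi", "recall", "outcome", "sex", "age", "centre"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with its variant annotation.

    ``variants`` columns: id, chrom, pos (1-based), ea, oa, eaf (true simulated
    frequency), optionally info.  ``dosages`` is individuals x variants in [0, 2].
    """

    iids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.iids = np.asarray(self.iids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.iids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.iids)} individuals x {len(self.variants)} variants"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.iids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def empirical_eaf(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(idx[0])

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def subset_variants(self, ids) -> "GenotypeMatrix":
        order = [self.index_of(v) for v in ids]
        return GenotypeMatrix(
            self.iids, self.variants.iloc[order].reset_index(drop=True), self.dosages[:, order]
        )


@dataclass
class TrueEffects:
    """Per-variant true effect vectors drawn for one configuration (SD units/allele)."""

    b_child: np.ndarray
    b_adult: np.ndarray
    b_pleio: np.ndarray
    roles: np.ndarray  # "child" | "adult" | "shared" per variant


@dataclass
class Study:
    """One cohort: genotypes plus analysis-facing phenotypes."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame


def _variant_frame(n_variants: int, eafs: np.ndarray) -> pd.DataFrame:
    alleles = ["A", "C", "G", "T"]
    chrom = 1 + np.arange(n_variants) // CHROM_SIZE
    pos = 1 + (np.arange(n_variants) % CHROM_SIZE) * VARIANT_SPACING
    # deterministic non-palindromic allele pairs
    ea = [alleles[j % 2] for j in range(n_variants)]          # A or C
    oa = [alleles[2 + (j % 2)] for j in range(n_variants)]    # G or T
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(n_variants)],
            "chrom": chrom.astype(int),
            "pos": pos.astype(int),
            "ea": ea,
            "oa": oa,
            "eaf": eafs,
        }
    )


def draw_variant_panel(config: SimulationConfig) -> pd.DataFrame:
    """The shared variant annotation (ids, positions, true frequencies) of both cohorts."""
    rng = substream(config.require_seed(), STREAM_PANEL)
    lo, hi = config.maf_range
    eafs = rng.uniform(lo, hi, size=config.n_variants)
    return _variant_frame(config.n_variants, eafs)


def simulate_genotypes(
    config: SimulationConfig,
    n_individuals: int,
    *,
    variants: pd.DataFrame | None = None,
    geno_stream: int = STREAM_EXPOSURE_GENO,
    iid_prefix: str = "IND",
) -> GenotypeMatrix:
    """Binomial(2, eaf) dosages for ``n_individuals`` on the configured variant panel."""
    if n_individuals <= 0:
        raise ConfigurationError("n_individuals must be > 0")
    if variants is None:
        variants = draw_variant_panel(config)
    rng = substream(config.require_seed(), geno_stream)
    eafs = variants["eaf"].to_numpy()
    dosages = rng.binomial(2, eafs, size=(n_individuals, len(variants))).astype(float)
    iids = np.array([f"{iid_prefix}{i + 1:06d}" for i in range(n_individuals)])
    return GenotypeMatrix(iids, variants.copy(), dosages)


def draw_effects(config: SimulationConfig) -> TrueEffects:
    """Draw the per-variant effect vectors once per configuration (seed substream).

    Shared variants receive child/adult effects from a bivariate normal with
    correlation ``shared_effect_correlation`` so that variants with larger adulthood
    than childhood effects (and vice versa) arise naturally.
    """
    rng = substream(config.require_seed(), STREAM_EFFECTS)
    nc, na, ns = (
        config.n_variants_child_specific,
        config.n_variants_adult_specific,
        config.n_variants_shared,
    )
    m = nc + na + ns
    roles = np.array(["child"] * nc + ["adult"] * na + ["shared"] * ns)
    b_child = np.zeros(m)
    b_adult = np.zeros(m)
    b_child[:nc] = rng.normal(0.0, config.effect_sd_child, size=nc)
    b_adult[nc : nc + na] = rng.normal(0.0, config.effect_sd_adult, size=na)
    if ns:
        rho = config.shared_effect_correlation
        z1 = rng.normal(size=ns)
        z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=ns)
        b_child[nc + na :] = config.effect_sd_child * z1
        b_adult[nc + na :] = config.effect_sd_adult * z2
    b_pleio = np.zeros(m)
    if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0:
        scope = {
            "all": np.ones(m, bool),
            "shared": roles == "shared",
            "child": roles == "child",
            "adult": roles == "adult",
        }[config.pleiotropy_scope]
        b_pleio[scope] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=scope.sum())
    return TrueEffects(b_child, b_adult, b_pleio, roles)


def _genic_var(b: np.ndarray, eaf: np.ndarray) -> float:
    return float(np.sum(b**2 * 2 * eaf * (1 - eaf)))


def _cross_cov(b1: np.ndarray, b2: np.ndarray, eaf: np.ndarray) -> float:
    return float(np.sum(b1 * b2 * 2 * eaf * (1 - eaf)))


def _residual_sd(total_structural_var: float, what: str) -> float:
    resid = 1.0 - total_structural_var
    if resid <= 0:
        raise ConfigurationError(
            f"structural variance of {what} is {total_structural_var:.3f} >= 1; "
            "reduce effect sizes, paths or confounding so traits can be unit-variance"
        )
    return float(np.sqrt(resid))


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    *,
    effects: TrueEffects | None = None,
    pheno_stream: int = STREAM_EXPOSURE_PHENO,
    with_recall: bool = True,
) -> pd.DataFrame:
    """Generate the phenotype table for one cohort.

    The effect vectors are drawn from a dedicated seed substream, so two cohorts built
    from the same config share identical true effects while ``pheno_stream`` keeps their
    phenotype noise independent.  The hidden confounder is returned in column
    ``confounder`` for diagnostics but is excluded from written outputs.
    """
    if effects is None:
        effects = draw_effects(config)
    m = genotypes.n_variants
    if len(effects.b_child) != m:
        raise ConfigurationError(
            f"variant partition ({len(effects.b_child)}) does not match genotype panel ({m})"
        )
    rng = substream(config.require_seed(), pheno_stream)
    n = genotypes.n_individuals
    eaf = genotypes.variants["eaf"].to_numpy()
    G = genotypes.dosages
    c = config.confounder_strength
    gamma = config.gamma_child_to_adult
    dc, da = config.delta_child_direct, config.delta_adult_direct

    U = rng.normal(size=n)
    gc = G @ effects.b_child
    ga = G @ effects.b_adult
    gp = G @ effects.b_pleio

    var_gc = _genic_var(effects.b_child, eaf)
    sd_eps_child = _residual_sd(var_gc + c**2, "childhood BMI")
    child = gc + c * U + rng.normal(scale=sd_eps_child, size=n)

    var_ga = _genic_var(effects.b_adult, eaf)
    cov_child_ga = _cross_cov(effects.b_child, effects.b_adult, eaf)
    cov_child_U = c
    var_adult_struct = (
        gamma**2 + var_ga + c**2 + 2 * gamma * cov_child_ga + 2 * gamma * c * cov_child_U
    )
    sd_eps_adult = _residual_sd(var_adult_struct, "adulthood BMI")
    adult = gamma * child + ga + c * U + rng.normal(scale=sd_eps_adult, size=n)

    # exact population covariances needed for the outcome's structural variance
    cov_child_adult = gamma + cov_child_ga + c * cov_child_U
    cov_child_gp = _cross_cov(effects.b_child, effects.b_pleio, eaf)
    cov_adult_gp = gamma * cov_child_gp + _cross_cov(effects.b_adult, effects.b_pleio, eaf)
    cov_adult_U = gamma * c + c
    var_gp = _genic_var(effects.b_pleio, eaf)
    lin = dc * child + da * adult + gp + c * U
    var_lin = (
        dc**2
        + da**2
        + var_gp
        + c**2
        + 2 * dc * da * cov_child_adult
        + 2 * dc * cov_child_gp
        + 2 * da * cov_adult_gp
        + 2 * dc * c * cov_child_U
        + 2 * da * c * cov_adult_U
    )

    # small nuisance covariates, independent of genotype
    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(40.0, 70.0, size=n)
    centre = rng.integers(0, config.n_centres, size=n)
    centre_effects = rng.normal(0.0, config.centre_effect_sd, size=config.n_centres)
    nuisance = (
        config.sex_effect * (sex - 0.5)
        + config.age_effect_per_year * (age - 55.0)
        + centre_effects[centre]
    )

    if config.outcome_kind == "quantitative":
        sd_eps_out = _residual_sd(var_lin, "quantitative outcome")
        outcome = lin + rng.normal(scale=sd_eps_out, size=n)
        outcome = outcome + nuisance
        outcome_col = outcome
    else:
        alpha = _solve_prevalence_intercept(lin + nuisance, config.binary_prevalence)
        outcome_col = rng.binomial(1, expit(alpha + lin + nuisance)).astype(int)

    child = child + nuisance
    adult = adult + nuisance

    table = pd.DataFrame(
        {
            "iid": genotypes.iids,
            "child_bmi_true": child,
            "adult_bmi": adult,
            "recall": pd.NA,
            "outcome": outcome_col,
            "sex": sex,
            "age": age,
            "centre": centre,
            "confounder": U,
        }
    )
    if with_recall:
        table["recall"] = discretize_recall(child, config.recall_proportions)
    return table


def _solve_prevalence_intercept(lin: np.ndarray, prevalence: float) -> float:
    """Logistic intercept such that mean case probability equals the target prevalence."""

    def gap(alpha: float) -> float:
        return float(expit(alpha + lin).mean() - prevalence)

    return brentq(gap, -40.0, 40.0, xtol=1e-10)


def discretize_recall(child_values: np.ndarray, proportions) -> np.ndarray:
    """Assign thinner/same/plumper by empirical quantile cutpoints.

    Cutpoints are the empirical quantiles at the cumulative proportions; values equal
    to a cutpoint go to the lower category (documented tie policy — a constant vector
    therefore collapses to a single category).
    """
    proportions = np.asarray(proportions, dtype=float)
    if len(proportions) != 3 or np.any(proportions <= 0):
        raise ConfigurationError("proportions must be 3 positive numbers")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ConfigurationError("proportions must sum to 1 (tolerance 1e-9)")
    values = np.asarray(child_values, dtype=float)
    q1, q2 = np.quantile(values, [proportions[0], proportions[0] + proportions[1]])
    cats = np.where(values <= q1, RECALL_LEVELS[0], np.where(values <= q2, RECALL_LEVELS[1], RECALL_LEVELS[2]))
    return cats


def make_two_sample_studies(config: SimulationConfig) -> tuple[Study, Study]:
    """Two cohorts sharing the variant panel and true effects, with disjoint individuals.

    The exposure cohort carries the recall category; both cohorts carry all traits so
    the outcome cohort can serve as an independent validation cohort.
    """
    panel = draw_variant_panel(config)
    effects = draw_effects(config)
    geno_exp = simulate_genotypes(
        config, config.n_exposure_cohort, variants=panel,
        geno_stream=STREAM_EXPOSURE_GENO, iid_prefix="EXP",
    )
    geno_out = simulate_genotypes(
        config, config.n_outcome_cohort, variants=panel,
        geno_stream=STREAM_OUTCOME_GENO, iid_prefix="OUT",
    )
    pheno_exp = simulate_phenotypes(
        geno_exp, config, effects=effects, pheno_stream=STREAM_EXPOSURE_PHENO
    )
    pheno_out = simulate_phenotypes(
        geno_out, config, effects=effects, pheno_stream=STREAM_OUTCOME_PHENO
    )
    return Study(geno_exp, pheno_exp), Study(geno_out, pheno_out)


def simulate_ld_panel(
    n_individuals: int,
    n_blocks: int,
    block_size: int,
    seed: int,
    *,
    copy_prob: float = 0.9,
    maf_range: tuple[float, float] = (0.1, 0.5),
    spacing: int = 50_000,
) -> GenotypeMatrix:
    """A reference panel with block LD, for exercising clumping and proxy search.

    Haplotype-copy model: within a block, each variant's allele copies the previous
    variant's allele with probability ``copy_prob`` on each of the two haplotypes,
    otherwise it is drawn fresh at that variant's frequency.  Blocks are independent;
    adjacent variants within a block are strongly correlated, decaying with distance.
    """
    rng = np.random.default_rng(seed)
    m = n_blocks * block_size
    eafs = rng.uniform(*maf_range, size=m)
    hap = np.empty((2 * n_individuals, m), dtype=np.int8)
    for b in range(n_blocks):
        for k in range(block_size):
            j = b * block_size + k
            fresh = rng.random(2 * n_individuals) < (1 - copy_prob)
            draw = (rng.random(2 * n_individuals) < eafs[j]).astype(np.int8)
            if k == 0:
                hap[:, j] = draw
            else:
                hap[:, j] = np.where(fresh, draw, hap[:, j - 1])
    dosages = (hap[::2] + hap[1::2]).astype(float)
    variants = _variant_frame(m, dosages.mean(axis=0) / 2.0)
    variants["pos"] = 1 + np.arange(m) * spacing
    variants["chrom"] = 1  # single chromosome; blocks are close enough to fall in clump windows
    iids = np.array([f"REF{i + 1:06d}" for i in range(n_individuals)])
    return GenotypeMatrix(iids, variants, dosages)


def write_phenotypes(table: pd.DataFrame, path: str) -> None:
    """Write the analysis-facing phenotype TSV (hidden confounder excluded)."""
    out = table.loc[:, PHENOTYPE_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
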