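"""Genetic risk scores and instrument-validation metrics.

A GRS is the weighted sum of effect-allele dosages over the clumped instruments.
Validation mirrors the original design: regression R^2 of the score against the
trait, the closed-form variance explained 2 beta^2 MAF (1 - MAF) summed over
instruments, ROC/odds-ratio prediction of the trait being > 1 SD above its mean,
and the R^2-based instrument F-statistic (F > 10 is the conventional adequacy bar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import HarmonisationError
from .simulate import GenotypeMatrix


def build_grs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    *,
    on_missing: str = "error",
) -> np.ndarray:
    """score_i = sum_j w_j * dosage_ij, dosages oriented to each weight's effect allele.

    ``weights`` is a summary-stat table (SNP, EA, OA, BETA).  A weight whose alleles
    match the panel swapped has its dosage flipped to 2 - d; unmatchable alleles raise
    a harmonisation error naming the variant.  Missing variants: error by default,
    ``on_missing="skip"`` drops them with a warning.
    """
    if on_missing not in ("error", "skip"):
        raise ValueError("on_missing must be 'error' or 'skip'")
    panel = genotypes.variants.set_index("id")
    scores = np.zeros(genotypes.n_individuals)
    for row in weights.itertuples(index=False):
        snp = row.SNP
        if snp not in panel.index:
            if on_missing == "error":
                raise KeyError(f"GRS weight variant {snp} absent from genotypes")
            import warnings

            warnings.warn(f"GRS weight variant {snp} missing; skipped", stacklevel=2)
            continue
        ea, oa = panel.loc[snp, "ea"], panel.loc[snp, "oa"]
        d = genotypes.dosage_vector(snp)
        if (row.EA, row.OA) == (ea, oa):
            pass
        elif (row.EA, row.OA) == (oa, ea):
            d = 2.0 - d
        else:
            raise HarmonisationError(
                f"variant {snp}: weight alleles {row.EA}/{row.OA} unmatchable to panel {ea}/{oa}"
            )
        scores = scores + float(row.BETA) * d
    return scores


def variance_explained_formula(betas, eafs) -> float:
    """Sum of 2 beta_j^2 MAF_j (1 - MAF_j) over instruments (betas in SD units)."""
    betas = np.asarray(betas, dtype=float)
    eafs = np.asarray(eafs, dtype=float)
    if np.any((eafs <= 0) | (eafs >= 1)):
        raise ValueError("effect-allele frequencies must lie strictly inside (0, 1)")
    maf = np.minimum(eafs, 1 - eafs)
    return float(np.sum(2.0 * betas**2 * maf * (1 - maf)))


def grs_regression_r2(scores, phenotype) -> float:
    """Squared Pearson correlation between the score and the trait."""
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if len(scores) != len(phenotype) or len(scores) < 3:
        raise ValueError("scores and phenotype must have equal length >= 3")
    if np.ptp(scores) == 0:
        raise ValueError("zero-variance score")
    r = np.corrcoef(scores, phenotype)[0, 1]
    return float(r * r)


@dataclass
class ExtremePrediction:
    """ROC and per-SD odds ratio for predicting a > 1 SD trait extreme from the score."""

    auc: float
    odds_ratio_per_sd: float
    or_ci_low: float
    or_ci_high: float
    or_p: float
    converged: bool
    n_cases: int
    n_controls: int


def extreme_prediction(scores, phenotype) -> ExtremePrediction:
    """Label = standardised trait > 1; AUC is the Mann-Whitney statistic of the scores,
    OR per 1-SD of score from logistic regression with a Wald 95% CI."""
    import statsmodels.api as sm
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("zero-variance score")
    z_pheno = (phenotype - phenotype.mean()) / phenotype.std(ddof=0)
    label = (z_pheno > 1.0).astype(int)
    if label.sum() == 0 or label.sum() == len(label):
        raise ValueError("one extreme-prediction class is empty")
    auc = float(roc_auc_score(label, scores))
    z_score = (scores - scores.mean()) / scores.std(ddof=0)
    X = np.column_stack([np.ones_like(z_score), z_score])
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(label, X).fit(disp=0, maxiter=100)
        b, s = float(fit.params[1]), float(fit.bse[1])
        if not fit.mle_retvals.get("converged", False) or not np.isfinite(s) or s > 50:
            raise ValueError("non-converged")
        from scipy.stats import norm

        return ExtremePrediction(
            auc=auc,
            odds_ratio_per_sd=float(np.exp(b)),
            or_ci_low=float(np.exp(b - 1.959963984540054 * s)),
            or_ci_high=float(np.exp(b + 1.959963984540054 * s)),
            or_p=float(2 * norm.sf(abs(b / s))),
            converged=True,
            n_cases=int(label.sum()),
            n_controls=int(len(label) - label.sum()),
        )
    except Exception:
        return ExtremePrediction(
            auc=auc,
            odds_ratio_per_sd=float("nan"),
            or_ci_low=float("nan"),
            or_ci_high=float("nan"),
            or_p=float("nan"),
            converged=False,
            n_cases=int(label.sum()),
            n_controls=int(len(label) - label.sum()),
        )


def instrument_f_statistic(r2: float, n: int, k: int) -> float:
    """Multi-instrument F from the score R^2: F = (r2/(1-r2)) * (n-k-1)/k."""
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if k < 1 or n <= k + 1:
        raise ValueError("need n > k + 1 >= 2")
    return float((r2 / (1 - r2)) * ((n - k - 1) / k))


def mean_chisq_f_statistic(betas, ses) -> float:
    """Alternative per-variant instrument strength: mean (beta/se)^2 over instruments."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    return float(np.mean((betas / ses) ** 2))


@dataclass
class GRSReport:
    """Validation metrics for one score against one trait."""

    trait: str
    n: int
    n_variants: int
    r2_regression: float
    var_explained_formula: float
    f_statistic: float
    extreme: ExtremePrediction

    def to_dict(self) -> dict:
        d = {
            "trait": self.trait,
            "n": self.n,
            "n_variants": self.n_variants,
            "r2_regression": self.r2_regression,
            "var_explained_formula": self.var_explained_formula,
            "f_statistic": self.f_statistic,
            "auc": self.extreme.auc,
            "odds_ratio_per_sd": self.extreme.odds_ratio_per_sd,
            "or_ci_low": self.extreme.or_ci_low,
            "or_ci_high": self.extreme.or_ci_high,
            "or_p": self.extreme.or_p,
        }
        return d


def validate_grs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    phenotype,
    trait: str,
) -> GRSReport:
    """Build the score and assemble the full validation report against one trait."""
    scores = build_grs(genotypes, weights)
    r2 = grs_regression_r2(scores, phenotype)
    vef = variance_explained_formula(weights["BETA"], weights["EAF"])
    k = len(weights)
    f = instrument_f_statistic(r2, genotypes.n_individuals, k)
    extreme = extreme_prediction(scores, phenotype)
    return GRSReport(
        trait=trait,
        n=genotypes.n_individuals,
        n_variants=k,
        r2_regression=r2,
        var_explained_formula=vef,
        f_statistic=f,
        extreme=extreme,
    )
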