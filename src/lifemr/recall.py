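"""Continuous childhood-BMI reconstruction from the 3-level body-size recall.

Adults report whether they were "thinner", "the same size as" or "plumper" than their
peers around age 10.  Each individual is assigned a continuous BMI by sampling from an
external reference distribution of measured childhood BMI, truncated to the stratum of
that individual's category; stratum boundaries are the reference-distribution quantiles
at the cumulative category proportions.  Pooling the three truncated strata at the
category proportions reassembles the parent distribution, so the reconstruction adds no
systematic distortion — it restores a continuous, GWAS-ready phenotype from the
categorical recall.  The reconstructed values are rank-inverse-normalised before
association testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import RECALL_LEVELS


@dataclass(frozen=True)
class ReferenceDistribution:
    """External childhood-BMI distribution anchoring the recall categories.

    mean/sd are on the natural kg/m^2 scale for both families; for the lognormal
    family the underlying log-scale parameters are solved by moment inversion.
    category_quantiles are the two cumulative probabilities splitting the
    distribution into thinner/same/plumper strata.
    """

    mean: float
    sd: float
    family: str
    category_quantiles: tuple[float, float]

    def _dist(self):
        if self.family == "normal":
            return stats.norm(loc=self.mean, scale=self.sd)
        # lognormal with natural-scale mean m and sd s:
        #   sigma^2 = log(1 + s^2/m^2),  mu = log(m) - sigma^2/2
        sigma2 = np.log1p(self.sd**2 / self.mean**2)
        sigma = float(np.sqrt(sigma2))
        mu = float(np.log(self.mean) - sigma2 / 2.0)
        return stats.lognorm(s=sigma, scale=np.exp(mu))

    def cutpoints(self) -> tuple[float, float]:
        """Natural-scale BMI values at the two category boundaries."""
        d = self._dist()
        q1, q2 = self.category_quantiles
        return float(d.ppf(q1)), float(d.ppf(q2))


def fit_reference_distribution(
    mean: float, sd: float, family: str = "normal", category_proportions=(1 / 3, 1 / 3, 1 / 3)
) -> ReferenceDistribution:
    """Build the reference distribution from summary statistics and category proportions."""
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"sd must be positive, got {sd!r}")
    if family == "lognormal" and (not np.isfinite(mean) or mean <= 0):
        raise ValueError("lognormal family requires a positive mean")
    if family not in ("normal", "lognormal"):
        raise ValueError(f"unknown family {family!r}")
    props = np.asarray(category_proportions, dtype=float)
    if len(props) != 3 or np.any(props <= 0):
        raise ValueError("category_proportions must be 3 strictly positive numbers")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("category_proportions must sum to 1")
    q1 = float(props[0])
    q2 = float(props[0] + props[1])
    return ReferenceDistribution(float(mean), float(sd), family, (q1, q2))


def assign_continuous_bmi(categories, refdist: ReferenceDistribution, seed: int) -> np.ndarray:
    """Draw each individual's BMI from the reference distribution truncated to its stratum.

    Inverse-CDF sampling: u ~ Uniform over the stratum's probability interval,
    value = F^{-1}(u); draws are independent across individuals and deterministic
    given the seed.
    """
    categories = np.asarray(categories, dtype=object)
    known = set(RECALL_LEVELS)
    bad = sorted(set(categories) - known)
    if bad:
        raise ValueError(f"unknown recall categories: {bad}; expected {RECALL_LEVELS}")
    rng = np.random.default_rng(seed)
    q1, q2 = refdist.category_quantiles
    bounds = {
        RECALL_LEVELS[0]: (0.0, q1),
        RECALL_LEVELS[1]: (q1, q2),
        RECALL_LEVELS[2]: (q2, 1.0),
    }
    dist = refdist._dist()
    u = rng.uniform(size=len(categories))
    lo = np.array([bounds[c][0] for c in categories])
    hi = np.array([bounds[c][1] for c in categories])
    return np.asarray(dist.ppf(lo + u * (hi - lo)), dtype=float)


def rank_inverse_normalise(values) -> np.ndarray:
    """Blom rank-based inverse normal transform: Phi^{-1}((rank - 3/8) / (n + 1/4)).

    Ties receive the average rank and therefore identical output; output is strictly
    monotone in the input ranks and has mean ~0 by symmetry of the score set.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-d vector with at least 2 values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; rank transform undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(values) + 0.25))
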