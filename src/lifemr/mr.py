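"""Two-sample Mendelian randomisation engine.

Harmonisation aligns every variant's exposure and outcome effects to a single effect
allele (frequency-resolving palindromic variants, dropping ambiguous ones), with an
LD-based proxy lookup for instruments absent from the outcome study.  Estimators:

* IVW — weighted regression of variant-outcome on variant-exposure effects through
  the origin, weights 1/se_Y^2, fixed-effect standard errors.
* MR-Egger — the same regression with a free intercept; the intercept estimates the
  average directional pleiotropic effect, the slope remains a (lower-power) causal
  estimate.  Uses the regression-estimated residual scale with t(k-2) tests.
* MVMR — weighted multiple regression of variant-outcome effects on two exposures'
  variant effects without intercept; each coefficient is that exposure's direct
  effect conditional on the other.
* Steiger filtering — drops variants explaining more variance in the outcome than
  in the exposure (2 beta^2 MAF (1-MAF) on both sides), guarding against reverse
  causation.
* Fixed-effect inverse-variance meta-analysis across outcome studies, with log-OR
  results pooled on the log scale and exponentiated only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    HarmonisationError,
    InsufficientInstrumentsError,
    NonIdentifiedError,
    ProxyLookupError,
    ScaleMismatchError,
    WeakConditionalInstrumentError,
)
from .simulate import GenotypeMatrix

Z95 = float(sps.norm.ppf(0.975))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_EAF_ZONE = 0.08  # |EAF - 0.5| <= zone -> ambiguous, variant dropped


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


@dataclass
class HarmonisedSet:
    """Allele-aligned exposure(s) and outcome effects, one row per instrument variant.

    ``table`` columns: SNP, EA, OA, EAF, then BX_<exposure>/SX_<exposure>/NX_<exposure>
    per exposure, BY, SY, NY, PROXY ('.' when the variant itself was present).
    """

    table: pd.DataFrame
    exposure_ids: list
    outcome_id: str
    outcome_scale: str = "sd"  # "sd" for quantitative, "log_or" for binary outcomes
    drops: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def bx(self, exposure: str | None = None) -> np.ndarray:
        return self.table[f"BX_{exposure or self.exposure_ids[0]}"].to_numpy(float)

    def sx(self, exposure: str | None = None) -> np.ndarray:
        return self.table[f"SX_{exposure or self.exposure_ids[0]}"].to_numpy(float)

    def by(self) -> np.ndarray:
        return self.table["BY"].to_numpy(float)

    def sy(self) -> np.ndarray:
        return self.table["SY"].to_numpy(float)

    def subset(self, mask: np.ndarray) -> "HarmonisedSet":
        return replace(self, table=self.table.loc[mask].reset_index(drop=True))


@dataclass
class MRResult:
    """One causal estimate: method, point, fixed-effect SE, 95% CI, p and bookkeeping."""

    method: str
    exposure: str
    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_variants: int
    f_statistic: float = float("nan")
    scale: str = "sd"

    @classmethod
    def from_estimate(cls, method, exposure, outcome, estimate, se, n_variants, *, p=None,
                      f_statistic=float("nan"), scale="sd") -> "MRResult":
        if p is None:
            p = float(np.clip(2 * sps.norm.sf(abs(estimate / se)), np.finfo(float).tiny, 1.0))
        return cls(method, exposure, outcome, float(estimate), float(se),
                   float(estimate - Z95 * se), float(estimate + Z95 * se), p,
                   int(n_variants), float(f_statistic), scale)


@dataclass
class EggerResult:
    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_p: float


def _orient_row(ea_ref, oa_ref, eaf_ref, ea, oa, eaf):
    """Return (+1/-1/None): sign to apply to the row's beta to match the reference
    allele pair, or None when the variant must be dropped, with a reason."""
    if _is_palindromic(ea_ref, oa_ref) or _is_palindromic(ea, oa):
        if abs(eaf_ref - 0.5) <= PALINDROMIC_EAF_ZONE or abs(eaf - 0.5) <= PALINDROMIC_EAF_ZONE:
            return None, "ambiguous"
        return (1 if (eaf_ref < 0.5) == (eaf < 0.5) else -1), None
    if (ea, oa) == (ea_ref, oa_ref):
        return 1, None
    if (ea, oa) == (oa_ref, ea_ref):
        return -1, None
    ea_c, oa_c = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
    if (ea_c, oa_c) == (ea_ref, oa_ref):
        return 1, None
    if (ea_c, oa_c) == (oa_ref, ea_ref):
        return -1, None
    return None, "allele_mismatch"


def harmonise(
    exposures: pd.DataFrame | list,
    outcome: pd.DataFrame,
    *,
    exposure_ids: list | None = None,
    outcome_id: str | None = None,
) -> HarmonisedSet:
    """Align exposure and outcome effects to one effect allele per variant.

    Instruments are the variants present in every table (pass pre-clumped exposure
    tables).  Swapped allele pairs flip the beta sign and EAF; palindromic variants
    are oriented by allele frequency when both frequencies are informative
    (|EAF - 0.5| > 0.08) and dropped as ambiguous otherwise.  Drop reasons are
    recorded on the returned set.
    """
    if isinstance(exposures, pd.DataFrame):
        exposures = [exposures]
    if exposure_ids is None:
        exposure_ids = [
            t.attrs.get("trait_id", f"exposure{i + 1}") for i, t in enumerate(exposures)
        ]
    if outcome_id is None:
        outcome_id = outcome.attrs.get("trait_id", "outcome")
    outcome_scale = "log_or" if outcome.attrs.get("trait_kind") == "binary" else "sd"

    tabs = [t.set_index("SNP") for t in exposures] + [outcome.set_index("SNP")]
    common = tabs[0].index
    for t in tabs[1:]:
        common = common.intersection(t.index)
    drops: dict[str, list] = {}
    rows = []
    for snp in common:
        ref = tabs[0].loc[snp]
        rec = {
            "SNP": snp,
            "EA": ref["EA"],
            "OA": ref["OA"],
            "EAF": float(ref["EAF"]),
            "PROXY": ref.get("PROXY", "."),
        }
        ok = True
        for t, label, is_outcome in (
            [(tabs[i], exposure_ids[i], False) for i in range(len(exposures))]
            + [(tabs[-1], outcome_id, True)]
        ):
            row = t.loc[snp]
            sign, reason = _orient_row(
                ref["EA"], ref["OA"], float(ref["EAF"]), row["EA"], row["OA"], float(row["EAF"])
            )
            if sign is None:
                drops.setdefault(reason, []).append(snp)
                ok = False
                break
            if is_outcome:
                rec["BY"] = sign * float(row["BETA"])
                rec["SY"] = float(row["SE"])
                rec["NY"] = int(row["N"])
                if isinstance(row.get("PROXY"), str) and row.get("PROXY") != ".":
                    rec["PROXY"] = row["PROXY"]
            else:
                rec[f"BX_{label}"] = sign * float(row["BETA"])
                rec[f"SX_{label}"] = float(row["SE"])
                rec[f"NX_{label}"] = int(row["N"])
        if ok:
            rows.append(rec)
    if not rows:
        raise HarmonisationError(
            f"no variants survived harmonisation (drops: { {k: len(v) for k, v in drops.items()} })"
        )
    table = pd.DataFrame(rows).reset_index(drop=True)
    return HarmonisedSet(table, list(exposure_ids), outcome_id, outcome_scale, drops)


@dataclass
class ProxyMatch:
    id: str
    r2: float
    sign: int  # sign of the dosage correlation between index and proxy effect alleles


def find_proxy(
    missing_variant: str,
    outcome_table: pd.DataFrame,
    panel: GenotypeMatrix,
    r2_min: float = 0.8,
    window: int = 250_000,
) -> ProxyMatch | None:
    """Best LD proxy for an instrument absent from the outcome study.

    Candidates are outcome-table variants in the panel on the index's chromosome
    within ``window`` bp; the highest-r^2 candidate is returned if r^2 > r2_min,
    with the dosage-correlation sign used to orient the proxy's effect allele to
    the index's.
    """
    var = panel.variants.set_index("id")
    if missing_variant not in var.index:
        raise ProxyLookupError(f"index variant {missing_variant} absent from reference panel")
    chrom = var.loc[missing_variant, "chrom"]
    pos = int(var.loc[missing_variant, "pos"])
    x_index = panel.dosage_vector(missing_variant)
    if np.ptp(x_index) == 0:
        return None
    best: ProxyMatch | None = None
    for snp in outcome_table["SNP"]:
        if snp == missing_variant or snp not in var.index:
            continue
        if var.loc[snp, "chrom"] != chrom or abs(int(var.loc[snp, "pos"]) - pos) > window:
            continue
        x = panel.dosage_vector(snp)
        if np.ptp(x) == 0:
            continue
        r = float(np.corrcoef(x_index, x)[0, 1])
        if best is None or r * r > best.r2:
            best = ProxyMatch(snp, r * r, int(np.sign(r)) or 1)
    if best is not None and best.r2 > r2_min:
        return best
    return None


def substitute_proxies(
    instruments: pd.DataFrame,
    outcome_table: pd.DataFrame,
    panel: GenotypeMatrix,
    r2_min: float = 0.8,
    window: int = 250_000,
) -> pd.DataFrame:
    """Outcome table augmented with proxy-derived rows for missing instruments.

    Each substituted row carries the index variant's id and panel alleles, with the
    proxy's effect size oriented through the panel's dosage-correlation sign; the
    PROXY column records the source variant.
    """
    present = set(outcome_table["SNP"])
    out = outcome_table.copy()
    if "PROXY" not in out.columns:
        out["PROXY"] = "."
    var = panel.variants.set_index("id")
    extra = []
    for snp in instruments["SNP"]:
        if snp in present or snp not in var.index:
            continue
        match = find_proxy(snp, outcome_table, panel, r2_min=r2_min, window=window)
        if match is None:
            continue
        prow = outcome_table.loc[outcome_table["SNP"] == match.id].iloc[0]
        pvar = var.loc[match.id]
        sign, reason = _orient_row(
            pvar["ea"], pvar["oa"], float(pvar["eaf"]),
            prow["EA"], prow["OA"], float(prow["EAF"]),
        )
        if sign is None:
            continue  # proxy itself unorientable (e.g. palindromic with EAF near 0.5)
        beta_panel_ea = sign * float(prow["BETA"])  # proxy beta on the panel's effect allele
        ivar = var.loc[snp]
        eaf = float(prow["EAF"]) if sign > 0 else 1 - float(prow["EAF"])
        extra.append(
            {
                "SNP": snp,
                "CHR": ivar["chrom"],
                "BP": ivar["pos"],
                "EA": ivar["ea"],
                "OA": ivar["oa"],
                "EAF": eaf if match.sign > 0 else 1 - eaf,
                "BETA": match.sign * beta_panel_ea,
                "SE": float(prow["SE"]),
                "P": float(prow["P"]),
                "N": int(prow["N"]),
                "PROXY": match.id,
            }
        )
    if extra:
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    out.attrs.update(outcome_table.attrs)
    return out


def _fstat(h: HarmonisedSet, exposure: str) -> float:
    bx, sx = h.bx(exposure), h.sx(exposure)
    return float(np.mean((bx / sx) ** 2))


def mr_ivw(h: HarmonisedSet, exposure: str | None = None, *, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate: weighted regression through the origin.

    estimate = sum(w bx by) / sum(w bx^2), w = 1/sy^2; fixed-effect
    se = sqrt(1 / sum(w bx^2)).  A single variant degenerates to the Wald ratio and
    is labelled as such.  ``random_effects`` inflates the SE by the multiplicative
    over-dispersion factor max(1, sqrt(Q/(k-1))) (off by default).
    """
    exposure = exposure or h.exposure_ids[0]
    bx, by, sy = h.bx(exposure), h.by(), h.sy()
    if np.all(bx == 0):
        raise NonIdentifiedError("all exposure betas are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    est = float(np.sum(w * bx * by)) / denom
    se = float(np.sqrt(1.0 / denom))
    k = len(bx)
    method = "Wald" if k == 1 else "IVW"
    if random_effects and k > 1:
        q = float(np.sum(w * (by - est * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return MRResult.from_estimate(
        method, exposure, h.outcome_id, est, se, k,
        f_statistic=_fstat(h, exposure), scale=h.outcome_scale,
    )


def mr_egger(h: HarmonisedSet, exposure: str | None = None) -> EggerResult:
    """MR-Egger regression: weighted regression of by on bx with a free intercept.

    Variants are re-oriented so all exposure betas are non-negative (required for
    the intercept to estimate the average directional pleiotropic effect).  SEs use
    the regression-estimated residual scale with t(k-2) tests.
    """
    import statsmodels.api as sm

    exposure = exposure or h.exposure_ids[0]
    k = h.n_variants
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 variants, got {k}")
    bx, by, sy = h.bx(exposure), h.by(), h.sy()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    icept, slope = float(fit.params[0]), float(fit.params[1])
    se_i, se_s = float(fit.bse[0]), float(fit.bse[1])
    slope_res = MRResult(
        "Egger-slope", exposure, h.outcome_id, slope, se_s,
        slope - Z95 * se_s, slope + Z95 * se_s, float(fit.pvalues[1]), k,
        _fstat(h, exposure), h.outcome_scale,
    )
    return EggerResult(slope_res, icept, se_i, float(fit.pvalues[0]))


def mvmr(h: HarmonisedSet, *, cond_max: float = 1e8) -> list:
    """Multivariable MR: weighted regression of by on all exposures' bx, no intercept.

    Each coefficient is that exposure's direct effect conditional on the others,
    with fixed-effect SEs from the weighted normal equations.  An exposure whose
    beta column is identically zero is dropped from the regression and reported as
    non-identified (NaN); genuinely collinear non-zero columns raise a
    weak-conditional-instrument error.
    """
    if len(h.exposure_ids) < 2:
        raise ValueError("MVMR needs at least two exposures in the harmonised set")
    k = h.n_variants
    if k < 3:
        raise InsufficientInstrumentsError(f"MVMR needs >= 3 variants, got {k}")
    by, sy = h.by(), h.sy()
    cols = {e: h.bx(e) for e in h.exposure_ids}
    active = [e for e, c in cols.items() if np.any(c != 0)]
    if not active:
        raise NonIdentifiedError("all exposure betas are zero for every exposure")
    X = np.column_stack([cols[e] for e in active])
    sw = 1.0 / sy
    Xw = X * sw[:, None]
    if np.linalg.cond(Xw) > cond_max:
        raise WeakConditionalInstrumentError(
            f"exposure beta columns near-collinear (cond={np.linalg.cond(Xw):.3g})"
        )
    yw = by * sw
    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    cov = np.linalg.inv(xtx)
    results = []
    for e in h.exposure_ids:
        if e in active:
            i = active.index(e)
            results.append(
                MRResult.from_estimate(
                    "MVMR", e, h.outcome_id, coef[i], float(np.sqrt(cov[i, i])), k,
                    scale=h.outcome_scale,
                )
            )
        else:
            results.append(
                MRResult("MVMR", e, h.outcome_id, float("nan"), float("nan"),
                         float("nan"), float("nan"), float("nan"), k,
                         float("nan"), h.outcome_scale)
            )
    return results


def steiger_filter(h: HarmonisedSet, exposure: str | None = None):
    """Drop variants whose outcome variance explained exceeds the exposure's.

    Both sides use 2 beta^2 MAF (1 - MAF); a variant is retained iff its exposure
    variance explained is >= its outcome value (for binary outcomes the log-OR
    scale makes this an approximation).  Returns the filtered set and an exclusion
    table carrying both variance values per variant.
    """
    exposure = exposure or h.exposure_ids[0]
    eaf = h.table["EAF"].to_numpy(float)
    maf = np.minimum(eaf, 1 - eaf)
    vx = 2 * h.bx(exposure) ** 2 * maf * (1 - maf)
    vy = 2 * h.by() ** 2 * maf * (1 - maf)
    keep = vx >= vy
    exclusions = pd.DataFrame(
        {
            "SNP": h.table["SNP"],
            "var_explained_exposure": vx,
            "var_explained_outcome": vy,
            "retained": keep,
        }
    )
    if not keep.any():
        import warnings

        warnings.warn("Steiger filtering removed every variant", stacklevel=2)
    return h.subset(keep), exclusions


def fixed_effect_meta(results: list) -> MRResult:
    """Inverse-variance fixed-effect pooling of per-study estimates (log scale for ORs)."""
    if not results:
        raise ValueError("no results to meta-analyse")
    scales = {r.scale for r in results}
    if len(scales) > 1 or "or" in scales:
        raise ScaleMismatchError(f"cannot meta-analyse across scales {sorted(scales)}")
    exposures = {r.exposure for r in results}
    if len(exposures) > 1:
        raise ScaleMismatchError(f"mixed exposures in meta-analysis: {sorted(exposures)}")
    if len(results) == 1:
        return results[0]
    est = np.array([r.estimate for r in results])
    se = np.array([r.se for r in results])
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    return MRResult.from_estimate(
        "meta", results[0].exposure, "+".join(r.outcome for r in results),
        pooled, pooled_se, max(r.n_variants for r in results), scale=results[0].scale,
    )


def to_odds_ratio(result: MRResult) -> MRResult:
    """Exponentiate a log-OR result for reporting; p unchanged, se kept on log scale."""
    if result.scale != "log_or":
        raise ScaleMismatchError(f"result is on scale {result.scale!r}, expected log_or")
    return replace(
        result,
        estimate=float(np.exp(result.estimate)),
        ci_low=float(np.exp(result.ci_low)),
        ci_high=float(np.exp(result.ci_high)),
        scale="or",
    )


def from_odds_ratio(result: MRResult) -> MRResult:
    """Inverse of :func:`to_odds_ratio` (round-trips exactly)."""
    if result.scale != "or":
        raise ScaleMismatchError(f"result is on scale {result.scale!r}, expected or")
    return replace(
        result,
        estimate=float(np.log(result.estimate)),
        ci_low=float(np.log(result.ci_low)),
        ci_high=float(np.log(result.ci_high)),
        scale="log_or",
    )


def results_to_frame(results: list) -> pd.DataFrame:
    """Tidy results table (method, exposure, outcome, estimate, se, CI, p, counts)."""
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "exposure": r.exposure,
                "outcome": r.outcome,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n_variants": r.n_variants,
                "f_statistic": r.f_statistic,
                "scale": r.scale,
            }
            for r in results
        ]
    )
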