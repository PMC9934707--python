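"""Per-variant association testing, QC filtering, LD and greedy clumping.

Summary statistics travel as pandas DataFrames in a fixed tab-delimited dialect with
columns SNP, CHR, BP, EA, OA, EAF, BETA, SE, P, N (optional INFO, CONVERGED); trait
metadata rides in ``DataFrame.attrs`` (``trait_id``, ``trait_kind``).

Quantitative association is covariate-residualised least squares: the phenotype is
rank-inverse-normalised upstream, residualised on sex/age/centre, and regressed on
each variant's dosage separately (a linear mixed model is unnecessary here — the
simulated cohorts contain no relatedness).  Binary traits use per-variant logistic
regression with covariates in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedLDError
from .simulate import GenotypeMatrix

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


def covariate_design(phenotypes: pd.DataFrame) -> np.ndarray:
    """Design matrix (with intercept) for sex, age and one-hot assessment centre."""
    n = len(phenotypes)
    cols = [np.ones(n)]
    if "sex" in phenotypes:
        cols.append(phenotypes["sex"].to_numpy(float))
    if "age" in phenotypes:
        cols.append(phenotypes["age"].to_numpy(float))
    if "centre" in phenotypes:
        centre = phenotypes["centre"].to_numpy()
        for level in np.unique(centre)[1:]:  # first level absorbed by intercept
            cols.append((centre == level).astype(float))
    return np.column_stack(cols)


def _residualise(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    *,
    trait_kind: str = "quantitative",
    trait_id: str = "trait",
    rint: bool = False,
) -> pd.DataFrame:
    """Per-variant association of ``phenotype`` with each dosage column.

    Quantitative: slope of the covariate-residualised phenotype on dosage with a
    two-sided t test (df = n - 2 - #covariates).  Binary: logistic log-OR with Wald
    normal p.  Effect-allele frequency is recomputed from the dosages.  Monomorphic
    variants are emitted with BETA=0, SE=inf, P=1 and CONVERGED=False so downstream
    QC drops them.
    """
    y = np.asarray(phenotype, dtype=float)
    n, m = genotypes.dosages.shape
    if len(y) != n:
        raise ValueError(f"phenotype length {len(y)} != {n} individuals")
    if isinstance(covariates, pd.DataFrame):
        covariates = covariate_design(covariates)
    if rint:
        from .recall import rank_inverse_normalise

        y = rank_inverse_normalise(y)

    G = genotypes.dosages
    eaf = G.mean(axis=0) / 2.0
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    pval = np.ones(m)
    converged = np.ones(m, dtype=bool)

    if trait_kind == "quantitative":
        k_cov = 0 if covariates is None else covariates.shape[1]
        yc = _residualise(y, covariates) if covariates is not None else y - y.mean()
        Gc = G - G.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Gc, Gc)
        poly = sxx > 0
        sxy = yc @ Gc
        syy = float(yc @ yc)
        df = max(n - 2 - max(k_cov - 1, 0), 1)
        b = np.where(poly, sxy / np.where(poly, sxx, 1.0), 0.0)
        rss = np.maximum(syy - b * sxy, 0.0)
        s = np.sqrt(rss / df / np.where(poly, sxx, np.inf))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, b / s, np.inf * np.sign(b))
        p = 2 * sps.t.sf(np.abs(t), df)
        p = np.where(np.isfinite(t), p, 0.0)
        beta[poly] = b[poly]
        se[poly] = s[poly]
        pval[poly] = np.clip(p[poly], np.finfo(float).tiny, 1.0)
        converged[~poly] = False
    elif trait_kind == "binary":
        import statsmodels.api as sm

        ybin = y.astype(int)
        base = covariates if covariates is not None else np.ones((n, 1))
        for j in range(m):
            x = G[:, j]
            if np.ptp(x) == 0:
                converged[j] = False
                continue
            X = np.column_stack([x, base])
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(ybin, X).fit(disp=0, maxiter=100)
                ok = bool(fit.mle_retvals.get("converged", False))
                bse = float(fit.bse[0])
                if not ok or not np.isfinite(bse) or bse > 50:
                    raise ValueError("separation / non-convergence")
                beta[j] = float(fit.params[0])
                se[j] = bse
                z = beta[j] / se[j]
                pval[j] = float(np.clip(2 * sps.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
            except Exception:
                converged[j] = False
                beta[j], se[j], pval[j] = 0.0, np.inf, 1.0
    else:
        raise ValueError(f"trait_kind must be quantitative|binary, got {trait_kind!r}")

    out = pd.DataFrame(
        {
            "SNP": genotypes.variants["id"].to_numpy(),
            "CHR": genotypes.variants["chrom"].to_numpy(),
            "BP": genotypes.variants["pos"].to_numpy(),
            "EA": genotypes.variants["ea"].to_numpy(),
            "OA": genotypes.variants["oa"].to_numpy(),
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": pval,
            "N": n,
            "CONVERGED": converged,
        }
    )
    if "info" in genotypes.variants.columns:
        out["INFO"] = genotypes.variants["info"].to_numpy()
    out.attrs["trait_id"] = trait_id
    out.attrs["trait_kind"] = trait_kind
    return out


def qc_filter(
    stats: pd.DataFrame,
    maf_min: float = 0.01,
    info_min: float = 0.8,
    return_counts: bool = False,
):
    """Retain variants with maf_min < EAF < 1 - maf_min and (INFO absent or > info_min).

    Non-converged rows (monomorphic / separated fits) are dropped as well.  Idempotent.
    """
    eaf = stats["EAF"].to_numpy(float)
    keep_maf = (eaf > maf_min) & (eaf < 1 - maf_min)
    if "INFO" in stats.columns:
        info = stats["INFO"].to_numpy(float)
        keep_info = np.isnan(info) | (info > info_min)
    else:
        keep_info = np.ones(len(stats), dtype=bool)
    keep_conv = (
        stats["CONVERGED"].to_numpy(bool) if "CONVERGED" in stats.columns else np.ones(len(stats), bool)
    )
    keep = keep_maf & keep_info & keep_conv
    counts = {
        "removed_maf": int((~keep_maf).sum()),
        "removed_info": int((keep_maf & ~keep_info).sum()),
        "removed_nonconverged": int((keep_maf & keep_info & ~keep_conv).sum()),
        "retained": int(keep.sum()),
    }
    out = stats.loc[keep].reset_index(drop=True)
    out.attrs.update(stats.attrs)
    if return_counts:
        return out, counts
    return out


def ld_r2(panel: GenotypeMatrix, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of the two dosage vectors in the reference panel."""
    xa = panel.dosage_vector(variant_a)
    xb = panel.dosage_vector(variant_b)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise UndefinedLDError(
            f"LD undefined: monomorphic variant among ({variant_a}, {variant_b})"
        )
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


@dataclass
class ClumpIndex:
    id: str
    chrom: int
    pos: int
    p: float
    members: list = field(default_factory=list)


@dataclass
class ClumpResult:
    """Greedy clumping output: index variants (ascending p) with their absorbed members."""

    indices: list

    @property
    def index_ids(self) -> list:
        return [ix.id for ix in self.indices]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": [ix.id for ix in self.indices],
                "CHR": [ix.chrom for ix in self.indices],
                "BP": [ix.pos for ix in self.indices],
                "P": [ix.p for ix in self.indices],
                "N_MEMBERS": [len(ix.members) for ix in self.indices],
                "MEMBERS": [",".join(ix.members) if ix.members else "." for ix in self.indices],
            }
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def ld_clump(
    stats: pd.DataFrame,
    panel: GenotypeMatrix,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window: int = 250_000,
    eval_radius: int = 1_000_000,
) -> ClumpResult:
    """Greedy selection of independent association signals.

    Repeatedly take the smallest-p unassigned variant with p <= p_thresh as an index
    (ties broken by chromosome, position, id) and assign to it every unassigned
    variant that is on the same chromosome and either strictly within ``window`` bp
    or has r^2 > r2_thresh with the index (r^2 evaluated within ``eval_radius`` bp
    and treated as 0 beyond).  Retained indices therefore satisfy pairwise
    independence by both distance and correlation.
    """
    ids = stats["SNP"].to_numpy()
    missing = [v for v in ids if not (panel.variants["id"] == v).any()]
    if missing:
        raise ValueError(f"{len(missing)} summary-stat variants absent from LD panel, e.g. {missing[:3]}")

    order = stats.loc[:, ["SNP", "CHR", "BP", "P"]].copy()
    order = order.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)
    pos = dict(zip(order["SNP"], order["BP"].astype(int)))
    chrom = dict(zip(order["SNP"], order["CHR"].astype(int)))
    pvals = dict(zip(order["SNP"], order["P"].astype(float)))

    # centred dosages for fast pairwise correlation
    col = {v: panel.dosage_vector(v) for v in ids}
    centred = {v: c - c.mean() for v, c in col.items()}
    norm = {v: float(np.sqrt(c @ c)) for v, c in centred.items()}

    def r2(a: str, b: str) -> float:
        if chrom[a] != chrom[b] or abs(pos[a] - pos[b]) > eval_radius:
            return 0.0
        if norm[a] == 0 or norm[b] == 0:
            return 0.0  # monomorphic in panel: no usable LD information
        r = float(centred[a] @ centred[b]) / (norm[a] * norm[b])
        return r * r

    unassigned = set(ids)
    indices: list[ClumpIndex] = []
    for snp in order["SNP"]:
        if snp not in unassigned or pvals[snp] > p_thresh:
            continue
        unassigned.discard(snp)
        members = []
        for other in list(unassigned):
            same_chrom = chrom[other] == chrom[snp]
            near = same_chrom and abs(pos[other] - pos[snp]) < window
            if near or r2(snp, other) > r2_thresh:
                unassigned.discard(other)
                members.append(other)
        members.sort(key=lambda v: (chrom[v], pos[v], v))
        indices.append(ClumpIndex(snp, chrom[snp], pos[snp], pvals[snp], members))
    return ClumpResult(indices)


def write_sumstats(stats: pd.DataFrame, path: str) -> None:
    cols = [c for c in SUMSTAT_COLUMNS + ["INFO", "CONVERGED"] if c in stats.columns]
    stats.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path: str, trait_id: str = "trait", trait_kind: str = "quantitative") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-stat file {path} lacks columns {sorted(missing)}")
    df.attrs["trait_id"] = trait_id
    df.attrs["trait_kind"] = trait_kind
    return df


def validate_sumstats(stats: pd.DataFrame, n_covariates: int = 0, tol: float = 1e-6) -> None:
    """Check the table-level invariants: positive SE, p consistent with beta/se, unique ids."""
    ok = stats["SE"].to_numpy(float) > 0
    if not ok.all():
        raise ValueError("non-positive SE present")
    if stats["SNP"].duplicated().any():
        raise ValueError("duplicate variant ids")
    kind = stats.attrs.get("trait_kind", "quantitative")
    z = stats["BETA"].to_numpy(float) / stats["SE"].to_numpy(float)
    finite = np.isfinite(z)
    if kind == "quantitative":
        df = stats["N"].to_numpy(float) - 2 - max(n_covariates - 1, 0)
        expect = 2 * sps.t.sf(np.abs(z[finite]), df[finite])
    else:
        expect = 2 * sps.norm.sf(np.abs(z[finite]))
    got = stats["P"].to_numpy(float)[finite]
    if np.max(np.abs(np.clip(expect, np.finfo(float).tiny, 1.0) - got), initial=0.0) > tol:
        raise ValueError("P inconsistent with BETA/SE under the stated test")
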