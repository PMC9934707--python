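"""End-to-end orchestration: simulate -> reconstruct -> GWAS -> clump -> validate
scores -> MR/MVMR -> sensitivity -> meta-analysis -> report.

Every stage reads its inputs from, and persists its outputs to, a result directory,
so individual stages can be re-run reproducibly; a JSON manifest records the resolved
configuration, thresholds, per-stage timings and output checksums.  All randomness
flows from the single config seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import mr as mrmod
from . import recall as recall_mod
from . import scores as scores_mod
from . import simulate as sim
from . import vcfio
from .config import STREAM_RECALL, ConfigurationError, SimulationConfig, substream
from .errors import LifemrError

import yaml

STAGES = ("simulate", "reconstruct", "gwas", "clump", "grs", "mr", "report")


@dataclass
class PipelineConfig:
    """Simulation config plus the analysis thresholds of the downstream stages."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # association / clumping
    p_thresh: float = 5e-8
    r2_thresh: float = 0.001
    clump_window: int = 250_000
    maf_min: float = 0.01
    info_min: float = 0.8
    # proxies
    proxy_r2: float = 0.8
    proxy_window: int = 250_000
    # reference distribution anchoring the recall categories
    ref_mean: float = 17.8
    ref_sd: float = 1.97
    ref_family: str = "normal"
    # sensitivity / reporting
    egger_flag_p: float = 0.01
    n_outcome_studies: int = 1

    _SIM_KEYS = frozenset(f.name for f in dataclasses.fields(SimulationConfig))

    def validate(self) -> None:
        self.simulation.validate()
        self.simulation.require_seed()
        if not 0 < self.p_thresh <= 1:
            raise ConfigurationError(f"p_thresh out of (0, 1]: {self.p_thresh}")
        for name in ("r2_thresh", "proxy_r2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} out of [0, 1]: {v}")
        for name in ("clump_window", "proxy_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.maf_min < 0.5:
            raise ConfigurationError(f"maf_min out of [0, 0.5): {self.maf_min}")
        if not 0 <= self.info_min <= 1:
            raise ConfigurationError(f"info_min out of [0, 1]: {self.info_min}")
        if self.ref_sd <= 0:
            raise ConfigurationError("ref_sd must be > 0")
        if self.ref_family not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown ref_family {self.ref_family!r}")
        if not 0 < self.egger_flag_p <= 1:
            raise ConfigurationError("egger_flag_p out of (0, 1]")
        if self.n_outcome_studies < 1:
            raise ConfigurationError("n_outcome_studies must be >= 1")

    @property
    def seed(self) -> int:
        return self.simulation.require_seed()

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "simulation"}
        d.update(self.simulation.to_dict())
        return d

    @classmethod
    def from_dict(cls, d: dict, strict: bool = True) -> "PipelineConfig":
        own = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        sim_part = {k: v for k, v in d.items() if k in cls._SIM_KEYS}
        pipe_part = {k: v for k, v in d.items() if k in own}
        unknown = set(d) - cls._SIM_KEYS - own
        if unknown:
            if strict:
                raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
            import warnings

            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
        cfg = cls(simulation=SimulationConfig.from_dict(sim_part), **pipe_part)
        cfg.validate()
        return cfg


def validate_config(path: str | Path, strict: bool = True) -> PipelineConfig:
    """Parse, apply defaults, range-check, and return the fully resolved config."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ConfigurationError("config file must contain a mapping")
    if "seed" not in d or d["seed"] is None:
        raise ConfigurationError("seed required")
    return PipelineConfig.from_dict(d, strict=strict)


# ---------------------------------------------------------------------- manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path, cfg: PipelineConfig):
        self.path = Path(outdir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config": cfg.to_dict(), "seed": cfg.seed, "stages": {}}
        self.data["config"] = cfg.to_dict()
        self.data["seed"] = cfg.seed

    def record(self, stage: str, seconds: float, outputs: list[Path], extra: dict | None = None):
        self.data["stages"][stage] = {
            "seconds": round(seconds, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
            **(extra or {}),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    exposure, outcome = sim.make_two_sample_studies(cfg.simulation)
    paths = []
    for name, study in (("exposure", exposure), ("outcome", outcome)):
        ppath = outdir / f"{name}_phenotypes.tsv"
        gpath = outdir / f"{name}_genotypes.vcf"
        sim.write_phenotypes(study.phenotypes, ppath)
        vcfio.write_vcf(study.genotypes, gpath)
        paths += [ppath, gpath]
    return paths


def stage_reconstruct(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    pheno = sim.read_phenotypes(outdir / "exposure_phenotypes.tsv")
    refdist = recall_mod.fit_reference_distribution(
        cfg.ref_mean, cfg.ref_sd, cfg.ref_family, cfg.simulation.recall_proportions
    )
    rng = substream(cfg.seed, STREAM_RECALL)
    pheno["child_bmi_recon"] = recall_mod.assign_continuous_bmi(pheno["recall"], refdist, rng)
    pheno["child_bmi_rint"] = recall_mod.rank_inverse_normalise(pheno["child_bmi_recon"])
    pheno["adult_bmi_rint"] = recall_mod.rank_inverse_normalise(pheno["adult_bmi"])
    path = outdir / "exposure_phenotypes_reconstructed.tsv"
    pheno.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return [path]


def _split_outcome_studies(pheno: pd.DataFrame, n_studies: int) -> list[np.ndarray]:
    return np.array_split(np.arange(len(pheno)), n_studies)


def stage_gwas(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    geno_exp = vcfio.read_vcf(str(outdir / "exposure_genotypes.vcf"))
    pheno_exp = pd.read_csv(outdir / "exposure_phenotypes_reconstructed.tsv", sep="\t")
    paths = []
    for trait, column in (("child_bmi", "child_bmi_rint"), ("adult_bmi", "adult_bmi_rint")):
        stats = assoc.run_gwas(
            geno_exp, pheno_exp[column], pheno_exp, trait_kind="quantitative", trait_id=trait
        )
        stats = assoc.qc_filter(stats, cfg.maf_min, cfg.info_min)
        p = outdir / f"gwas_{trait}.tsv"
        assoc.write_sumstats(stats, p)
        paths.append(p)

    geno_out = vcfio.read_vcf(str(outdir / "outcome_genotypes.vcf"))
    pheno_out = sim.read_phenotypes(outdir / "outcome_phenotypes.tsv")
    kind = cfg.simulation.outcome_kind
    for s, idx in enumerate(_split_outcome_studies(pheno_out, cfg.n_outcome_studies), start=1):
        sub = sim.GenotypeMatrix(
            geno_out.iids[idx], geno_out.variants, geno_out.dosages[idx]
        )
        stats = assoc.run_gwas(
            sub,
            pheno_out["outcome"].to_numpy()[idx],
            pheno_out.iloc[idx],
            trait_kind="binary" if kind == "binary" else "quantitative",
            trait_id=f"outcome_study{s}",
        )
        stats = assoc.qc_filter(stats, cfg.maf_min, cfg.info_min)
        p = outdir / f"gwas_outcome_study{s}.tsv"
        assoc.write_sumstats(stats, p)
        paths.append(p)
    return paths


def stage_clump(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    panel = vcfio.read_vcf(str(outdir / "exposure_genotypes.vcf"))
    paths = []
    for trait in ("child_bmi", "adult_bmi"):
        stats = assoc.read_sumstats(outdir / f"gwas_{trait}.tsv", trait_id=trait)
        clump = assoc.ld_clump(
            stats, panel, p_thresh=cfg.p_thresh, r2_thresh=cfg.r2_thresh, window=cfg.clump_window
        )
        p = outdir / f"instruments_{trait}.tsv"
        clump.write_tsv(p)
        paths.append(p)
    return paths


def _instrument_stats(outdir: Path, trait: str) -> pd.DataFrame:
    stats = assoc.read_sumstats(outdir / f"gwas_{trait}.tsv", trait_id=trait)
    idx = pd.read_csv(outdir / f"instruments_{trait}.tsv", sep="\t")
    out = stats[stats["SNP"].isin(set(idx["SNP"]))].reset_index(drop=True)
    out.attrs.update(stats.attrs)
    return out


def stage_grs(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    # the outcome cohort doubles as the independent validation cohort
    geno = vcfio.read_vcf(str(outdir / "outcome_genotypes.vcf"))
    pheno = sim.read_phenotypes(outdir / "outcome_phenotypes.tsv")
    reports = {}
    scores_cols = {"iid": pheno["iid"]}
    for trait, target_col in (("child_bmi", "child_bmi_true"), ("adult_bmi", "adult_bmi")):
        weights = _instrument_stats(outdir, trait)
        scores_cols[f"grs_{trait}"] = scores_mod.build_grs(geno, weights)
        for target_name, target in (("child_bmi_true", pheno["child_bmi_true"]),
                                    ("adult_bmi", pheno["adult_bmi"])):
            rep = scores_mod.validate_grs(geno, weights, target, target_name)
            reports[f"grs_{trait}__vs__{target_name}"] = rep.to_dict()
    spath = outdir / "grs_scores.tsv"
    pd.DataFrame(scores_cols).to_csv(spath, sep="\t", index=False, float_format="%.10g")
    jpath = outdir / "grs_report.json"
    jpath.write_text(json.dumps(reports, indent=2, sort_keys=True) + "\n")
    return [spath, jpath]


def _cross_clumped_union(cfg: PipelineConfig, outdir: Path, panel) -> list[str]:
    """Union of both exposures' instruments, re-clumped jointly on the smaller p."""
    frames = []
    for trait in ("child_bmi", "adult_bmi"):
        frames.append(_instrument_stats(outdir, trait))
    both = pd.concat(frames, ignore_index=True)
    both = both.sort_values(["SNP", "P"]).drop_duplicates("SNP", keep="first").reset_index(drop=True)
    clump = assoc.ld_clump(
        both, panel, p_thresh=1.0, r2_thresh=cfg.r2_thresh, window=cfg.clump_window
    )
    return clump.index_ids


def stage_mr(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    panel = vcfio.read_vcf(str(outdir / "exposure_genotypes.vcf"))
    child = assoc.read_sumstats(outdir / "gwas_child_bmi.tsv", trait_id="child_bmi")
    adult = assoc.read_sumstats(outdir / "gwas_adult_bmi.tsv", trait_id="adult_bmi")
    inst = {"child_bmi": _instrument_stats(outdir, "child_bmi"),
            "adult_bmi": _instrument_stats(outdir, "adult_bmi")}
    union_ids = _cross_clumped_union(cfg, outdir, panel)
    kind = "binary" if cfg.simulation.outcome_kind == "binary" else "quantitative"

    results: list[mrmod.MRResult] = []
    egger_rows = []
    steiger_frames = []
    per_study: dict[str, list[mrmod.MRResult]] = {}

    for s in range(1, cfg.n_outcome_studies + 1):
        outcome = assoc.read_sumstats(
            outdir / f"gwas_outcome_study{s}.tsv", trait_id=f"outcome_study{s}", trait_kind=kind
        )
        for trait in ("child_bmi", "adult_bmi"):
            exp_stats = inst[trait]
            out_prox = mrmod.substitute_proxies(
                exp_stats, outcome, panel, r2_min=cfg.proxy_r2, window=cfg.proxy_window
            )
            h = mrmod.harmonise(exp_stats, out_prox)
            ivw = mrmod.mr_ivw(h)
            results.append(ivw)
            per_study.setdefault(f"IVW:{trait}", []).append(ivw)
            try:
                egger = mrmod.mr_egger(h)
                results.append(egger.slope)
                egger_rows.append(
                    {
                        "exposure": trait,
                        "outcome": h.outcome_id,
                        "intercept": egger.intercept,
                        "intercept_se": egger.intercept_se,
                        "intercept_p": egger.intercept_p,
                        "flagged": egger.intercept_p < cfg.egger_flag_p,
                    }
                )
            except LifemrError:
                pass
            h_st, excl = mrmod.steiger_filter(h)
            excl.insert(0, "exposure", trait)
            excl.insert(1, "outcome", h.outcome_id)
            steiger_frames.append(excl)
            if h_st.n_variants >= 1:
                st = mrmod.mr_ivw(h_st)
                st = dataclasses.replace(st, method=f"{st.method}-Steiger")
                results.append(st)
                per_study.setdefault(f"IVW-Steiger:{trait}", []).append(st)

        # MVMR on the cross-clumped union of instruments
        child_u = child[child["SNP"].isin(union_ids)].reset_index(drop=True)
        child_u.attrs.update(child.attrs)
        adult_u = adult[adult["SNP"].isin(union_ids)].reset_index(drop=True)
        adult_u.attrs.update(adult.attrs)
        out_prox = mrmod.substitute_proxies(
            child_u, outcome, panel, r2_min=cfg.proxy_r2, window=cfg.proxy_window
        )
        h2 = mrmod.harmonise([child_u, adult_u], out_prox)
        for res in mrmod.mvmr(h2):
            results.append(res)
            per_study.setdefault(f"MVMR:{res.exposure}", []).append(res)

    if cfg.n_outcome_studies > 1:
        for key, rs in per_study.items():
            if len(rs) > 1:
                base = key.split(":")[0]
                pooled = mrmod.fixed_effect_meta(rs)
                results.append(dataclasses.replace(pooled, method=f"meta-{base}"))

    # reporting scale: exponentiate log-OR results alongside the originals
    if kind == "binary":
        results += [mrmod.to_odds_ratio(r) for r in list(results) if r.scale == "log_or"]

    rpath = outdir / "mr_results.tsv"
    mrmod.results_to_frame(results).to_csv(rpath, sep="\t", index=False, float_format="%.10g")
    epath = outdir / "egger_intercepts.tsv"
    pd.DataFrame(egger_rows).to_csv(epath, sep="\t", index=False, float_format="%.10g")
    spath = outdir / "steiger_exclusions.tsv"
    pd.concat(steiger_frames, ignore_index=True).to_csv(
        spath, sep="\t", index=False, float_format="%.10g"
    )
    return [rpath, epath, spath]


def stage_report(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    res = pd.read_csv(outdir / "mr_results.tsv", sep="\t")
    res = res[res["scale"] != "log_or"] if (res["scale"] == "or").any() else res
    rows = []
    for (exposure, outcome), grp in res.groupby(["exposure", "outcome"], sort=True):
        row = {"exposure": exposure, "outcome": outcome}
        for _, r in grp.iterrows():
            row[r["method"]] = f'{r["estimate"]:.4g} [{r["ci_low"]:.4g}, {r["ci_high"]:.4g}]'
            row[f'{r["method"]}_p'] = f'{r["p"]:.3g}'
        rows.append(row)
    path = outdir / "report.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return [path]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "reconstruct": stage_reconstruct,
    "gwas": stage_gwas,
    "clump": stage_clump,
    "grs": stage_grs,
    "mr": stage_mr,
    "report": stage_report,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, cfg)
    t0 = time.perf_counter()
    try:
        outputs = _STAGE_FUNCS[stage](cfg, outdir)
    except Exception as err:
        raise LifemrError(
            f"stage {stage!r} failed ({err}); completed stages: "
            f"{sorted(manifest.data['stages'])}"
        ) from err
    extra = {
        "thresholds": {
            "p_thresh": cfg.p_thresh,
            "r2_thresh": cfg.r2_thresh,
            "clump_window": cfg.clump_window,
            "proxy_r2": cfg.proxy_r2,
            "proxy_window": cfg.proxy_window,
            "maf_min": cfg.maf_min,
            "info_min": cfg.info_min,
            "egger_flag_p": cfg.egger_flag_p,
        }
    }
    manifest.record(stage, time.perf_counter() - t0, outputs, extra)
    return outputs


def run_pipeline(config: str | Path | PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage in order; returns the result directory."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    cfg.validate()
    for stage in STAGES:
        run_stage(stage, cfg, outdir)
    return Path(outdir)
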