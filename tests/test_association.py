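"""Association stage: GWAS calibration and closed-form agreement, QC filtering,
LD computation and greedy clumping against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lifemr import SimulationConfig, ld_clump, ld_r2, qc_filter, run_gwas, simulate_genotypes, simulate_ld_panel
from lifemr.association import ClumpResult, read_sumstats, validate_sumstats, write_sumstats
from lifemr.errors import UndefinedLDError
from lifemr.simulate import GenotypeMatrix


def _geno(n_variants=10, n=500, seed=2, maf=(0.1, 0.5)):
    c = SimulationConfig(
        seed=seed, n_variants_child_specific=n_variants, n_variants_adult_specific=0,
        n_variants_shared=0, maf_range=maf, n_exposure_cohort=n, n_outcome_cohort=n,
        effect_sd_child=0.0,
    )
    return simulate_genotypes(c, n)


class TestRunGwas:
    def test_noiseless_phenotype_recovers_planted_beta(self):
        g = _geno(n_variants=3)
        y = 0.3 * g.dosages[:, 1]
        stats_df = run_gwas(g, y)
        assert stats_df["BETA"].iloc[1] == pytest.approx(0.3, abs=1e-10)
        assert stats_df["P"].iloc[1] < 1e-100

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(8)
        g = _geno(n_variants=1, n=200)
        y = rng.normal(size=200)
        res = run_gwas(g, y)
        x = g.dosages[:, 0]
        xc, yc = x - x.mean(), y - y.mean()
        beta_hat = (xc @ yc) / (xc @ xc)
        assert res["BETA"].iloc[0] == pytest.approx(beta_hat, abs=1e-10)
        # and against statsmodels OLS with intercept
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res["BETA"].iloc[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert res["SE"].iloc[0] == pytest.approx(fit.bse[1], rel=1e-8)
        assert res["P"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_covariate_residualisation_matches_joint_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 400
        g = _geno(n_variants=1, n=n)
        cov = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 0.2 * g.dosages[:, 0] + 0.5 * cov[:, 1] + rng.normal(size=n)
        res = run_gwas(g, y, covariates=cov)
        fit = sm.OLS(y, np.column_stack([g.dosages[:, 0], cov])).fit()
        # covariates here are independent of dosage, so the two estimates agree closely
        assert res["BETA"].iloc[0] == pytest.approx(fit.params[0], abs=5e-3)

    def test_type_one_error_rate_under_null(self):
        g = _geno(n_variants=1000, n=600, seed=4)
        y = np.random.default_rng(5).normal(size=600)
        res = run_gwas(g, y)
        frac = (res["P"] < 0.05).mean()
        assert 0.035 < frac < 0.065

    def test_null_pvalues_uniform_ks(self):
        g = _geno(n_variants=1000, n=600, seed=6)
        y = np.random.default_rng(7).normal(size=600)
        res = run_gwas(g, y)
        assert stats.kstest(res["P"], "uniform").pvalue > 0.01

    def test_monomorphic_variant_flagged(self):
        g = _geno(n_variants=2, n=50)
        g.dosages[:, 0] = 2.0
        res = run_gwas(g, np.random.default_rng(0).normal(size=50))
        assert not res["CONVERGED"].iloc[0]
        assert res["SE"].iloc[0] == np.inf and res["BETA"].iloc[0] == 0.0

    def test_binary_gwas_recovers_logistic_slope(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        g = _geno(n_variants=2, n=3000)
        lp = -1.5 + 0.4 * g.dosages[:, 0]
        y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        res = run_gwas(g, y, trait_kind="binary")
        fit = sm.Logit(y, sm.add_constant(g.dosages[:, 0])).fit(disp=0)
        assert res["BETA"].iloc[0] == pytest.approx(fit.params[1], abs=1e-6)
        assert res["SE"].iloc[0] == pytest.approx(fit.bse[1], rel=1e-6)

    def test_written_table_validates_and_round_trips(self, tmp_path):
        g = _geno(n_variants=20, n=300)
        res = run_gwas(g, np.random.default_rng(1).normal(size=300))
        validate_sumstats(res)
        path = tmp_path / "stats.tsv"
        write_sumstats(res, path)
        back = read_sumstats(path)
        np.testing.assert_allclose(back["BETA"], res["BETA"], rtol=1e-9)


class TestQcFilter:
    @staticmethod
    def frame(eafs, infos=None):
        df = pd.DataFrame(
            {
                "SNP": [f"v{i}" for i in range(len(eafs))],
                "CHR": 1, "BP": np.arange(len(eafs)) + 1,
                "EA": "A", "OA": "G",
                "EAF": eafs, "BETA": 0.1, "SE": 0.05,
                "P": 0.04, "N": 1000,
            }
        )
        if infos is not None:
            df["INFO"] = infos
        return df

    def test_maf_and_info_rules(self):
        df = self.frame([0.005, 0.5, 0.996, 0.3, 0.4], [0.9, 0.9, 0.9, 0.79, 0.81])
        out, counts = qc_filter(df, return_counts=True)
        assert list(out["SNP"]) == ["v1", "v4"]
        assert counts == {"removed_maf": 2, "removed_info": 1, "removed_nonconverged": 0, "retained": 2}

    def test_empty_table(self):
        out, counts = qc_filter(self.frame([]), return_counts=True)
        assert len(out) == 0 and counts["retained"] == 0

    def test_idempotent(self):
        df = self.frame([0.005, 0.5, 0.3], [0.9, 0.7, 0.95])
        once = qc_filter(df)
        twice = qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)


class TestLdR2:
    def test_self_and_duplicate_correlation(self):
        panel = simulate_ld_panel(200, 2, 3, seed=3)
        assert ld_r2(panel, "rs1", "rs1") == pytest.approx(1.0)
        dup = GenotypeMatrix(panel.iids, panel.variants, panel.dosages.copy())
        dup.dosages[:, 1] = dup.dosages[:, 0]
        assert ld_r2(dup, "rs1", "rs2") == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        g = _geno(n_variants=2, n=5000, seed=10)
        assert ld_r2(g, "rs1", "rs2") < 0.01

    def test_monomorphic_raises(self):
        g = _geno(n_variants=2, n=50)
        g.dosages[:, 0] = 0.0
        with pytest.raises(UndefinedLDError):
            ld_r2(g, "rs1", "rs2")


def brute_force_clump(stats_df, panel, p_thresh, r2_thresh, window, eval_radius=1_000_000):
    """Independent reference clumping: explicit pairwise r2 matrix, greedy by sorted p."""
    df = stats_df.sort_values(["P", "CHR", "BP", "SNP"]).reset_index(drop=True)
    ids = list(df["SNP"])
    pos = df.set_index("SNP")["BP"].to_dict()
    chrom = df.set_index("SNP")["CHR"].to_dict()
    r2 = {}
    for a in ids:
        for b in ids:
            if a < b and chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= eval_radius:
                try:
                    r2[(a, b)] = ld_r2(panel, a, b)
                except UndefinedLDError:
                    r2[(a, b)] = 0.0

    def pair_r2(a, b):
        return r2.get((a, b) if a < b else (b, a), 0.0)

    assigned = set()
    out = []
    for _, row in df.iterrows():
        v = row["SNP"]
        if v in assigned or row["P"] > p_thresh:
            continue
        assigned.add(v)
        members = []
        for u in ids:
            if u in assigned:
                continue
            near = chrom[u] == chrom[v] and abs(pos[u] - pos[v]) < window
            if near or pair_r2(u, v) > r2_thresh:
                assigned.add(u)
                members.append(u)
        out.append((v, members))
    return out


class TestLdClump:
    def test_r2_rule_dominates_distance(self):
        panel = simulate_ld_panel(500, 1, 2, seed=5, copy_prob=1.0, spacing=300_000)
        df = pd.DataFrame(
            {
                "SNP": ["rs1", "rs2"], "CHR": 1, "BP": [1, 300_001],
                "EA": "A", "OA": "G", "EAF": 0.3,
                "BETA": [0.1, 0.1], "SE": [0.015, 0.016],
                "P": [1e-10, 1e-9], "N": 500,
            }
        )
        res = ld_clump(df, panel, window=250_000)
        assert res.index_ids == ["rs1"]
        assert res.indices[0].members == ["rs2"]

    def test_distance_rule_alone(self):
        g = _geno(n_variants=2, n=2000, seed=12)
        g.variants.loc[:, "pos"] = [1, 100_001]
        df = pd.DataFrame(
            {
                "SNP": ["rs1", "rs2"], "CHR": 1, "BP": [1, 100_001],
                "EA": "A", "OA": "G", "EAF": 0.3,
                "BETA": 0.1, "SE": 0.01, "P": [1e-9, 1e-8], "N": 2000,
            }
        )
        res = ld_clump(df, g, window=250_000)
        assert res.index_ids == ["rs1"]

    def test_no_significant_variants_empty_result(self):
        g = _geno(n_variants=3, n=500)
        df = pd.DataFrame(
            {
                "SNP": ["rs1", "rs2", "rs3"], "CHR": 1, "BP": [1, 2_000_000, 4_000_000],
                "EA": "A", "OA": "G", "EAF": 0.3,
                "BETA": 0.01, "SE": 0.05, "P": [0.2, 0.5, 0.9], "N": 500,
            }
        )
        assert ld_clump(df, g).index_ids == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        panel = simulate_ld_panel(400, 10, 5, seed=seed, copy_prob=0.85, spacing=60_000)
        k = panel.n_variants
        df = pd.DataFrame(
            {
                "SNP": panel.variants["id"], "CHR": panel.variants["chrom"],
                "BP": panel.variants["pos"], "EA": panel.variants["ea"],
                "OA": panel.variants["oa"], "EAF": panel.variants["eaf"],
                "BETA": rng.normal(0, 0.05, k), "SE": 0.02,
                "P": 10.0 ** rng.uniform(-12, 0, k), "N": 400,
            }
        )
        mine = ld_clump(df, panel, p_thresh=1e-4, r2_thresh=0.001, window=250_000)
        oracle = brute_force_clump(df, panel, 1e-4, 0.001, 250_000)
        assert mine.index_ids == [v for v, _ in oracle]
        assert [ix.members for ix in mine.indices] == [sorted(m, key=lambda v: (
            int(panel.variants.set_index("id").loc[v, "chrom"]),
            int(panel.variants.set_index("id").loc[v, "pos"]), v)) for _, m in oracle]
        # pairwise independence invariant (r2 under the rule's 1 Mb evaluation radius)
        va = panel.variants.set_index("id")
        for i, a in enumerate(mine.index_ids):
            for b in mine.index_ids[i + 1 :]:
                if va.loc[a, "chrom"] != va.loc[b, "chrom"]:
                    continue
                dist = abs(int(va.loc[a, "pos"]) - int(va.loc[b, "pos"]))
                assert dist >= 250_000
                if dist <= 1_000_000:
                    assert ld_r2(panel, a, b) <= 0.001
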