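"""MR engine: harmonisation and proxies, IVW / Egger / MVMR against independent
weighted-least-squares oracles, Steiger filtering, meta-analysis and OR reporting."""

import numpy as np
import pandas as pd
import pytest

from lifemr import (
    find_proxy,
    fixed_effect_meta,
    harmonise,
    mr_egger,
    mr_ivw,
    mvmr,
    simulate_ld_panel,
    steiger_filter,
    substitute_proxies,
    to_odds_ratio,
)
from lifemr.errors import (
    HarmonisationError,
    InsufficientInstrumentsError,
    NonIdentifiedError,
    ProxyLookupError,
    ScaleMismatchError,
    WeakConditionalInstrumentError,
)
from lifemr.mr import MRResult, from_odds_ratio
from tests.conftest import make_sumstats


def random_harmonised(rng, k, *, n_exposures=1, slope=0.3, intercept=0.0):
    """Consistent exposure/outcome tables around a known causal slope."""
    snps = [f"rs{i}" for i in range(k)]
    bx = rng.normal(0.05, 0.1, size=(k, n_exposures))
    sy = rng.uniform(0.01, 0.05, size=k)
    by = bx @ np.full(n_exposures, slope) + intercept + rng.normal(0, sy)
    exps = [
        make_sumstats(snps, bx[:, e], rng.uniform(0.01, 0.03, k), trait_id=f"x{e}")
        for e in range(n_exposures)
    ]
    out = make_sumstats(snps, by, sy, trait_id="y")
    return harmonise(exps, out), exps, out


class TestHarmonise:
    def test_allele_swap_reorients_beta(self):
        exp = make_sumstats(["rs1"], [0.1], [0.02], ea="A", oa="G", eafs=[0.3])
        out = make_sumstats(["rs1"], [-0.2], [0.02], ea="G", oa="A", eafs=[0.7])
        h = harmonise(exp, out)
        assert h.by()[0] == pytest.approx(0.2)

    def test_strand_flip_reorients(self):
        exp = make_sumstats(["rs1"], [0.1], [0.02], ea="A", oa="G", eafs=[0.3])
        out = make_sumstats(["rs1"], [0.2], [0.02], ea="C", oa="T", eafs=[0.72])
        # outcome reported on the other strand, alleles swapped: C/T complements G/A
        h = harmonise(exp, out)
        assert h.by()[0] == pytest.approx(-0.2)

    def test_palindromic_resolved_by_frequency(self):
        exp = make_sumstats(["rs1"], [0.1], [0.02], ea="A", oa="T", eafs=[0.10])
        out = make_sumstats(["rs1"], [0.2], [0.02], ea="A", oa="T", eafs=[0.12])
        h = harmonise(exp, out)
        assert h.n_variants == 1 and h.by()[0] == pytest.approx(0.2)
        # opposite frequency side -> flip
        out2 = make_sumstats(["rs1"], [0.2], [0.02], ea="A", oa="T", eafs=[0.88])
        assert harmonise(exp, out2).by()[0] == pytest.approx(-0.2)

    def test_palindromic_ambiguous_dropped(self):
        exp = make_sumstats(["rs1", "rs2"], [0.1, 0.1], [0.02, 0.02], ea="A", oa="T",
                            eafs=[0.50, 0.2])
        out = make_sumstats(["rs1", "rs2"], [0.2, 0.2], [0.02, 0.02], ea="A", oa="T",
                            eafs=[0.48, 0.2])
        h = harmonise(exp, out)
        assert h.n_variants == 1
        assert h.drops.get("ambiguous") == ["rs1"]

    def test_empty_overlap_raises(self):
        exp = make_sumstats(["rs1"], [0.1], [0.02])
        out = make_sumstats(["rs2"], [0.2], [0.02])
        with pytest.raises(HarmonisationError):
            harmonise(exp, out)


class TestFindProxy:
    @staticmethod
    @pytest.fixture(scope="class")
    def panel():
        return simulate_ld_panel(600, 4, 5, seed=9, copy_prob=0.97, spacing=10_000)

    def test_near_duplicate_returned(self, panel):
        out = make_sumstats(["rs2"], [0.1], [0.02], positions=[panel.variants["pos"][1]])
        match = find_proxy("rs1", out, panel)
        assert match is not None and match.id == "rs2" and match.r2 > 0.8

    def test_low_r2_returns_none(self, panel):
        # rs6 starts a new LD block: essentially uncorrelated with rs5
        out = make_sumstats(["rs6"], [0.1], [0.02], positions=[panel.variants["pos"][5]])
        assert find_proxy("rs5", out, panel) is None

    def test_window_rule_excludes_distant_proxy(self):
        panel = simulate_ld_panel(600, 1, 2, seed=10, copy_prob=1.0, spacing=260_000)
        out = make_sumstats(["rs2"], [0.1], [0.02], positions=[panel.variants["pos"][1]])
        assert find_proxy("rs1", out, panel, window=250_000) is None
        assert find_proxy("rs1", out, panel, window=300_000) is not None

    def test_missing_index_raises(self, panel):
        out = make_sumstats(["rs2"], [0.1], [0.02])
        with pytest.raises(ProxyLookupError):
            find_proxy("rs999", out, panel)

    def test_substitute_proxies_orients_effect(self, panel):
        # instrument rs1 absent from outcome study; rs2 (r2 ~ 0.94) stands in
        inst = make_sumstats(["rs1"], [0.1], [0.02],
                             ea=[panel.variants["ea"][0]], oa=[panel.variants["oa"][0]],
                             eafs=[panel.variants["eaf"][0]])
        out = make_sumstats(["rs2"], [0.25], [0.02],
                            ea=[panel.variants["ea"][1]], oa=[panel.variants["oa"][1]],
                            eafs=[panel.variants["eaf"][1]],
                            positions=[panel.variants["pos"][1]])
        merged = substitute_proxies(inst, out, panel)
        row = merged[merged["SNP"] == "rs1"].iloc[0]
        assert row["PROXY"] == "rs2"
        r = np.corrcoef(panel.dosage_vector("rs1"), panel.dosage_vector("rs2"))[0, 1]
        assert row["BETA"] == pytest.approx(np.sign(r) * 0.25)


class TestIvw:
    def test_single_variant_wald_ratio(self):
        h, *_ = random_harmonised(np.random.default_rng(0), 5)
        one = h.subset(np.array([True] + [False] * 4))
        one.table.loc[0, ["BX_x0", "BY", "SY"]] = [0.5, 0.1, 0.05]
        res = mr_ivw(one)
        assert res.method == "Wald"
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)

    def test_all_outcome_betas_zero(self):
        h, *_ = random_harmonised(np.random.default_rng(1), 10)
        h.table["BY"] = 0.0
        assert mr_ivw(h).estimate == 0.0

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            h, *_ = random_harmonised(rng, rng.integers(3, 40))
            res = mr_ivw(h)
            w = 1 / h.sy() ** 2
            X = (h.bx() * np.sqrt(w))[:, None]
            y = h.by() * np.sqrt(w)
            est = float(np.linalg.lstsq(X, y, rcond=None)[0][0])
            se = float(np.sqrt(1.0 / (X[:, 0] @ X[:, 0])))
            assert res.estimate == pytest.approx(est, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-12)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        h, *_ = random_harmonised(rng, 15)
        est0 = mr_ivw(h).estimate
        flip = rng.random(15) < 0.5
        h.table.loc[flip, "BX_x0"] *= -1
        h.table.loc[flip, "BY"] *= -1
        assert mr_ivw(h).estimate == pytest.approx(est0, abs=1e-12)

    def test_non_identified_raises(self):
        h, *_ = random_harmonised(np.random.default_rng(4), 5)
        h.table["BX_x0"] = 0.0
        with pytest.raises(NonIdentifiedError):
            mr_ivw(h)


class TestEgger:
    def test_noiseless_fit_recovers_slope_and_intercept(self):
        snps = [f"rs{i}" for i in range(6)]
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        exp = make_sumstats(snps, bx, np.full(6, 0.02))
        out = make_sumstats(snps, 0.3 * bx, np.full(6, 0.02))
        res = mr_egger(harmonise(exp, out))
        assert res.slope.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_pleiotropy_in_intercept(self):
        snps = [f"rs{i}" for i in range(6)]
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        exp = make_sumstats(snps, bx, np.full(6, 0.02))
        out = make_sumstats(snps, 0.3 * bx + 0.05, np.full(6, 0.02))
        res = mr_egger(harmonise(exp, out))
        assert res.intercept == pytest.approx(0.05, abs=1e-10)
        assert res.slope.estimate == pytest.approx(0.3, abs=1e-10)

    def test_too_few_variants_raise(self):
        h, *_ = random_harmonised(np.random.default_rng(5), 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_type_one_error_calibrated(self):
        # summary-level null: no pleiotropy -> intercept p < 0.05 in ~5% of runs
        rng = np.random.default_rng(6)
        hits = 0
        runs = 400
        for _ in range(runs):
            h, *_ = random_harmonised(rng, 30, slope=0.2)
            if mr_egger(h).intercept_p < 0.05:
                hits += 1
        assert abs(hits / runs - 0.05) < 0.03


class TestMvmr:
    def test_zero_secondary_reduces_to_ivw(self):
        rng = np.random.default_rng(7)
        h, *_ = random_harmonised(rng, 20, n_exposures=2)
        h.table["BX_x1"] = 0.0
        res = mvmr(h)
        assert np.isnan(res[1].estimate)
        assert res[0].estimate == pytest.approx(mr_ivw(h, "x0").estimate, abs=1e-10)

    def test_exact_two_exposure_recovery(self):
        rng = np.random.default_rng(8)
        snps = [f"rs{i}" for i in range(10)]
        bx1 = rng.normal(0, 0.1, 10)
        bx2 = rng.normal(0, 0.1, 10)
        by = 0.0 * bx1 + 0.4 * bx2
        e1 = make_sumstats(snps, bx1, np.full(10, 0.02), trait_id="x1")
        e2 = make_sumstats(snps, bx2, np.full(10, 0.02), trait_id="x2")
        out = make_sumstats(snps, by, np.full(10, 0.02), trait_id="y")
        res = mvmr(harmonise([e1, e2], out))
        assert res[0].estimate == pytest.approx(0.0, abs=1e-10)
        assert res[1].estimate == pytest.approx(0.4, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            k = int(rng.integers(5, 50))
            h, *_ = random_harmonised(rng, k, n_exposures=2)
            # correlate the exposure columns
            h.table["BX_x1"] = 0.6 * h.table["BX_x0"] + 0.4 * h.table["BX_x1"]
            res = mvmr(h)
            X = np.column_stack([h.bx("x0"), h.bx("x1")])
            W = np.diag(1 / h.sy() ** 2)
            xtwx = X.T @ W @ X
            coef = np.linalg.solve(xtwx, X.T @ W @ h.by())
            cov = np.linalg.inv(xtwx)
            for i in range(2):
                assert res[i].estimate == pytest.approx(coef[i], abs=1e-10)
                assert res[i].se == pytest.approx(np.sqrt(cov[i, i]), abs=1e-12)

    def test_collinear_columns_raise(self):
        rng = np.random.default_rng(10)
        h, *_ = random_harmonised(rng, 15, n_exposures=2)
        h.table["BX_x1"] = 2.0 * h.table["BX_x0"]
        with pytest.raises(WeakConditionalInstrumentError):
            mvmr(h)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(11)
        h, *_ = random_harmonised(rng, 20, n_exposures=2)
        base = [r.estimate for r in mvmr(h)]
        flip = rng.random(20) < 0.5
        for col in ("BX_x0", "BX_x1", "BY"):
            h.table.loc[flip, col] *= -1
        flipped = [r.estimate for r in mvmr(h)]
        np.testing.assert_allclose(base, flipped, atol=1e-12)


class TestSteiger:
    def test_retention_by_variance_comparison(self):
        exp = make_sumstats(["rs1", "rs2"], [0.05, 0.02], [0.01, 0.01], eafs=[0.3, 0.3])
        out = make_sumstats(["rs1", "rs2"], [0.02, 0.05], [0.01, 0.01], eafs=[0.3, 0.3])
        h = harmonise(exp, out)
        kept, excl = steiger_filter(h)
        assert list(kept.table["SNP"]) == ["rs1"]
        assert excl["retained"].tolist() == [True, False]

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(12)
        h, exps, out = random_harmonised(rng, 10)
        kept, excl = steiger_filter(h)
        for _, row in excl.iterrows():
            eaf = float(h.table.set_index("SNP").loc[row["SNP"], "EAF"])
            maf = min(eaf, 1 - eaf)
            bx = float(h.table.set_index("SNP").loc[row["SNP"], "BX_x0"])
            by = float(h.table.set_index("SNP").loc[row["SNP"], "BY"])
            vx = 2 * bx**2 * maf * (1 - maf)
            vy = 2 * by**2 * maf * (1 - maf)
            assert row["var_explained_exposure"] == pytest.approx(vx, rel=1e-12)
            assert row["var_explained_outcome"] == pytest.approx(vy, rel=1e-12)
            assert row["retained"] == (vx >= vy)
        assert kept.n_variants <= h.n_variants

    def test_never_increases_count_and_directionally_consistent(self):
        rng = np.random.default_rng(13)
        agree = 0
        for _ in range(50):
            h, *_ = random_harmonised(rng, 40, slope=0.3)
            kept, _ = steiger_filter(h)
            assert kept.n_variants <= h.n_variants
            if kept.n_variants >= 2 and np.sign(mr_ivw(kept).estimate) == np.sign(
                mr_ivw(h).estimate
            ):
                agree += 1
        assert agree >= 48  # no reverse causation simulated -> signs agree


class TestMetaAndScales:
    def test_two_identical_inputs(self):
        r = MRResult.from_estimate("IVW", "x", "y", 0.2, 0.1, 10)
        pooled = fixed_effect_meta([r, r])
        assert pooled.estimate == pytest.approx(0.2, abs=1e-15)
        assert pooled.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-15)

    def test_single_input_identity(self):
        r = MRResult.from_estimate("IVW", "x", "y", 0.2, 0.1, 10)
        assert fixed_effect_meta([r]) is r

    def test_hand_computed_two_study_case(self):
        a = MRResult.from_estimate("IVW", "x", "y1", 0.1, 0.1, 10)
        b = MRResult.from_estimate("IVW", "x", "y2", 0.3, 0.1, 10)
        pooled = fixed_effect_meta([a, b])
        assert pooled.estimate == pytest.approx(0.2, abs=1e-12)
        assert pooled.se == pytest.approx(np.sqrt(1 / 200), abs=1e-12)

    def test_matches_metafor_fixed_effect_weights(self):
        # independent hand calculation with unequal SEs
        a = MRResult.from_estimate("IVW", "x", "y1", 0.15, 0.05, 10)
        b = MRResult.from_estimate("IVW", "x", "y2", 0.35, 0.12, 10)
        w = np.array([1 / 0.05**2, 1 / 0.12**2])
        expected = np.sum(w * [0.15, 0.35]) / w.sum()
        pooled = fixed_effect_meta([a, b])
        assert pooled.estimate == pytest.approx(expected, rel=1e-12)

    def test_mixed_scales_raise(self):
        a = MRResult.from_estimate("IVW", "x", "y1", 0.2, 0.1, 10, scale="sd")
        b = MRResult.from_estimate("IVW", "x", "y2", 0.2, 0.1, 10, scale="log_or")
        with pytest.raises(ScaleMismatchError):
            fixed_effect_meta([a, b])

    def test_or_round_trip(self):
        r = MRResult.from_estimate("IVW", "x", "y", 0.9, 0.03, 10, scale="log_or")
        orr = to_odds_ratio(r)
        assert orr.estimate == pytest.approx(np.exp(0.9))
        assert orr.p == r.p
        back = from_odds_ratio(orr)
        assert back.estimate == pytest.approx(0.9, abs=1e-12)
        assert back.ci_low == pytest.approx(r.ci_low, abs=1e-12)
        with pytest.raises(ScaleMismatchError):
            to_odds_ratio(orr)
        zero = to_odds_ratio(MRResult.from_estimate("IVW", "x", "y", 0.0, 0.1, 5, scale="log_or"))
        assert zero.estimate == pytest.approx(1.0)
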