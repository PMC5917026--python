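"""FDR, signatures, moderated t (incl. external limma cross-check),
rank enrichment, and reporter-assay effects."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelreg import enrichment
from allelreg.enrichment import GeneScore
from allelreg.genomics_io import ExpressionMatrix
from allelreg import synthdata
from allelreg.config import SimulationConfig


def expr_from_log2(mat: np.ndarray, prefix: str) -> ExpressionMatrix:
    """Wrap a log2-space matrix as raw FPKM so that transformed('log2')
    recovers it exactly (fpkm = 2^x - 1)."""
    raw = 2.0 ** mat - 1.0
    df = pd.DataFrame(raw, index=[f"g{i}" for i in range(mat.shape[0])],
                      columns=[f"{prefix}{j}" for j in range(mat.shape[1])])
    return ExpressionMatrix(df)


class TestBhFdr:
    def test_hand_computed_stepup(self):
        # p = (0.01, 0.02, 0.03, 0.04), m = 4:
        # q_(i) = min_{j>=i} p_(j) * m / j = 0.04 for every rank
        q = enrichment.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert enrichment.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(enrichment.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(57)
        p = np.sort(rng.uniform(size=50))
        q = enrichment.bh_fdr(p)
        assert all(a <= b + 1e-15 for a, b in zip(q, q[1:]))
        assert (q >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enrichment.bh_fdr([0.5, 1.5])


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(n_genes=600, seed=59)
    panel = synthdata.simulate_haplotype_panel(cfg)
    geno = synthdata.panel_to_genotypes(panel)
    expr, sets = synthdata.simulate_coexpression_and_sets(cfg, geno)
    return cfg, expr, sets


class TestCorrelationSignature:
    def test_anchor_excluded_from_its_own_signature(self, planted):
        _, expr, _ = planted
        scores = enrichment.correlation_signature(expr, "ELL2")
        assert "ELL2" not in {s.gene for s in scores}

    def test_planted_members_score_higher(self, planted):
        _, expr, sets = planted
        scores = enrichment.correlation_signature(expr, "ELL2")
        members = set(sets["RPG"]) | set(sets["SEC"])
        r_in = [s.score for s in scores if s.gene in members]
        r_out = [s.score for s in scores if s.gene not in members]
        assert np.mean(r_in) > np.mean(r_out) + 0.3

    def test_null_matrix_has_no_fdr_significant_genes(self):
        rng = np.random.default_rng(61)
        raw = pd.DataFrame(
            rng.lognormal(3.0, 0.5, size=(400, 50)),
            index=[f"g{i}" for i in range(400)],
            columns=[f"s{j}" for j in range(50)])
        expr = ExpressionMatrix(raw)
        anchor = rng.normal(size=50)
        scores = enrichment.correlation_signature(expr, anchor)
        frac_sig = np.mean([s.q < 0.05 for s in scores])
        assert frac_sig <= 0.01

    def test_low_expression_genes_filtered(self):
        raw = pd.DataFrame(
            [[10.0] * 6, [0.1] * 6, [20.0, 18, 22, 19, 21, 20]],
            index=["anchor", "low", "kept"],
            columns=[f"s{j}" for j in range(6)])
        raw.loc["anchor"] = [1, 2, 3, 4, 5, 6]
        expr = ExpressionMatrix(raw)
        scores = enrichment.correlation_signature(expr, "anchor",
                                                  min_mean_fpkm=5.0)
        assert {s.gene for s in scores} == {"kept"}

    def test_constant_anchor_rejected(self):
        raw = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                           columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            enrichment.correlation_signature(ExpressionMatrix(raw),
                                             np.ones(3), min_mean_fpkm=0.0)


class TestModeratedT:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(63)
        mat = rng.normal(5.0, 1.0, size=(40, 5))
        a = expr_from_log2(mat, "a")
        b = expr_from_log2(mat, "b")
        scores, _ = enrichment.moderated_t(a, b)
        for s in scores:
            assert s.score == pytest.approx(0.0, abs=1e-10)
            assert s.p == pytest.approx(1.0, abs=1e-10)

    def test_prior_parameters_recovered_from_simulated_model(self):
        # simulate the assumed model exactly: s0_sq = 1, d0 = 4,
        # sigma_g^2 ~ d0 s0^2 / chi2_d0, 4 + 4 samples per gene
        d0_true, s0_true = 4.0, 1.0
        d0_hats, s0_hats = [], []
        for seed in range(50):
            rng = np.random.default_rng(10_000 + seed)
            n_genes = 5000
            sig2 = d0_true * s0_true / rng.chisquare(d0_true, n_genes)
            d_g = 6.0
            s2 = sig2 * rng.chisquare(int(d_g), n_genes) / d_g
            d0_hat, s0_hat = enrichment.fit_variance_prior(s2, d_g)
            d0_hats.append(d0_hat)
            s0_hats.append(s0_hat)
        assert 2.5 < np.median(d0_hats) < 6.0
        assert 0.8 < np.median(s0_hats) < 1.25

    def test_override_limits_interpolate_ordinary_t_and_z(self):
        rng = np.random.default_rng(65)
        # gene-specific variances so a finite prior df is identifiable
        sd = np.sqrt(4.0 / rng.chisquare(4.0, size=400))
        A = rng.normal(5.0, 1.0, size=(400, 4)) * sd[:, None]
        B = rng.normal(5.0, 1.0, size=(400, 4)) * sd[:, None]
        B[:10] += 2.0
        a, b = expr_from_log2(A, "a"), expr_from_log2(B, "b")
        plain, p_plain = enrichment.moderated_t(a, b, d0_override=0.0)
        zlim, p_z = enrichment.moderated_t(a, b, d0_override=float("inf"))
        mid, p_mid = enrichment.moderated_t(a, b)
        # d0 = 0 reproduces the ordinary two-sample pooled t
        for s, gA, gB in zip(plain, A, B):
            t_ref = stats.ttest_ind(gA, gB, equal_var=True)
            assert s.score == pytest.approx(t_ref.statistic, rel=1e-9)
            assert s.p == pytest.approx(t_ref.pvalue, rel=1e-9)
        assert p_plain.d_g == 6.0
        # moderated |t| lies between the two limits' spread behavior:
        # shrunken variances are between s_g^2 and s0^2
        assert 0 < p_mid.d0 < float("inf")

    def test_zero_variance_genes_flagged_not_crashing(self):
        A = np.vstack([np.full(4, 3.0), np.random.default_rng(67).normal(
            5, 1, size=(5, 4))])
        B = np.vstack([np.full(4, 3.0), np.random.default_rng(68).normal(
            5, 1, size=(5, 4))])
        scores, params = enrichment.moderated_t(expr_from_log2(A, "a"),
                                                expr_from_log2(B, "b"))
        assert scores[0].flagged
        assert params.n_genes_fit == 5

    def test_prior_fit_matches_limma_squeezeVar(self, tmp_path):
        # external oracle: R limma's squeezeVar on the same variances
        rng = np.random.default_rng(69)
        sig2 = 4.0 * 1.0 / rng.chisquare(4.0, 2000)
        d_g = 6.0
        s2 = sig2 * rng.chisquare(int(d_g), 2000) / d_g
        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path}/s2.txt", quiet=TRUE)\n'
            'fit <- squeezeVar(s2, df=6)\n'
            'cat(sprintf("%.12g %.12g\\n", fit$df.prior, fit$var.prior))\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        d0_r, s0_r = map(float, out.stdout.split())
        d0_py, s0_py = enrichment.fit_variance_prior(s2, d_g)
        assert d0_py == pytest.approx(d0_r, rel=0.02)
        assert s0_py == pytest.approx(s0_r, rel=0.02)
        # and the squeezed posterior variances agree gene by gene
        post_py = (d0_py * s0_py + d_g * s2) / (d0_py + d_g)
        script2 = tmp_path / "oracle2.R"
        script2.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path}/s2.txt", quiet=TRUE)\n'
            'fit <- squeezeVar(s2, df=6)\n'
            f'write(fit$var.post, "{tmp_path}/post.txt", ncolumns=1)\n')
        subprocess.run(["Rscript", str(script2)], check=True,
                       capture_output=True)
        post_r = np.loadtxt(tmp_path / "post.txt")
        assert np.allclose(post_py, post_r, rtol=0.02)


class TestLog2Ratio:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(71)
        mat = rng.lognormal(2, 1, size=(20, 6))
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(20)],
                          columns=[f"s{j}" for j in range(6)])
        scores = enrichment.log2_ratio_signature(ExpressionMatrix(df),
                                                 ExpressionMatrix(df.copy()))
        assert all(s.score == 0.0 for s in scores)

    def test_doubling_with_floor_hand_value(self):
        a = ExpressionMatrix(pd.DataFrame([[7.5, 7.5]], index=["g"],
                                          columns=["x", "y"]))
        b = ExpressionMatrix(pd.DataFrame([[3.5, 3.5]], index=["g"],
                                          columns=["u", "v"]))
        s = enrichment.log2_ratio_signature(a, b, floor=0.5)
        assert s[0].score == pytest.approx(1.0)  # log2(8/4)


class TestRankEnrichment:
    @staticmethod
    def scores_from(vals):
        return [GeneScore(gene=f"g{i}", score=float(v),
                          score_type="correlation")
                for i, v in enumerate(vals)]

    def test_balanced_symmetric_set_gives_zero_z(self):
        # members occupy perfectly symmetric ranks around the median
        scores = self.scores_from(range(10))
        members = ["g0", "g9", "g1", "g8"]
        res = enrichment.rank_enrichment(scores, members)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_top_block_strongly_enriched(self):
        scores = self.scores_from(range(200))
        members = [f"g{i}" for i in range(180, 200)]
        res = enrichment.rank_enrichment(scores, members)
        assert res.direction == "up"
        assert res.p < 1e-10

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(73)
        vals = rng.normal(size=120)
        members = [f"g{i}" for i in rng.choice(120, 15, replace=False)]
        r1 = enrichment.rank_enrichment(self.scores_from(vals), members)
        r2 = enrichment.rank_enrichment(self.scores_from(np.exp(3 * vals)),
                                        members)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_normal_approximation_agrees_with_permutation(self):
        rng = np.random.default_rng(75)
        vals = rng.normal(size=300)
        vals[:25] += 0.6
        members = [f"g{i}" for i in range(25)]
        scores = self.scores_from(vals)
        a = enrichment.rank_enrichment(scores, members, mode="ranksum")
        b = enrichment.rank_enrichment(scores, members, mode="permutation",
                                       n_permutations=20000, seed=5)
        mc = 3 * math.sqrt(max(b.p, 1e-4) * (1 - b.p) / 20000)
        assert abs(a.p - b.p) <= mc + 0.005

    def test_statistic_matches_scipy_mannwhitney_normal_p(self):
        rng = np.random.default_rng(77)
        vals = rng.normal(size=90)
        members = [f"g{i}" for i in rng.choice(90, 20, replace=False)]
        res = enrichment.rank_enrichment(self.scores_from(vals), members)
        in_vals = vals[[int(m[1:]) for m in members]]
        out_vals = np.delete(vals, [int(m[1:]) for m in members])
        ref = stats.mannwhitneyu(in_vals, out_vals, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_sets_rejected(self):
        scores = self.scores_from(range(5))
        with pytest.raises(ValueError):
            enrichment.rank_enrichment(scores, ["nope"])
        with pytest.raises(ValueError):
            enrichment.rank_enrichment(scores, [f"g{i}" for i in range(5)])


class TestLuciferase:
    @staticmethod
    def frame(firefly_risk, renilla_risk, firefly_prot, renilla_prot):
        return pd.DataFrame({"firefly_risk": firefly_risk,
                             "renilla_risk": renilla_risk,
                             "firefly_prot": firefly_prot,
                             "renilla_prot": renilla_prot})

    def test_equal_alleles_zero_effect(self):
        m = self.frame([10, 12, 11], [5, 6, 5.5], [10, 12, 11], [5, 6, 5.5])
        assert enrichment.luciferase_effect(m).effect == pytest.approx(0.0)

    def test_hand_computed_halving(self):
        # risk/prot normalized ratios 0.5, 0.5, 0.25 -> median log2 = -1
        m = self.frame([5, 5, 2.5], [10, 10, 10], [10, 10, 10], [10, 10, 10])
        res = enrichment.luciferase_effect(m)
        assert res.effect == pytest.approx(-1.0)
        assert sorted(res.replicate_log2_ratios) == pytest.approx([-2, -1, -1])

    def test_renilla_rescaling_invariance(self):
        rng = np.random.default_rng(79)
        m = self.frame(rng.uniform(5, 15, 4), rng.uniform(5, 15, 4),
                       rng.uniform(5, 15, 4), rng.uniform(5, 15, 4))
        base = enrichment.luciferase_effect(m).effect
        m2 = m.copy()
        m2["firefly_risk"] *= 3.0
        m2["renilla_risk"] *= 3.0
        assert enrichment.luciferase_effect(m2).effect == pytest.approx(base)

    def test_replicate_count_bounds(self):
        with pytest.raises(ValueError, match="3..7"):
            enrichment.luciferase_effect(self.frame([1, 1], [1, 1], [1, 1],
                                                    [1, 1]))
        with pytest.raises(ValueError, match="positive"):
            enrichment.luciferase_effect(self.frame([1, 1, 0], [1, 1, 1],
                                                    [1, 1, 1], [1, 1, 1]))
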