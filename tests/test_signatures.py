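"""DE, scoring, enrichment and cohort selection against independent oracles."""

import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gcniche as g
from gcniche.signatures import moderated_t_paired_de


def paired_fixture(seed=0, n_genes=50, n_pairs=8, n_de=5, **kw):
    cfg = g.ExpressionSimConfig(
        seed=seed, n_genes=n_genes, n_pairs=n_pairs, n_de=n_de, **kw
    )
    return g.simulate_paired_roi_expression(cfg)


class TestModeratedT:
    def test_equal_variances_shrink_to_full_pooling(self):
        # one shared true variance: the prior df estimate diverges, the
        # moderated t orders genes exactly by |logFC|, and the ordering
        # still agrees closely with the ordinary paired t
        expr, _ = paired_fixture(seed=1, n_genes=50, n_pairs=10, n_de=8, gene_sd=0.5)
        res = moderated_t_paired_de(expr)
        assert np.isinf(res.d0)
        t_abs = res.table["t"].abs().to_numpy()
        lfc_abs = res.table["logFC"].abs().to_numpy()
        assert (np.argsort(t_abs) == np.argsort(lfc_abs)).all()
        dz = expr.values.loc[:, expr.design.zone == "DZ"].to_numpy()
        lz = expr.values.loc[:, expr.design.zone == "LZ"].to_numpy()
        d = dz - lz
        t_ord = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(d.shape[1]))
        assert stats.spearmanr(t_abs, np.abs(t_ord)).statistic > 0.9

    def test_d0_zero_recovers_ordinary_paired_t(self):
        expr, _ = paired_fixture(seed=2)
        res = moderated_t_paired_de(expr, d0_override=0.0)
        dz = expr.values.loc[:, expr.design.zone == "DZ"].to_numpy()
        lz = expr.values.loc[:, expr.design.zone == "LZ"].to_numpy()
        d = dz - lz
        t_ord = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(d.shape[1]))
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_ord, rtol=1e-10)

    def test_matches_limma_ebayes_oracle(self):
        # independent cross-check: limma's one-sample eBayes on the same
        # within-pair differences
        expr, _ = paired_fixture(seed=42, n_genes=80, n_pairs=6, n_de=10,
                                 logfc=1.5, gene_sd=0.6)
        res = moderated_t_paired_de(expr)
        dz = expr.values.loc[:, expr.design.zone == "DZ"].to_numpy()
        lz = expr.values.loc[:, expr.design.zone == "LZ"].to_numpy()
        diffs = pd.DataFrame(dz - lz, index=expr.values.index)
        with tempfile.TemporaryDirectory() as td:
            diffs.to_csv(f"{td}/diffs.tsv", sep="\t")
            script = f"""
suppressMessages(library(limma))
d <- as.matrix(read.delim("{td}/diffs.tsv", row.names=1))
fit <- eBayes(lmFit(d, design=matrix(1, ncol(d), 1)))
out <- data.frame(t_limma=fit$t[,1], p_limma=fit$p.value[,1],
                  d0=fit$df.prior, s0=fit$s2.prior)
write.csv(out, "{td}/limma.csv")
"""
            proc = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True
            )
            assert proc.returncode == 0, proc.stderr
            lim = pd.read_csv(f"{td}/limma.csv", index_col=0)
        assert res.d0 == pytest.approx(lim["d0"].iloc[0], rel=1e-3)
        assert res.s0_sq == pytest.approx(lim["s0"].iloc[0], rel=1e-3)
        np.testing.assert_allclose(
            res.table["t"].to_numpy(), lim["t_limma"].to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(
            res.table["pvalue"].to_numpy(), lim["p_limma"].to_numpy(), rtol=1e-6
        )

    def test_bh_adjustment_monotone(self):
        expr, _ = paired_fixture(seed=3, n_genes=200, n_de=30)
        tab = moderated_t_paired_de(expr).table
        order = np.argsort(tab["pvalue"].to_numpy())
        adj_sorted = tab["adj_pvalue"].to_numpy()[order]
        assert (np.diff(adj_sorted) >= -1e-12).all()
        assert (tab["adj_pvalue"] >= tab["pvalue"] - 1e-12).all()

    def test_posterior_variance_between_bounds(self):
        expr, _ = paired_fixture(seed=4, n_genes=300)
        res = moderated_t_paired_de(expr)
        s2 = res.table["s2"].to_numpy()
        n = res.df_residual + 1
        post = (res.d0 * res.s0_sq + res.df_residual * s2) / (res.d0 + res.df_residual)
        lo = np.minimum(s2, res.s0_sq) - 1e-12
        hi = np.maximum(s2, res.s0_sq) + 1e-12
        assert ((post >= lo) & (post <= hi)).all()

    def test_incomplete_pair_error_names_pair(self):
        expr, _ = paired_fixture(seed=5)
        vals = expr.values.drop(columns=["P03_LZ"])
        design = expr.design.drop(index=["P03_LZ"])
        broken = g.ExpressionMatrix(vals, design)
        with pytest.raises(ValueError, match="P03"):
            moderated_t_paired_de(broken)

    def test_rank_sum_variant_with_lfc_filter(self):
        expr, truth = paired_fixture(
            seed=6, n_genes=300, n_pairs=12, n_de=40, logfc=2.0, gene_sd=0.4
        )
        res = moderated_t_paired_de(expr, method="rank_sum", lfc_cutoff=0.25)
        assert res.method == "rank_sum"
        hits = set(res.significant_genes)
        planted = set(truth.de_genes)
        assert len(hits & planted) / len(planted) > 0.8
        assert (res.table.loc[res.table.significant, "logFC"].abs() > 0.25).all()


class TestScoring:
    def test_single_gene_mean_z_is_gene_zscore(self):
        expr, _ = paired_fixture(seed=7, n_genes=20)
        gene = expr.values.index[3]
        sig = g.GeneSignature("one", [gene])
        score = g.score_signature(expr, sig, method="mean_z")
        row = expr.values.loc[gene]
        z = (row - row.mean()) / row.std(ddof=0)
        np.testing.assert_allclose(score.to_numpy(), z.to_numpy())

    def test_constant_matrix_total_vs_mean_z(self):
        vals = pd.DataFrame(3.0, index=["g1", "g2"], columns=["s1", "s2", "s3"])
        em = g.ExpressionMatrix(vals)
        sig = g.GeneSignature("s", ["g1", "g2"])
        assert (g.score_signature(em, sig, method="total") == 6.0).all()
        with pytest.raises(ValueError):
            g.score_signature(em, sig, method="mean_z")

    def test_mean_z_invariant_to_genewise_affine_rescale(self):
        expr, _ = paired_fixture(seed=8, n_genes=30)
        sig = g.GeneSignature("s", list(expr.values.index[:10]))
        base = g.score_signature(expr, sig, method="mean_z")
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 3.0, 30)[:, None]
        b = rng.normal(0, 5, 30)[:, None]
        scaled = g.ExpressionMatrix(expr.values * a + b, expr.design)
        rescored = g.score_signature(scaled, sig, method="mean_z")
        np.testing.assert_allclose(base.to_numpy(), rescored.to_numpy(), atol=1e-10)

    def test_no_overlap_rejected(self):
        expr, _ = paired_fixture(seed=9, n_genes=10)
        with pytest.raises(ValueError):
            g.score_signature(expr, g.GeneSignature("x", ["NOPE"]))


class TestTertiles:
    def test_nine_distinct_scores_split_evenly(self):
        s = pd.Series(np.arange(9.0))
        tert = g.tertile_stratify(s)
        assert tert.value_counts().to_dict() == {"low": 3, "mid": 3, "high": 3}

    def test_tie_convention_assigns_lower_stratum(self):
        s = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 3.0])
        tert = g.tertile_stratify(s)
        # oracle: q1/3 and q2/3 of the sorted array with linear interpolation;
        # ties at a boundary fall into the lower stratum
        q1, q2 = np.quantile(s, [1 / 3, 2 / 3])
        expected = np.where(s <= q1, "low", np.where(s <= q2, "mid", "high"))
        assert (tert.to_numpy() == expected).all()
        # in particular all three 1.0 values land together
        assert tert[s == 1.0].nunique() == 1

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            g.tertile_stratify(pd.Series([2.0, 2.0, 2.0]))


class TestEnrichment:
    def toy_ranking(self):
        return pd.Series(
            [5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
            index=[f"g{i}" for i in range(8)],
        )

    def test_hand_computed_running_sum(self):
        ranked = self.toy_ranking()
        sig = g.GeneSignature("top", ["g0", "g2", "g4"])
        res = g.enrichment_score(ranked, sig, n_perm=99, seed=0)
        # manual oracle, weight 1: hit increments |stat|/9 at ranks 0,2,4;
        # misses decrement 1/5
        inc = {0: 5 / 9, 2: 3 / 9, 4: 1 / 9}
        run, best = 0.0, 0.0
        for i in range(8):
            run += inc.get(i, -1 / 5)
            if abs(run) > abs(best):
                best = run
        assert res.es == pytest.approx(best)

    def test_signature_at_top_is_maximal(self):
        ranked = self.toy_ranking()
        sig = g.GeneSignature("top", ["g0", "g1", "g2"])
        res = g.enrichment_score(ranked, sig, n_perm=99, seed=0)
        # all hits first: the running sum peaks at the last hit with value 1
        assert res.es == pytest.approx(1.0)
        assert set(res.leading_edge) == {"g0", "g1", "g2"}

    def test_reversal_symmetry(self):
        ranked = self.toy_ranking()
        sig = g.GeneSignature("s", ["g0", "g1"])
        mirrored = pd.Series(
            -ranked.to_numpy()[::-1], index=ranked.index[::-1]
        )
        sig_m = g.GeneSignature("s", ["g0", "g1"])
        a = g.enrichment_score(ranked, sig, n_perm=9, seed=0, weight=1.0)
        b = g.enrichment_score(mirrored, sig_m, n_perm=9, seed=0, weight=1.0)
        assert a.es == pytest.approx(-b.es)

    def test_permutation_p_calibrated(self):
        # random signatures on a fixed ranked list: p should be uniform
        rng = np.random.default_rng(20)
        ranked = pd.Series(
            rng.normal(size=60), index=[f"g{i}" for i in range(60)]
        )
        rejections = 0
        n_sims = 400
        for s in range(n_sims):
            sim_rng = np.random.default_rng(1000 + s)
            genes = list(sim_rng.choice(60, size=8, replace=False))
            sig = g.GeneSignature("r", [f"g{i}" for i in genes])
            res = g.enrichment_score(ranked, sig, n_perm=99, seed=s)
            rejections += res.p <= 0.05
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_disjoint_signature_rejected(self):
        with pytest.raises(ValueError):
            g.enrichment_score(self.toy_ranking(), g.GeneSignature("x", ["zz"]))


class TestCrossCohort:
    def make_cohorts(self, n_cohorts, beta, seed0=0, n_samples=120):
        sig = g.GeneSignature("dz", [f"S{i:03d}" for i in range(30)])
        cohorts, tc = {}, None
        for i in range(n_cohorts):
            cfg = g.ExpressionSimConfig(
                seed=seed0 + i, n_genes=200, n_samples=n_samples, cohort_beta=beta
            )
            em, truth = g.simulate_cohort(cfg, sig, f"c{i}")
            cohorts[f"c{i}"] = em
            tc = g.GeneSignature("tcell", truth.tcell_genes)
        return cohorts, sig, tc

    def test_planted_anticorrelation_selected(self):
        cohorts, sig, tc = self.make_cohorts(4, beta=-2.0)
        out = g.cross_cohort_gene_correlations(cohorts, sig, tc, min_datasets=3)
        assert len(out.selected) / len(sig) >= 0.9

    def test_threshold_monotonicity(self):
        cohorts, sig, tc = self.make_cohorts(4, beta=-2.0, seed0=50)
        a = g.cross_cohort_gene_correlations(cohorts, sig, tc, min_datasets=2)
        b = g.cross_cohort_gene_correlations(cohorts, sig, tc, min_datasets=3)
        assert set(b.selected) <= set(a.selected)

    def test_impossible_threshold_empty(self):
        cohorts, sig, tc = self.make_cohorts(2, beta=-2.0, seed0=80)
        out = g.cross_cohort_gene_correlations(cohorts, sig, tc, min_datasets=3)
        assert out.selected == []

    def test_small_cohort_excluded_with_warning(self):
        cohorts, sig, tc = self.make_cohorts(3, beta=-2.0, seed0=90)
        small_cfg = g.ExpressionSimConfig(seed=99, n_genes=200, n_samples=5)
        cohorts["tiny"], _ = g.simulate_cohort(small_cfg, sig, "tiny")
        with pytest.warns(UserWarning, match="tiny"):
            out = g.cross_cohort_gene_correlations(cohorts, sig, tc)
        assert "tiny" in out.excluded_cohorts


class TestGroupAssignment:
    def test_antithetic_scores_reduce_to_dz_tertiles(self):
        rng = np.random.default_rng(30)
        dz = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        lz = -dz
        groups = g.dz_lz_group_assignment(dz, lz)
        tert = g.tertile_stratify(dz)
        expected = tert.map(
            {"high": "DZ-like", "mid": "Intermediate", "low": "LZ-like"}
        )
        assert (groups == expected).all()

    def test_two_cluster_cohort_high_purity(self):
        rng = np.random.default_rng(31)
        n = 150
        latent = np.concatenate([np.full(n, 1.0), np.full(n, -1.0)])
        dz = pd.Series(latent + rng.normal(0, 0.3, 2 * n))
        lz = pd.Series(-latent + rng.normal(0, 0.3, 2 * n))
        groups = g.dz_lz_group_assignment(dz, lz)
        true_dz = np.arange(2 * n) < n
        called_dz = (groups == "DZ-like").to_numpy()
        purity = (true_dz & called_dz).sum() / called_dz.sum()
        assert purity >= 0.9

    def test_degenerate_delta_rejected(self):
        s = pd.Series([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            g.dz_lz_group_assignment(s, s)
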