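"""Composition PCA, moderated linear models, and preranked GSEA."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from scipy.optimize import brentq

from ctdeconv import (
    enrichment_score,
    moderated_lm,
    preranked_gsea,
    proportion_pca,
    run_de_models,
)


def _expr_fixture(n_genes=10, n=8, seed=5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {"intercept": 1.0, "case": np.repeat([0.0, 1.0], n // 2),
         "cov": rng.normal(size=n)},
        index=[f"s{i}" for i in range(n)],
    )
    beta = rng.normal(size=(n_genes, 3))
    sd = np.sqrt(0.5 / rng.chisquare(6, n_genes) * 6)
    y = beta @ X.to_numpy().T + rng.normal(size=(n_genes, n)) * sd[:, None]
    expr = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)], columns=X.index)
    return expr, X


class TestProportionPCA:
    def _props(self, n=20, k=7, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.dirichlet(np.linspace(6, 1, k), size=n),
                            index=[f"S{i}" for i in range(n)],
                            columns=[f"type{j}" for j in range(k)])

    def test_rank_one_matrix_pc1_explains_all(self):
        base = np.array([0.5, 0.3, 0.1, 0.05, 0.03, 0.01, 0.01])
        t = np.linspace(0, 1, 20)
        d = np.array([1, -1, 0, 0, 0, 0, 0]) * 0.02
        p = base[None, :] + t[:, None] * d[None, :]
        pcs = proportion_pca(pd.DataFrame(p), n_pcs=5)
        assert pcs.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_orthogonal(self):
        pcs = proportion_pca(self._props())
        gram = pcs.scores.T @ pcs.scores
        off = gram.to_numpy() - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_loadings_match_hand_eigendecomposition(self):
        """3-sample, 2-column toy: PC1 loading equals the top eigenvector of
        the 2x2 covariance (computed by hand from the characteristic
        polynomial)."""
        x = np.array([[0.2, 0.8], [0.5, 0.5], [0.8, 0.2]])
        c = x - x.mean(axis=0)
        cov = c.T @ c / 2.0
        # eigenvector of [[a, b], [b, a]] with a=b: (1, -1)/sqrt(2)
        pcs = proportion_pca(pd.DataFrame(x), n_pcs=1)
        v = pcs.loadings.to_numpy()[:, 0]
        expected = np.array([1, -1]) / np.sqrt(2)
        assert abs(abs(v @ expected) - 1.0) < 1e-12
        assert pcs.variance_explained[0] == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        p = pd.DataFrame(np.full((10, 7), 1 / 7))
        with pytest.raises(ValueError, match="constant"):
            proportion_pca(p)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            proportion_pca(self._props(n=4))


def _oracle_squeeze(s2, df):
    """Independent implementation of the moment-matching shrinkage: solve the
    trigamma equation by bisection rather than Newton."""
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    excess = e.var(ddof=1) - special.polygamma(1, df / 2)
    if excess <= 0:
        return np.inf, float(np.exp(e.mean())), np.full_like(s2, np.exp(e.mean()))
    half_d0 = brentq(lambda x: special.polygamma(1, x) - excess, 1e-8, 1e8)
    d0 = 2 * half_d0
    s0 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    post = (d0 * s0 + df * s2) / (d0 + df)
    return d0, s0, post


class TestModeratedLM:
    def test_matches_independent_shrinkage_oracle(self):
        """(d0, s0^2, t_mod) agree with a brute-force implementation of the
        moment equations to 1e-8 on a 10-gene fixture."""
        expr, X = _expr_fixture()
        table, info = moderated_lm(expr, X, "case")
        # oracle: per-gene OLS + moment equations, all recomputed from scratch
        Xv = X.to_numpy()
        h = np.linalg.inv(Xv.T @ Xv)
        betas, s2s = [], []
        for g in expr.index:
            y = expr.loc[g].to_numpy()
            b = h @ Xv.T @ y
            r = y - Xv @ b
            betas.append(b[1])
            s2s.append((r @ r) / (len(y) - 3))
        d0, s0, post = _oracle_squeeze(np.array(s2s), len(X) - 3)
        assert info["d0"] == pytest.approx(d0, abs=1e-8)
        assert info["s0_sq"] == pytest.approx(s0, abs=1e-8)
        t_expected = np.array(betas) / np.sqrt(post * h[1, 1])
        np.testing.assert_allclose(table["t_mod"].to_numpy(), t_expected, atol=1e-8)

    def test_equal_variances_pool_completely(self):
        """Genes sharing identical residual variance drive d0 -> inf and
        t_mod equals the ordinary t computed with the pooled variance."""
        expr, X = _expr_fixture(n_genes=6)
        # clone one gene with shifted means: residuals identical across genes
        y0 = expr.iloc[0].to_numpy()
        rows = [y0 + k for k in range(6)]
        expr_eq = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)], columns=X.index)
        table, info = moderated_lm(expr_eq, X, "case")
        assert np.isinf(info["d0"])
        # every posterior variance collapses to the common prior variance
        np.testing.assert_allclose(table["s2_post"], info["s0_sq"], rtol=1e-12)
        Xv = X.to_numpy()
        h = np.linalg.inv(Xv.T @ Xv)
        b = h @ Xv.T @ y0
        t_pooled = b[1] / np.sqrt(info["s0_sq"] * h[1, 1])
        np.testing.assert_allclose(table["t_mod"].to_numpy(), t_pooled, rtol=1e-10)

    def test_zero_prior_df_gives_ordinary_t(self):
        expr, X = _expr_fixture()
        table, info = moderated_lm(expr, X, "case", prior_df=0.0)
        Xv = X.to_numpy()
        h = np.linalg.inv(Xv.T @ Xv)
        for g in expr.index:
            y = expr.loc[g].to_numpy()
            b = h @ Xv.T @ y
            r = y - Xv @ b
            s2 = (r @ r) / (len(y) - 3)
            t_ord = b[1] / np.sqrt(s2 * h[1, 1])
            assert table.loc[g, "t_mod"] == pytest.approx(t_ord, rel=1e-12)

    def test_coefficients_equal_ols(self):
        expr, X = _expr_fixture(n_genes=20)
        table, _ = moderated_lm(expr, X, "case")
        import statsmodels.api as sm

        for g in list(expr.index)[:5]:
            ols = sm.OLS(expr.loc[g].to_numpy(), X.to_numpy()).fit()
            assert table.loc[g, "logfc"] == pytest.approx(ols.params[1], rel=1e-10)

    def test_rank_deficient_design_rejected(self):
        expr, X = _expr_fixture()
        X2 = X.copy()
        X2["dup"] = X2["case"]
        with pytest.raises(ValueError, match="rank deficient"):
            moderated_lm(expr, X2, "case")

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_limma(self, tmp_path):
        """Dual-route check against the reference empirical-Bayes
        implementation in Bioconductor limma."""
        expr, X = _expr_fixture(n_genes=40, n=12, seed=11)
        np.savetxt(tmp_path / "expr.tsv", expr.to_numpy(), delimiter="\t")
        np.savetxt(tmp_path / "design.tsv", X.to_numpy(), delimiter="\t")
        table, info = moderated_lm(expr, X, "case")
        script = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.table("{tmp_path}/expr.tsv"))
        X <- as.matrix(read.table("{tmp_path}/design.tsv"))
        fit <- eBayes(lmFit(y, X))
        write.table(data.frame(d0=fit$df.prior, s0=fit$s2.prior),
                    "{tmp_path}/prior.tsv", row.names=FALSE)
        write.table(fit$t[,2], "{tmp_path}/t.tsv", row.names=FALSE, col.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        prior = pd.read_csv(tmp_path / "prior.tsv", sep=" ")
        t_r = np.loadtxt(tmp_path / "t.tsv")
        assert info["d0"] == pytest.approx(prior["d0"][0], rel=1e-6)
        assert info["s0_sq"] == pytest.approx(prior["s0"][0], rel=1e-6)
        np.testing.assert_allclose(table["t_mod"].to_numpy(), t_r, rtol=1e-6)


class TestRunDEModels:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        meta = pd.DataFrame(
            {"case": np.repeat([0, 1], 30),
             "gestational_age": rng.normal(36, 2, n).clip(25, 43),
             "fetal_sex": rng.choice(["female", "male"], n),
             "study": [f"study{i % 2}" for i in range(n)]},
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
        expr = pd.DataFrame(rng.normal(8, 1, size=(30, n)),
                            index=[f"g{i}" for i in range(30)], columns=meta.index)
        return expr, meta

    def test_none_pcs_identity(self):
        expr, meta = self._cohort()
        tables, summary = run_de_models(expr, meta, pcs=None)
        pd.testing.assert_frame_equal(tables["base"], tables["celltype_adjusted"])

    def test_pc_adjustment_changes_df_not_genes(self):
        expr, meta = self._cohort()
        rng = np.random.default_rng(1)
        props = pd.DataFrame(rng.dirichlet(np.ones(7), size=len(meta)),
                             index=meta.index)
        pcs = proportion_pca(props)
        tables, summary = run_de_models(expr, meta, pcs)
        assert len(tables["base"]) == len(tables["celltype_adjusted"])
        assert summary["base"]["df_residual"] - summary["celltype_adjusted"]["df_residual"] == 5


def _brute_force_es(stats_sorted, hits, weight=1.0):
    """Direct evaluation of the running sum, independent of the library."""
    n = len(stats_sorted)
    nh = hits.sum()
    w = np.abs(stats_sorted) ** weight
    denom = w[hits].sum()
    running, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            running += w[i] / denom
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def test_es_matches_brute_force(self):
        """10-gene list with statistics 10..1, set = top two genes."""
        ranked = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        gene_set = {"g0", "g1"}
        es = enrichment_score(ranked, gene_set)
        hits = np.array([True, True] + [False] * 8)
        expected = _brute_force_es(ranked.to_numpy(), hits)
        assert es == pytest.approx(expected, abs=1e-12)

    def test_mirror_antisymmetry(self):
        """For an antisymmetric statistic vector, the ES of a set equals
        -ES of its mirrored-rank set."""
        vals = np.array([5.0, 4.0, 3.0, 1.0, -1.0, -3.0, -4.0, -5.0])
        ranked = pd.Series(vals, index=[f"g{i}" for i in range(8)])
        es_top = enrichment_score(ranked, {"g0", "g1"})
        es_bottom = enrichment_score(ranked, {"g6", "g7"})
        assert es_top == pytest.approx(-es_bottom, abs=1e-12)

    def test_perm_p_resolution(self):
        rng = np.random.default_rng(0)
        ranked = pd.Series(np.linspace(5, -5, 40), index=[f"g{i}" for i in range(40)])
        sets = {"top": {f"g{i}" for i in range(5)}}
        out = preranked_gsea(ranked, sets, n_permutations=99, seed=1)
        assert out.loc["top", "perm_p"] == pytest.approx(1.0 / 100.0)

    def test_skips_absent_set_with_warning(self):
        ranked = pd.Series(np.linspace(3, -3, 20), index=[f"g{i}" for i in range(20)])
        with pytest.warns(UserWarning, match="skipped"):
            out = preranked_gsea(ranked, {"absent": {"x", "y"}}, n_permutations=10, seed=0)
        assert len(out) == 0

    def test_planted_set_enriched(self):
        rng = np.random.default_rng(2)
        stats_ = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        planted = [f"g{i}" for i in range(15)]
        stats_[planted] += 3.0
        out = preranked_gsea(stats_, {"planted": set(planted),
                                      "random": {f"g{i}" for i in range(100, 115)}},
                             n_permutations=200, seed=3)
        assert out.loc["planted", "perm_p"] < 0.01
        assert out.loc["planted", "es"] > 0.5
        assert out.loc["random", "perm_p"] > 0.05
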