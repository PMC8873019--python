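"""Co-expression networks: bicor, soft threshold, modules, eigengenes,
genotype association, preservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cnvomics import network
from cnvomics.network import NetworkParams

from conftest import make_block_expression


class TestBicor:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(0, 1, 30)
        expr = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        C = network.bicor_matrix(expr)
        assert C.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert C.loc["a", "c"] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(C, C.T)

    def test_robust_to_gross_outlier(self, rng):
        """One contaminated pair moves bicor less than Pearson."""
        n = 60
        x = rng.normal(0, 1, n)
        y = 0.8 * x + 0.6 * rng.normal(0, 1, n)
        r_clean = np.corrcoef(x, y)[0, 1]
        xc, yc = x.copy(), y.copy()
        xc[0], yc[0] = 10.0, -10.0
        expr = pd.DataFrame([xc, yc], index=["x", "y"])
        b = network.bicor_matrix(expr).loc["x", "y"]
        p = np.corrcoef(xc, yc)[0, 1]
        assert abs(b - r_clean) < abs(p - r_clean)

    def test_constant_row_falls_back_with_warning(self, rng):
        expr = pd.DataFrame([rng.normal(0, 1, 20), np.ones(20)],
                            index=["a", "flat"])
        with pytest.warns(UserWarning, match="fallback"):
            C = network.bicor_matrix(expr)
        assert np.isfinite(C.to_numpy()).all()

    def test_needs_four_samples(self, rng):
        with pytest.raises(ValueError):
            network.bicor_matrix(pd.DataFrame(rng.normal(0, 1, (5, 3))))


class TestSoftThreshold:
    def test_power_law_degrees_fit_well(self, rng):
        # k from a truncated Pareto (exponent 2.5): near-perfect fit index
        k = 100 * rng.uniform(0.02, 1, 5000) ** (-1 / 2.5)
        fit = network.scale_free_fit(k)
        assert fit > 0.95

    def test_scan_matches_per_power_recomputation(self, rng):
        expr, _ = make_block_expression(n_blocks=2, block_size=40,
                                        n_noise=40, n_samples=20, seed=8)
        powers = (2, 4, 6)
        beta, table = network.pick_soft_threshold(expr, powers, r2_min=2.0)
        C = network.correlation_matrix(expr, "bicor").to_numpy()
        for i, b in enumerate(powers):
            A = network.signed_adjacency(C, b)
            np.fill_diagonal(A, 0.0)
            assert table["fit_index"].iloc[i] == pytest.approx(
                network.scale_free_fit(A.sum(axis=1)), abs=1e-12)

    def test_fallback_when_no_power_reaches_target(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (60, 10)))
        with pytest.warns(UserWarning, match="best power"):
            beta, table = network.pick_soft_threshold(expr, (1, 2),
                                                      r2_min=0.999)
        assert beta in (1, 2)

    def test_adjacency_bounds(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (30, 12)))
        A = network.signed_adjacency(
            network.correlation_matrix(expr, "bicor"), 6)
        assert (A >= 0).all() and (A <= 1).all()


class TestTom:
    def test_range_and_diagonal(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (40, 15)))
        A = network.signed_adjacency(
            network.correlation_matrix(expr, "pearson"), 4)
        T = network.tom_matrix(A)
        assert (T >= 0).all() and (T <= 1).all()
        np.testing.assert_allclose(np.diag(T), 1.0)


class TestModuleDetection:
    @pytest.fixture(scope="class")
    def planted(self):
        expr, truth = make_block_expression(seed=3)
        res = network.CoexpressionNetwork(
            expr, NetworkParams(power=6, min_module_size=30)).fit()
        return expr, truth, res

    def test_planted_blocks_recovered(self, planted):
        _, truth, res = planted
        lab = res.labels.to_numpy()
        assigned = lab != network.GREY
        ari = adjusted_rand_score(truth[assigned], lab[assigned])
        assert ari >= 0.8
        assert (lab[truth == "noise"] == network.GREY).mean() >= 0.8

    def test_min_module_size_enforced(self, planted):
        _, _, res = planted
        sizes = res.labels.value_counts().drop(network.GREY, errors="ignore")
        assert (sizes >= 30).all()

    def test_sample_permutation_invariance(self, planted):
        expr, _, res = planted
        perm = expr.iloc[:, np.random.default_rng(1).permutation(expr.shape[1])]
        res2 = network.CoexpressionNetwork(
            perm, NetworkParams(power=6, min_module_size=30)).fit()
        pd.testing.assert_series_equal(res.labels, res2.labels)

    def test_highly_correlated_blocks_merge(self):
        rng = np.random.default_rng(9)
        n_s = 40
        f = rng.normal(0, 1, n_s)
        f2 = 0.95 * f + np.sqrt(1 - 0.95 ** 2) * rng.normal(0, 1, n_s)
        X1 = np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(0, 1, (80, n_s))
        X2 = np.sqrt(0.8) * f2 + np.sqrt(0.2) * rng.normal(0, 1, (80, n_s))
        expr = pd.DataFrame(np.vstack([X1, X2, rng.normal(0, 1, (100, n_s))]))
        res = network.CoexpressionNetwork(
            expr, NetworkParams(power=6, min_module_size=30)).fit()
        planted = res.labels.iloc[:160]
        # the two driver factors correlate at 0.95 -> dissimilarity 0.05
        # is below the 0.1 merge cut, leaving a single merged module
        assert planted.nunique() == 1 and planted.iloc[0] != network.GREY

    def test_too_few_genes_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (20, 10)))
        with pytest.raises(ValueError):
            network.CoexpressionNetwork(expr,
                                        NetworkParams(min_module_size=30))


class TestEigengenes:
    def test_single_member_module_kme_one(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (3, 20)),
                            index=["a", "b", "c"])
        labels = pd.Series({"a": "M1", "b": network.GREY, "c": network.GREY})
        me, kme = network.module_eigengene_kme(expr, labels)
        assert kme.loc["a", "M1"] == pytest.approx(1.0, abs=1e-9)

    def test_latent_factor_recovered(self, rng):
        f = rng.normal(0, 1, 30)
        X = np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(0, 1, (60, 30))
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(60)])
        labels = pd.Series("M1", index=expr.index)
        me, _ = network.module_eigengene_kme(expr, labels)
        assert abs(np.corrcoef(me["M1"], f)[0, 1]) >= 0.9

    def test_sign_flip_symmetry(self, rng):
        f = rng.normal(0, 1, 25)
        X = np.sqrt(0.7) * f + np.sqrt(0.3) * rng.normal(0, 1, (40, 25))
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(40)])
        labels = pd.Series("M1", index=expr.index)
        me1, kme1 = network.module_eigengene_kme(expr, labels)
        me2, kme2 = network.module_eigengene_kme(-expr, labels)
        np.testing.assert_allclose(np.abs(kme1), np.abs(kme2), atol=1e-9)

    def test_eigengene_unit_norm_and_orientation(self, rng):
        expr, _ = make_block_expression(n_blocks=1, block_size=50,
                                        n_noise=0, n_samples=20, seed=4)
        labels = pd.Series("M1", index=expr.index)
        me, kme = network.module_eigengene_kme(expr, labels)
        assert np.linalg.norm(me["M1"]) == pytest.approx(1.0)
        assert kme.loc[labels == "M1", "M1"].mean() > 0


class TestGenotypeAssociation:
    def test_dosage_coded_eigengene(self, rna_1m, rng):
        dose = np.where(rna_1m["genotype"] == "DEL", -1.0,
                        np.where(rna_1m["genotype"] == "DUP", 1.0, 0.0))
        me = pd.DataFrame({"M1": dose + rng.normal(0, 0.1, len(rna_1m))},
                          index=rna_1m["sample_id"])
        out = network.eigengene_genotype_association(me, rna_1m)
        res = out.set_index("contrast")
        assert res.loc["DEL_vs_CTRL", "q"] < 0.05
        assert res.loc["DUP_vs_CTRL", "q"] < 0.05
        assert np.sign(res.loc["DEL_vs_CTRL", "effect"]) == -1
        assert np.sign(res.loc["DUP_vs_CTRL", "effect"]) == 1

    def test_constant_eigengene(self, rna_1m):
        me = pd.DataFrame({"M1": np.ones(len(rna_1m))},
                          index=rna_1m["sample_id"])
        out = network.eigengene_genotype_association(me, rna_1m)
        assert (out["effect"] == 0).all() and (out["p"] == 1).all()

    def test_pseudoreplication_controlled(self, rna_1m):
        """Eigengenes driven only by individual effects: the mixed model
        keeps type-I error near nominal while sample-level OLS, which
        treats clones/replicates as independent, is badly inflated."""
        rng = np.random.default_rng(0)
        ind = rna_1m["individual"].to_numpy()
        levels = rna_1m["individual"].unique()
        geno = rna_1m["genotype"].to_numpy()
        lmm = ols = 0
        n_sim = 60
        for _ in range(n_sim):
            b = dict(zip(levels, rng.normal(0, 1, len(levels))))
            y = np.array([b[i] for i in ind]) + rng.normal(0, 0.3, len(ind))
            me = pd.DataFrame({"M": y}, index=rna_1m["sample_id"])
            out = network.eigengene_genotype_association(me, rna_1m)
            lmm += out.set_index("contrast").loc["DEL_vs_CTRL", "p"] < 0.05
            ols += stats.ttest_ind(y[geno == "DEL"],
                                   y[geno == "CTRL"]).pvalue < 0.05
        assert lmm / n_sim <= 0.10
        assert ols / n_sim > 0.10


class TestPreservation:
    @pytest.fixture(scope="class")
    def fitted(self):
        expr, truth = make_block_expression(seed=5)
        res = network.CoexpressionNetwork(
            expr, NetworkParams(power=6, min_module_size=30)).fit()
        return expr, res

    def test_self_preservation_strong(self, fitted):
        expr, res = fitted
        pres = network.module_preservation(expr, res.labels, expr,
                                           power=6, n_perm=50, seed=1)
        assert (pres["z_summary"] > 10).all()

    def test_label_permutation_destroys_preservation(self, fitted):
        expr, res = fitted
        perm = expr.copy()
        perm.index = np.random.default_rng(2).permutation(expr.index)
        pres = network.module_preservation(expr, res.labels, perm,
                                           power=6, n_perm=50, seed=1)
        assert (pres["z_summary"].abs() < 2).all()

    def test_uncorrelated_module_not_preserved(self, rng):
        expr, _ = make_block_expression(n_blocks=1, block_size=60,
                                        n_noise=140, n_samples=30, seed=6)
        labels = pd.Series(network.GREY, index=expr.index)
        labels.iloc[100:150] = "Mnull"  # a module of pure-noise genes
        pres = network.module_preservation(expr, labels, expr,
                                           power=6, n_perm=50, seed=2)
        assert abs(pres["z_summary"].iloc[0]) < 3

    def test_monotone_in_planted_correlation(self):
        """Two layers sharing the same hub structure (per-gene loadings)
        but independent samples: the preservation Z-summary rises with
        the planted intra-module correlation."""
        rng = np.random.default_rng(7)
        m, n_noise, n_s = 30, 470, 60
        u = rng.uniform(0.4, 1.0, m)  # shared hub loadings

        def layer(icor, r):
            lam = np.sqrt(icor) * u
            f = r.normal(0, 1, n_s)
            block = (lam[:, None] * f
                     + np.sqrt(1 - lam ** 2)[:, None] * r.normal(0, 1, (m, n_s)))
            noise = r.normal(0, 1, (n_noise, n_s))
            return pd.DataFrame(np.vstack([block, noise]),
                                index=[f"g{i}" for i in range(m + n_noise)])

        zs = []
        for icor in (0.3, 0.5, 0.7):
            ref = layer(icor, np.random.default_rng(8))
            test = layer(icor, np.random.default_rng(9))
            labels = pd.Series(network.GREY, index=ref.index)
            labels.iloc[:m] = "M1"
            pres = network.module_preservation(ref, labels, test,
                                               power=6, n_perm=100, seed=3)
            zs.append(pres["z_summary"].iloc[0])
        assert zs[0] < zs[1] < zs[2]

    def test_small_shared_module_skipped(self, fitted, rng):
        expr, res = fitted
        test = expr.iloc[:50]  # most module genes absent from test layer
        labels = pd.Series(network.GREY, index=expr.index)
        labels.iloc[48:120] = "M1"  # only 2 genes shared with test
        with pytest.warns(UserWarning, match="skipped"):
            pres = network.module_preservation(expr, labels,
                                               test.iloc[:, :20],
                                               power=6, n_perm=10, seed=4)
        assert pres.empty


class TestRegressCovariates:
    def test_covariate_signal_removed(self, rng):
        n = 30
        cov = rng.normal(0, 1, n)
        expr = pd.DataFrame(np.outer(rng.normal(0, 1, 50), cov)
                            + rng.normal(0, 0.1, (50, n)))
        resid = network.regress_covariates(expr, cov)
        cors = [abs(np.corrcoef(resid.iloc[g], cov)[0, 1]) for g in range(50)]
        assert max(cors) < 0.1


class TestPresets:
    def test_study_presets_recorded(self):
        assert network.PRESETS["org1M"].power == 16
        assert network.PRESETS["org1M"].min_module_size == 50
        assert network.PRESETS["iPSC"].power == 14
        assert network.PRESETS["org3M"].power == 19
        assert network.PRESETS["protein_org1M"].min_module_size == 40
        p = NetworkParams(merge_cut_height=0.1)
        assert p.merge_cut_height == 0.1
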