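"""Unit tests for the co-expression network workflow."""

import numpy as np
import pandas as pd
import pytest
from _oracles import t_two_sided_p

from plaquekit.coexpr import (
    UNASSIGNED,
    adjacency,
    detect_modules,
    eigengene_phenotype_correlation,
    gene_significance,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    remove_covariates,
    select_hubs,
    tom_similarity,
)


def _expr_from_blocks(latents, sizes, noise_sd=0.05, n=40, seed=0, loadings=None):
    """Block-structured expression: each block driven by one latent vector."""
    rng = np.random.default_rng(seed)
    rows = []
    for latent, size in zip(latents, sizes):
        load = loadings if loadings is not None else np.ones(size)
        rows.append(np.outer(load, latent) + rng.normal(0, noise_sd, (size, n)))
    X = np.vstack(rows)
    genes = [f"G{i:04d}" for i in range(X.shape[0])]
    samples = [f"S{j:03d}" for j in range(n)]
    return pd.DataFrame(X, index=genes, columns=samples)


class TestAdjacency:
    def test_beta_one_equals_absolute_correlation(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(5, 20)))
        a = adjacency(expr, beta=1.0).to_numpy()
        r = np.abs(np.corrcoef(expr.to_numpy()))
        np.testing.assert_allclose(a, r, atol=1e-12)

    def test_perfect_correlation_stays_one(self):
        base = np.linspace(0, 1, 10)
        expr = pd.DataFrame([base, 2 * base + 1])
        a = adjacency(expr, beta=10.0)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_soft_threshold_power(self):
        # construct two genes with exact correlation 0.5
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        y = np.array([1.0, -1, 1, -1, -1, 1, -1, 1])  # r = 0
        z = (x + np.sqrt(3) * y) / 2  # corr(x, z) = 0.5
        expr = pd.DataFrame([x, z])
        a = adjacency(expr, beta=10.0)
        assert a.iloc[0, 1] == pytest.approx(0.5**10, rel=1e-9)

    def test_zero_variance_gene_is_an_error(self):
        expr = pd.DataFrame([[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            adjacency(expr)


class TestTom:
    def test_two_gene_network_equals_adjacency(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.3)

    def test_complete_unit_graph_is_all_ones(self):
        a = np.ones((5, 5))
        assert np.allclose(tom_similarity(a), 1.0)

    def test_three_gene_hand_evaluation(self):
        a = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, 0.4], [0.6, 0.4, 1.0]])
        tom = tom_similarity(a)
        # TOM_12 = (a13*a23 + a12) / (min(k1, k2) + 1 - a12)
        k1, k2 = 0.8 + 0.6, 0.8 + 0.4
        expected = (0.6 * 0.4 + 0.8) / (min(k1, k2) + 1 - 0.8)
        assert tom[0, 1] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_range_and_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j)) + a[i, j]
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expected = num / (min(k_i, k_j) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(min(expected, 1.0), rel=1e-10)


class TestEigengene:
    def test_identical_genes_give_positively_signed_profile(self):
        latent = np.sin(np.linspace(0, 3, 30))
        expr = _expr_from_blocks([latent], [6], noise_sd=0.0, n=30)
        e = module_eigengene(expr, list(expr.index))
        z = (latent - latent.mean()) / latent.std()
        r = np.corrcoef(e, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_sign_alignment_is_idempotent_under_global_flip(self):
        latent = np.cos(np.linspace(0, 4, 25))
        expr = _expr_from_blocks([latent], [5], noise_sd=0.01, n=25, seed=3)
        e1 = module_eigengene(expr, list(expr.index))
        e2 = module_eigengene(-expr, list(expr.index))
        # flipping every gene flips the mean profile too, so orientation flips with it
        np.testing.assert_allclose(e2.to_numpy(), -e1.to_numpy(), atol=1e-9)


class TestDetectModules:
    def test_two_orthogonal_blocks_recovered_exactly(self):
        rng = np.random.default_rng(1)
        l1, l2 = rng.standard_normal((2, 40))
        expr = _expr_from_blocks([l1, l2], [50, 50], noise_sd=0.2, n=40, seed=2)
        adj = adjacency(expr, beta=6.0)
        tom = tom_similarity(adj)
        res = detect_modules(tom, expr, min_size=44, merge_cut=0.25)
        assert sorted(res.labels.unique()) == ["M1", "M2"]
        first_block = res.labels.iloc[:50]
        assert first_block.nunique() == 1
        assert res.labels.iloc[50:].nunique() == 1
        assert first_block.iloc[0] != res.labels.iloc[50]

    def test_min_size_larger_than_any_cluster_unassigns_all(self):
        rng = np.random.default_rng(4)
        l1 = rng.standard_normal(30)
        expr = _expr_from_blocks([l1], [10], noise_sd=0.2, n=30)
        tom = tom_similarity(adjacency(expr, beta=6.0))
        with pytest.warns(UserWarning, match="unassigned"):
            res = detect_modules(tom, expr, min_size=20)
        assert (res.labels == UNASSIGNED).all()

    def test_modules_sharing_a_latent_are_merged(self):
        rng = np.random.default_rng(5)
        shared = rng.standard_normal(40)
        l1 = shared + rng.normal(0, 0.4, 40)  # eigengene corr ≈ 0.8 > 0.75
        l2 = shared + rng.normal(0, 0.4, 40)
        expr = _expr_from_blocks([l1, l2], [15, 15], noise_sd=0.1, n=40, seed=6)
        tom = tom_similarity(adjacency(expr, beta=6.0))
        res = detect_modules(tom, expr, min_size=10, merge_cut=0.25, cut_height=0.35)
        assert len(res.modules) == 1
        assert len(res.merge_history) == 1

    def test_labels_invariant_to_gene_order(self):
        rng = np.random.default_rng(7)
        l1, l2 = rng.standard_normal((2, 40))
        expr = _expr_from_blocks([l1, l2], [20, 20], noise_sd=0.1, n=40, seed=8)
        tom = tom_similarity(adjacency(expr, beta=6.0))
        res = detect_modules(tom, expr, min_size=10)
        perm = rng.permutation(len(expr))
        expr_p = expr.iloc[perm]
        tom_p = tom_similarity(adjacency(expr_p, beta=6.0))
        res_p = detect_modules(tom_p, expr_p, min_size=10)
        joined = pd.crosstab(res.labels, res_p.labels.loc[res.labels.index])
        # permutation of genes only renames modules: one nonzero cell per row
        assert ((joined > 0).sum(axis=1) == 1).all()


class TestCorrelationTables:
    def test_trait_equal_to_eigengene_gives_unit_r(self):
        e = pd.Series(np.linspace(-1, 1, 12), index=[f"S{i}" for i in range(12)])
        eig = pd.DataFrame({"M1": e})
        traits = pd.DataFrame({"t": e * 3 + 1})
        out = module_trait_correlation(eig, traits)
        assert out.loc[("M1", "t"), "r"] == pytest.approx(1.0)

    def test_orthogonal_trait_gives_zero_r(self):
        n = 20
        e = pd.Series(np.sin(np.arange(n)), index=range(n))
        t = pd.Series(np.ones(n), index=range(n))
        t.iloc[::2] = -1
        t -= t.mean()
        e_orth = e - (e @ t) / (t @ t) * t
        out = module_trait_correlation(pd.DataFrame({"M1": e_orth}), pd.DataFrame({"t": t}))
        assert abs(out.loc[("M1", "t"), "r"]) < 1e-12

    def test_p_value_matches_t_density_integration(self):
        rng = np.random.default_rng(2)
        n = 10
        x = rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        eig = pd.DataFrame({"M1": pd.Series(x, index=range(n))})
        traits = pd.DataFrame({"t": pd.Series(y, index=range(n))})
        out = module_trait_correlation(eig, traits)
        r = out.loc[("M1", "t"), "r"]
        t_stat = r * np.sqrt((n - 2) / (1 - r**2))
        assert out.loc[("M1", "t"), "p"] == pytest.approx(
            t_two_sided_p(t_stat, n - 2), rel=1e-9
        )

    def test_constant_trait_gives_missing(self):
        eig = pd.DataFrame({"M1": pd.Series(np.arange(5.0), index=range(5))})
        out = module_trait_correlation(eig, pd.DataFrame({"t": pd.Series(np.ones(5), index=range(5))}))
        assert np.isnan(out.loc[("M1", "t"), "r"])


class TestGsMmHubs:
    def test_gene_equal_to_trait_has_unit_gs(self):
        x = np.linspace(0, 1, 15)
        expr = pd.DataFrame([x], index=["g"], columns=[f"S{i}" for i in range(15)])
        gs = gene_significance(expr, pd.Series(x, index=expr.columns))
        assert gs["g"] == pytest.approx(1.0)

    def test_planted_hub_has_high_mm(self):
        latent = np.random.default_rng(0).standard_normal(88)
        expr = _expr_from_blocks([latent], [20], noise_sd=0.1, n=88, seed=1)
        e = module_eigengene(expr, list(expr.index))
        mm = module_membership(expr, e)
        assert (mm > 0.9).all()

    def test_no_qualifying_genes_warns_and_returns_empty(self):
        genes = ["a", "b", "c"]
        gs = pd.Series([0.5, 0.5, 0.5], index=genes)
        mm = pd.Series([0.1, 0.2, 0.3], index=genes)
        adj = pd.DataFrame(np.eye(3), index=genes, columns=genes)
        with pytest.warns(UserWarning, match="0 genes"):
            hubs, edges = select_hubs(gs, mm, adj, genes)
        assert hubs == [] and edges.empty

    def test_top_n_selection_by_mm(self):
        genes = [f"g{i}" for i in range(8)]
        gs = pd.Series(0.5, index=genes)
        mm = pd.Series(np.linspace(0.99, 0.82, 8), index=genes)
        adj = pd.DataFrame(0.5, index=genes, columns=genes)
        hubs, edges = select_hubs(gs, mm, adj, genes, top_n=5)
        assert hubs == genes[:5]
        assert set(edges["source"]) == set(genes[:5])
        hubs1, _ = select_hubs(gs, mm, adj, genes, top_n=1)
        assert hubs1 == ["g0"]


class TestRemoveCovariates:
    def test_exact_removal_of_planted_batch_shift(self):
        n = 20
        ann = pd.DataFrame(
            {"batch": ["b1"] * 10 + ["b2"] * 10, "trait": [0, 1] * 10},
            index=[f"S{i}" for i in range(n)],
        )
        flat = np.zeros(n)
        flat[10:] += 2.0  # pure batch effect
        expr = pd.DataFrame([flat], index=["g"], columns=ann.index)
        out = remove_covariates(expr, ann, unwanted=["batch"], retained=["trait"])
        assert np.allclose(out.loc["g"], out.loc["g"].iloc[0])

    def test_no_unwanted_covariates_is_identity(self):
        expr = pd.DataFrame(np.arange(8.0).reshape(2, 4), columns=list("abcd"))
        ann = pd.DataFrame({"batch": ["b1", "b1", "b2", "b2"]}, index=list("abcd"))
        out = remove_covariates(expr, ann, unwanted=[])
        assert out.equals(expr)

    def test_trait_signal_preserved_when_batch_removed(self):
        rng = np.random.default_rng(9)
        n = 60
        trait = np.repeat([0.0, 1.0], n // 2)
        batch = np.tile([0.0, 1.0], n // 2)
        ann = pd.DataFrame(
            {"batch": np.where(batch > 0, "b2", "b1"), "trait": trait},
            index=[f"S{i}" for i in range(n)],
        )
        gene = 2.0 * trait + 3.0 * batch + rng.normal(0, 0.1, n)
        expr = pd.DataFrame([gene], index=["g"], columns=ann.index)
        out = remove_covariates(expr, ann, unwanted=["batch"], retained=["trait"])
        cleaned = out.loc["g"].to_numpy()
        r_batch = np.corrcoef(cleaned, batch)[0, 1]
        r_trait = np.corrcoef(cleaned, trait)[0, 1]
        assert abs(r_batch) < 0.05
        assert r_trait > 0.95

    def test_collinear_design_error_names_aliased_columns(self):
        ann = pd.DataFrame(
            {"batch": ["b1", "b2", "b1", "b2"], "dup": ["b1", "b2", "b1", "b2"]},
            index=list("abcd"),
        )
        expr = pd.DataFrame(np.ones((1, 4)), index=["g"], columns=list("abcd"))
        with pytest.raises(ValueError, match="aliased"):
            remove_covariates(expr, ann, unwanted=["batch", "dup"])


class TestPhenotypeCorrelation:
    def test_affine_phenotype_gives_unit_r(self):
        idx = [f"S{i}" for i in range(9)]
        e = pd.Series(np.arange(9.0), index=idx)
        pheno = 2 * e + 5
        groups = pd.Series(["a"] * 5 + ["b"] * 4, index=idx)
        out = eigengene_phenotype_correlation(e, pheno, groups)
        assert out.loc["a", "r"] == pytest.approx(1.0)
        assert out.loc["b", "r"] == pytest.approx(1.0)

    def test_small_group_gives_missing_with_warning(self):
        idx = ["s1", "s2", "s3", "s4"]
        e = pd.Series([1.0, 2, 3, 4], index=idx)
        pheno = pd.Series([1.0, 2, np.nan, np.nan], index=idx)
        groups = pd.Series(["a", "a", "a", "a"], index=idx)
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = eigengene_phenotype_correlation(e, pheno, groups)
        assert np.isnan(out.loc["a", "r"])

    def test_constant_phenotype_gives_missing(self):
        idx = [f"S{i}" for i in range(6)]
        e = pd.Series(np.arange(6.0), index=idx)
        pheno = pd.Series(np.ones(6), index=idx)
        groups = pd.Series(["a"] * 6, index=idx)
        out = eigengene_phenotype_correlation(e, pheno, groups)
        assert np.isnan(out.loc["a", "r"])
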