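"""Signed network construction, TOM, clustering and merging behaviour."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.coexpression_network import scale_free_fit


def frame(rows, n_samples=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(rows,
                        index=[f"g{i}" for i in range(rows.shape[0])],
                        columns=[f"s{j}" for j in range(rows.shape[1])])


class TestCorrelationMatrix:
    def test_duplicate_gene_correlates_perfectly(self):
        values = frame([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert cx.correlation_matrix(values).iloc[0, 1] == pytest.approx(1.0)

    def test_negated_gene_anticorrelates(self):
        values = frame([[1, 2, 3, 4], [-1, -2, -3, -4]])
        assert cx.correlation_matrix(values).iloc[0, 1] == pytest.approx(-1.0)

    def test_closed_form_pearson(self):
        values = frame([[1, 2, 3, 4], [1, 2, 3, 5]])
        # cov = 6.5/..., r = 6.5 / sqrt(5 * 8.75)
        expected = 6.5 / math.sqrt(5 * 8.75)
        assert cx.correlation_matrix(values).iloc[0, 1] == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.9827, abs=5e-5)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            cx.correlation_matrix(frame([[1, 2], [3, 4]]))

    def test_zero_variance_gene_warns_and_gets_zero(self):
        values = frame([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            cor = cx.correlation_matrix(values)
        assert cor.iloc[0, 1] == 0.0
        assert cor.iloc[0, 0] == 1.0


class TestSignedAdjacency:
    def test_printed_value_at_published_softpower(self):
        adj = cx.signed_adjacency(0.8, 26)
        assert math.floor(adj * 1000) / 1000 == 0.064

    def test_endpoints(self):
        assert cx.signed_adjacency(1.0, 26) == pytest.approx(1.0)
        assert cx.signed_adjacency(-1.0, 26) == pytest.approx(0.0)

    def test_zero_correlation_squared(self):
        assert cx.signed_adjacency(0.0, 2) == pytest.approx(0.25)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            cx.signed_adjacency(0.5, 0)

    def test_monotone_in_correlation(self):
        cors = np.linspace(-1, 1, 41)
        adj = cx.signed_adjacency(cors, 7)
        assert (np.diff(adj) > 0).all()
        assert ((adj >= 0) & (adj <= 1)).all()


class TestSoftThreshold:
    def test_exact_power_law_connectivity_fits_well(self):
        # frequency(k) ~ k^-1.5 on a discrete grid is a perfect log-log line
        ks = np.concatenate([
            np.full(int(round(1000 * k ** -1.5)), float(k))
            for k in [1, 2, 4, 8, 16, 32]
        ])
        assert scale_free_fit(ks) >= 0.9

    def test_identical_genes_degenerate(self):
        values = frame(np.tile([[1, 2, 3, 4, 5]], (6, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            cx.pick_soft_threshold(values, betas=[2])

    def test_mean_connectivity_non_increasing_in_beta(self, pipeline_run):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cx.pick_soft_threshold(
                pipeline_run.log_values.iloc[:200], betas=range(1, 11))
        mk = fit.table["mean_connectivity"].to_numpy()
        assert (np.diff(mk) <= 1e-9).all()

    def test_chosen_beta_is_smallest_reaching_target(self):
        rng = np.random.default_rng(0)
        values = frame(rng.normal(size=(80, 10)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cx.pick_soft_threshold(values, betas=range(1, 13),
                                         target_r2=0.5)
        ok = fit.table[fit.table.signed_r2 >= 0.5]
        if len(ok):
            assert fit.chosen_beta == ok.beta.iloc[0]
        else:
            assert fit.chosen_beta == int(
                fit.table.loc[fit.table.signed_r2.idxmax(), "beta"])


class TestTom:
    def test_three_node_hand_example(self):
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 0.0)
        tom = cx.tom_matrix(adj)
        # l_12 = 0.25, k = 1 each: (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)
        assert (np.diag(tom) == 1).all()

    def test_perfect_overlap_reaches_one(self):
        # two nodes joined at full weight sharing all neighbours at full weight
        n = 5
        adj = np.zeros((n, n))
        adj[0, 1] = adj[1, 0] = 1.0
        for u in range(2, n):
            adj[0, u] = adj[u, 0] = 1.0
            adj[1, u] = adj[u, 1] = 1.0
        assert cx.tom_matrix(adj)[0, 1] == pytest.approx(1.0)

    def test_isolated_pair_is_zero(self):
        adj = np.zeros((4, 4))
        assert cx.tom_matrix(adj)[0, 1] == 0.0

    def test_out_of_range_adjacency_rejected(self):
        adj = np.full((3, 3), 1.5)
        with pytest.raises(ValueError):
            cx.tom_matrix(adj)

    def test_symmetric_and_bounded_on_random_input(self):
        rng = np.random.default_rng(1)
        a = rng.random((30, 30))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = cx.tom_matrix(a)
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1


def block_tom(sizes, within=0.9, between=0.0):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    return tom


class TestClusterAndCut:
    def test_two_separated_blocks_give_two_modules(self):
        part = cx.cluster_and_cut(block_tom([40, 35]), min_size=30,
                                  cut_height=0.5)
        assert len(part.modules) == 2
        assert sorted(part.module_sizes) == [35, 40]

    def test_small_block_goes_to_background(self):
        part = cx.cluster_and_cut(block_tom([40, 10]), min_size=30,
                                  cut_height=0.5)
        assert len(part.modules) == 1
        assert (part.module_of_gene == "background").sum() == 10

    def test_identity_tom_yields_no_modules(self):
        tom = np.eye(50)
        part = cx.cluster_and_cut(tom, min_size=30)
        assert part.modules == []

    def test_invalid_cut_height_rejected(self):
        with pytest.raises(ValueError):
            cx.cluster_and_cut(block_tom([40, 35]), cut_height=1.5)

    def test_deterministic(self):
        tom = block_tom([40, 35], within=0.8)
        a = cx.cluster_and_cut(tom, cut_height=0.6)
        b = cx.cluster_and_cut(tom, cut_height=0.6)
        pd.testing.assert_series_equal(a.module_of_gene, b.module_of_gene)


class TestEigengene:
    def test_rank_one_module(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        values = frame(np.tile(profile, (6, 1)))
        eig, varexp = cx.module_eigengene(values, list(values.index))
        assert varexp == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert np.corrcoef(eig, z)[0, 1] == pytest.approx(1.0)

    def test_orientation_keeps_mean_gene_correlation_positive(self):
        rng = np.random.default_rng(2)
        values = frame(rng.normal(size=(10, 8)))
        eig, _ = cx.module_eigengene(values, list(values.index))
        flipped, _ = cx.module_eigengene(-values, list(values.index))
        cors = [np.corrcoef(values.loc[g], eig)[0, 1] for g in values.index]
        assert np.mean(cors) > 0
        assert np.allclose(flipped, -eig)

    def test_recovers_latent_profile_at_low_noise(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=12)
        load = rng.uniform(0.8, 1.2, size=40)
        noise = 0.1 * rng.normal(size=(40, 12))
        values = frame(np.outer(load, latent) + noise)
        eig, _ = cx.module_eigengene(values, list(values.index))
        assert abs(np.corrcoef(eig, latent)[0, 1]) >= 0.95

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            cx.module_eigengene(frame([[1, 2, 3]]), [])


def two_module_expr(cor_between, n_per_module=10, n_samples=40, seed=4):
    """Expression with two noiseless modules whose profiles correlate at
    exactly ``cor_between``."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n_samples)
    w = rng.normal(size=n_samples)
    u = (u - u.mean()) / u.std()
    w = w - w.mean()
    w -= u * (u @ w) / (u @ u)  # orthogonalise
    w /= w.std()
    v = cor_between * u + math.sqrt(1 - cor_between**2) * w
    rows = [u * s for s in np.linspace(1, 2, n_per_module)]
    rows += [v * s for s in np.linspace(1, 2, n_per_module)]
    values = frame(rows)
    labels = ["A"] * n_per_module + ["B"] * n_per_module
    part = cx.ModulePartition(
        module_of_gene=pd.Series(labels, index=values.index))
    return values, part


class TestMergeModules:
    def test_similar_modules_merge(self):
        values, part = two_module_expr(0.9)
        merged = cx.merge_modules(values, part, merge_threshold=0.15)
        assert len(merged.modules) == 1
        assert merged.merge_history

    def test_dissimilar_modules_stay(self):
        values, part = two_module_expr(0.8)
        merged = cx.merge_modules(values, part, merge_threshold=0.15)
        assert len(merged.modules) == 2

    def test_threshold_comparison_is_strict(self):
        values, part = two_module_expr(0.8)
        eigs, _ = cx.coexpression_network._compute_eigengenes(values, part)
        diss = 1.0 - np.corrcoef(eigs.to_numpy().T)[0, 1]
        at = cx.merge_modules(values, part, merge_threshold=diss)
        above = cx.merge_modules(values, part, merge_threshold=diss + 1e-9)
        assert len(at.modules) == 2  # strictly-below rule: no merge at equality
        assert len(above.modules) == 1

    def test_merged_label_from_larger_module(self):
        values, part = two_module_expr(0.95)
        bigger = part.module_of_gene.copy()
        bigger.iloc[0] = "B"  # B now has 11 genes, A has 9
        part = cx.ModulePartition(module_of_gene=bigger)
        merged = cx.merge_modules(values, part)
        assert merged.modules == ["B"]


class TestExportEdges:
    def make(self):
        genes = ["a", "b", "c", "d"]
        cor = pd.DataFrame(np.eye(4), index=genes, columns=genes)
        cor.loc["a", "b"] = cor.loc["b", "a"] = 0.8  # boundary, excluded
        cor.loc["a", "c"] = cor.loc["c", "a"] = -0.85
        cor.loc["b", "d"] = cor.loc["d", "b"] = 0.95  # cross-module
        part = cx.ModulePartition(module_of_gene=pd.Series(
            {"a": "M1", "b": "M1", "c": "M1", "d": "M2"}))
        return cor, part

    def test_threshold_strict_absolute_and_within_module(self):
        cor, part = self.make()
        edges = cx.export_edges(cor, part, cor_cutoff=0.8, beta=26)
        pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert pairs == {("a", "c")}
        assert edges.iloc[0]["cor"] == pytest.approx(-0.85)
        assert edges.iloc[0]["adj"] == pytest.approx(
            cx.signed_adjacency(-0.85, 26))

    def test_each_pair_once_no_self_edges(self, pipeline_run):
        edges = pipeline_run.edges
        assert (edges.gene_a != edges.gene_b).all()
        keys = list(zip(edges.gene_a, edges.gene_b))
        assert len(keys) == len(set(frozenset(k) for k in keys))
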