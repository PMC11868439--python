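"""Frequency tables, correlation distance, ward.D linkage, module markers."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from lpcmod.modules import (cluster_frequency_table, cut_modules,
                            fraction_expressing, frequency_correlation,
                            module_markers, ward_d_linkage)
from lpcmod.simulate import CohortSimConfig, simulate_frequency_table

from conftest import make_adata


# ---------------------------------------------------------------------------
# independent brute-force linkage oracle (dict-based, recomputed per merge)
# ---------------------------------------------------------------------------

def bruteforce_ward_d(D):
    """Reference agglomeration: explicit cluster dict + pairwise recurrence."""
    D = np.asarray(D, dtype=float)
    D = (D + D.T) / 2
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    node = {i: i for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = min(dist, key=lambda ij: (dist[ij], min(clusters[ij[0]]),
                                         min(clusters[ij[1]])))
        i, j = best
        h = dist[best]
        merges.append((node[i], node[j], h, len(clusters[i]) + len(clusters[j])))
        ni, nj = len(clusters[i]), len(clusters[j])
        new_dist = {}
        for (a, b), d_ab in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = d_ab
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = len(clusters[k])
            d_ki = dist[tuple(sorted((k, i)))]
            d_kj = dist[tuple(sorted((k, j)))]
            d_new = ((ni + nk) * d_ki + (nj + nk) * d_kj - nk * h) / (ni + nj + nk)
            new_dist[tuple(sorted((k, i)))] = d_new
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
        node[i] = n + step
        dist = new_dist
    return merges


def random_dissimilarity(rng, n):
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestFrequencyTable:
    def test_single_unit_proportions(self):
        freq = cluster_frequency_table(["A", "A", "B", "B", "B"], ["u"] * 5)
        assert freq.loc["A", "u"] == pytest.approx(0.4)
        assert freq.loc["B", "u"] == pytest.approx(0.6)

    def test_columns_sum_to_one(self, default_cohort):
        adata, _ = default_cohort
        freq = cluster_frequency_table(adata.obs["cluster"], adata.obs["individual"])
        assert np.allclose(freq.sum(axis=0), 1.0, atol=1e-12)

    def test_agrees_with_generator_truth_within_sampling_error(self, default_cohort):
        adata, truth = default_cohort
        freq = cluster_frequency_table(adata.obs["true_type"], adata.obs["individual"])
        n = adata.obs.groupby("individual", observed=True).size()
        for t in freq.index:
            obs = freq.loc[t]
            exp = truth[t].reindex(obs.index)
            # realised proportions ARE the truth table here (same draw), so
            # the reconstruction from per-cell labels is exact
            assert np.allclose(obs, exp, atol=1e-12)


class TestCorrelation:
    def test_identical_rows_have_zero_distance(self):
        freq = pd.DataFrame([[0.2, 0.4, 0.3], [0.2, 0.4, 0.3], [0.6, 0.2, 0.4]],
                            index=list("ABC"))
        corr, dist = frequency_correlation(freq)
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert dist.loc["A", "B"] == pytest.approx(0.0)

    def test_two_cluster_composition_is_perfectly_anticorrelated(self):
        x = np.array([0.1, 0.5, 0.9])
        freq = pd.DataFrame([x, 1 - x], index=["A", "B"])
        corr, dist = frequency_correlation(freq)
        assert corr.loc["A", "B"] == pytest.approx(-1.0)
        assert dist.loc["A", "B"] == pytest.approx(2.0)

    def test_zero_variance_row_maps_to_zero_correlation(self):
        freq = pd.DataFrame([[0.5, 0.5, 0.5], [0.2, 0.3, 0.4], [0.3, 0.2, 0.1]],
                            index=list("ABC"))
        corr, _ = frequency_correlation(freq)
        assert corr.loc["A", "B"] == 0.0
        assert corr.loc["A", "A"] == 1.0

    def test_needs_three_units(self):
        with pytest.raises(ValueError, match="3 sample units"):
            frequency_correlation(pd.DataFrame([[0.5, 0.5], [0.5, 0.5]]))

    def test_planted_modules_correlate_within(self, rng):
        from lpcmod.simulate import CellTypeSpec
        types = [CellTypeSpec(n) for n in "ABCD"]
        cfg = CohortSimConfig(
            n_individuals=42, conditions={"HL": 42}, cell_types=types,
            baseline_freqs={n: 0.25 for n in "ABCD"},
            module_loadings={"A": (1.0, 0.0), "B": (1.0, 0.0),
                             "C": (0.0, 1.0), "D": (0.0, 1.0)},
            cells_per_individual=1000, seed=2)
        freq = simulate_frequency_table(cfg)
        corr, _ = frequency_correlation(freq)
        within = np.mean([corr.loc["A", "B"], corr.loc["C", "D"]])
        between = np.mean([corr.loc["A", "C"], corr.loc["A", "D"],
                           corr.loc["B", "C"], corr.loc["B", "D"]])
        assert within > between


class TestWardLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        tree = ward_d_linkage(D)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.3)

    def test_four_leaf_block_structure(self):
        """Two tight pairs merge first; the cross merge joins the blocks."""
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        D[2, 3] = D[3, 2] = 0.1
        tree = ward_d_linkage(D)
        first_two = {frozenset(map(int, m[:2])) for m in tree.merges[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        assert tree.merges[0, 2] == pytest.approx(0.1)
        assert tree.merges[2, 2] > 1.0  # block join is farther than any leaf pair

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            D = random_dissimilarity(rng, n)
            tree = ward_d_linkage(D)
            oracle = bruteforce_ward_d(D)
            for mine, ref in zip(tree.merges, oracle):
                assert {int(mine[0]), int(mine[1])} == {ref[0], ref[1]}
                assert mine[2] == pytest.approx(ref[2], abs=1e-10)
                assert mine[3] == ref[3]

    def test_matches_r_hclust_ward_d(self, tmp_path):
        """Merge heights agree with R's hclust(method='ward.D')."""
        rng = np.random.default_rng(123)
        D = random_dissimilarity(rng, 9)
        tree = ward_d_linkage(D)
        mat = tmp_path / "d.txt"
        np.savetxt(mat, D)
        script = (f'd <- as.dist(as.matrix(read.table("{mat}")));'
                  f'h <- hclust(d, method="ward.D");'
                  f'cat(sprintf("%.12f", h$height), sep="\\n")')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r_heights = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(np.sort(tree.merges[:, 2]), np.sort(r_heights), atol=1e-9)

    def test_ward_d2_dialect_matches_scipy_on_euclidean_input(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist, squareform
        X = rng.normal(size=(10, 3))
        mine = ward_d_linkage(squareform(pdist(X)), dialect="ward.D2")
        ref = linkage(pdist(X), method="ward")
        assert np.allclose(np.sort(mine.merges[:, 2]), np.sort(ref[:, 2]), atol=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_d_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            ward_d_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_newick_and_nested_outputs(self):
        D = np.array([[0.0, 0.2, 1.0], [0.2, 0.0, 1.1], [1.0, 1.1, 0.0]])
        tree = ward_d_linkage(D, labels=["x", "y", "z"])
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "x" in nwk and "z" in nwk

        def leaves(node):
            if isinstance(node, list):
                return [g for child in node for g in leaves(child)]
            return [node]

        assert sorted(leaves(tree.to_nested_lists())) == ["x", "y", "z"]


class TestCutModules:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(0)
        D = random_dissimilarity(rng, 6)
        tree = ward_d_linkage(D, labels=list("abcdef"))
        singles = cut_modules(tree, 6)
        assert singles.nunique() == 6
        one = cut_modules(tree, 1)
        assert one.nunique() == 1

    def test_partitions_nested_as_k_decreases(self):
        rng = np.random.default_rng(1)
        D = random_dissimilarity(rng, 8)
        tree = ward_d_linkage(D)
        prev = cut_modules(tree, 8)
        for k in range(7, 0, -1):
            cur = cut_modules(tree, k)
            # every current module is a union of previous modules
            grouping = pd.DataFrame({"prev": prev, "cur": cur})
            assert (grouping.groupby("prev")["cur"].nunique() == 1).all()
            prev = cur

    def test_out_of_range_k(self):
        tree = ward_d_linkage(np.array([[0.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            cut_modules(tree, 0)
        with pytest.raises(ValueError):
            cut_modules(tree, 3)


class TestModuleMarkers:
    def build(self, rng):
        """Three clusters in two modules; gene g0 planted in module 1."""
        n_per = 40
        counts = rng.poisson(3.0, size=(3 * n_per, 30))
        counts[:2 * n_per, 0] = rng.poisson(12.0, 2 * n_per)  # planted marker
        clusters = ["c1"] * n_per + ["c2"] * n_per + ["c3"] * n_per
        adata = make_adata(counts, obs={"cluster": clusters})
        modules = pd.Series({"c1": 1, "c2": 1, "c3": 2})
        return adata, modules

    def test_identical_expression_yields_null_gene(self, rng):
        counts = np.full((20, 5), 4)
        adata = make_adata(counts, obs={"cluster": ["c1"] * 10 + ["c2"] * 10})
        deg, _ = module_markers(adata, pd.Series({"c1": 1, "c2": 2}),
                                top_n=5, padj_max=1.1)
        assert (deg["log2fc"] == 0).all()
        assert (deg["pvalue"] == 1.0).all()

    def test_planted_marker_lands_in_its_module_top_set(self, rng):
        adata, modules = self.build(rng)
        deg, top = module_markers(adata, modules, top_n=5)
        assert "g0" in top[1]
        assert "g0" not in top.get(2, [])
        row = deg[(deg["module"] == 1) & (deg["gene"] == "g0")].iloc[0]
        assert row["padj"] < 0.01 and row["log2fc"] > 0

    def test_adjusted_p_not_below_raw(self, rng):
        adata, modules = self.build(rng)
        deg, _ = module_markers(adata, modules, top_n=5, padj_max=1.1)
        assert (deg["padj"] >= deg["pvalue"] - 1e-12).all()
        assert deg["frac_in"].between(0, 1).all()

    def test_tiny_module_skipped(self, rng):
        counts = rng.poisson(3.0, size=(22, 10))
        clusters = ["c1"] * 20 + ["c2"] * 2
        adata = make_adata(counts, obs={"cluster": clusters})
        deg, top = module_markers(adata, pd.Series({"c1": 1, "c2": 2}))
        assert set(deg["module"]) == {1}


class TestFractionExpressing:
    def test_trivial_fractions(self):
        counts = np.array([[1, 0], [2, 0], [3, 0], [4, 0]])
        adata = make_adata(counts, obs={"cluster": ["c1", "c1", "c2", "c2"]})
        modules = pd.Series({"c1": 1, "c2": 2})
        out = fraction_expressing(adata, {1: ["g0"], 2: ["g1"]}, modules)
        g0 = out[out["gene_set"] == 1]
        assert (g0["fraction_in"] == 1.0).all()
        g1 = out[out["gene_set"] == 2]
        assert (g1["fraction_in"] == 0.0).all() and (g1["fraction_out"] == 0.0).all()

    def test_planted_marker_enriched_in_own_module(self, rng):
        adata, modules = TestModuleMarkers().build(rng)
        out = fraction_expressing(adata, {1: ["g0"]}, modules)
        m1 = out[(out["module"] == 1)].iloc[0]
        assert m1["fraction_in"] > m1["fraction_out"]
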