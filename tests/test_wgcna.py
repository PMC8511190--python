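import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from pcenet.io import ExpressionMatrix
from pcenet.wgcna import (
    AdjacencyMatrix,
    ModulePartition,
    SimilarityMatrix,
    adjacency,
    bh_adjust,
    cluster_dendrogram,
    correlation_matrix,
    dynamic_tree_cut,
    eigenproteins,
    module_membership,
    module_trait_association,
    pick_soft_power,
    tom_similarity,
)
from conftest import random_expression


def expr(values, prefix="P"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"S{j}" for j in range(values.shape[1])],
        )
    )


class TestCorrelationMatrix:
    def test_duplicate_and_negated_profiles(self):
        base = [1.0, 3.0, 2.0, 5.0, 4.0]
        X = expr([base, base, [10.0 - v for v in base]])  # negated up to shift
        S = correlation_matrix(X).S
        assert S[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert S[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pairwise_pearson_formula(self):
        rng = np.random.default_rng(3)
        X = random_expression(rng, n_proteins=10, n_samples=15)
        S = correlation_matrix(X).S
        M = X.values
        for i in range(10):
            for j in range(10):
                xi, xj = M[i] - M[i].mean(), M[j] - M[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(S[i, j] - r) < 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(expr([[1, 2], [3, 4]]))

    def test_zero_variance_protein_dropped_with_warning(self):
        X = expr([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            S = correlation_matrix(X)
        assert S.protein_ids == ["P0", "P2"]


class TestPickSoftPower:
    def test_synthetic_data_reaches_target_fit(self, small_dataset):
        _, X, _, _ = small_dataset
        beta, fits = pick_soft_power(correlation_matrix(X.log2p1()))
        assert fits.loc[fits["beta"] == beta, "r_squared"].iloc[0] >= 0.8

    def test_degenerate_spread_warns_and_returns_smallest(self):
        ids = [f"P{i}" for i in range(12)]
        S = SimilarityMatrix(ids, np.eye(12))
        with pytest.warns(UserWarning):
            beta, _ = pick_soft_power(S, candidates=[2, 5, 9])
        assert beta == 2


class TestAdjacency:
    @pytest.mark.parametrize(
        "s,beta,expected",
        [(1.0, 7, 1.0), (-0.5, 2, 0.25), (0.3, 1, 0.3)],
    )
    def test_unsigned_power_closed_form(self, s, beta, expected):
        ids = ["a", "b"]
        S = SimilarityMatrix(ids, np.array([[1.0, s], [s, 1.0]]))
        assert adjacency(S, beta).A[0, 1] == pytest.approx(expected, abs=1e-15)

    def test_beta_one_is_absolute_similarity(self):
        rng = np.random.default_rng(0)
        S = correlation_matrix(random_expression(rng, 6, 10))
        A = adjacency(S, 1).A
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(A[off], np.abs(S.S[off]))


def brute_force_tom(A):
    """Direct triple-loop evaluation of the overlap formula."""
    a = A.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (L + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return T


class TestTOM:
    def test_path_graph_hand_value(self):
        ids = ["a", "b", "c"]
        A = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        T = tom_similarity(AdjacencyMatrix(ids, A, 1)).T
        assert T[0, 2] == pytest.approx(0.5, abs=1e-15)

    def test_clique_shared_neighbors_give_unit_overlap(self):
        n = 5
        A = np.ones((n, n))
        T = tom_similarity(AdjacencyMatrix([f"p{i}" for i in range(n)], A, 1)).T
        assert np.allclose(T, 1.0)

    def test_matches_triple_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            R = rng.random((8, 8))
            A = (R + R.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom_similarity(AdjacencyMatrix(list("abcdefgh"), A, 1)).T
            assert np.max(np.abs(T - brute_force_tom(A))) < 1e-12

    def test_bounds_on_random_adjacency(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            R = rng.random((12, 12))
            A = (R + R.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom_similarity(AdjacencyMatrix([str(i) for i in range(12)], A, 1)).T
            assert T.min() >= 0.0 and T.max() <= 1.0 + 1e-12


class TestDendrogramAndCut:
    def test_duplicates_merge_first_at_zero(self):
        D = np.array(
            [[0.0, 0.0, 0.8], [0.0, 0.0, 0.8], [0.8, 0.8, 0.0]]
        )
        Z = cluster_dendrogram(D, ["a", "b", "c"]).Z
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_hand_computed_average_linkage(self):
        D = np.array(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]
        )
        Z = cluster_dendrogram(D, ["a", "b", "c"]).Z
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(4, 12)
            R = rng.random((n, n))
            D = (R + R.T) / 2
            np.fill_diagonal(D, 0.0)
            Z = cluster_dendrogram(D, [str(i) for i in range(n)]).Z
            assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            cluster_dendrogram(D, ["a", "b", "c"])

    def test_two_planted_blocks_fully_recovered(self):
        n = 40  # two blocks of 20
        D = np.full((n, n), 0.9)
        D[:20, :20] = 0.05
        D[20:, 20:] = 0.05
        np.fill_diagonal(D, 0.0)
        ids = [f"P{i:02d}" for i in range(n)]
        part = dynamic_tree_cut(cluster_dendrogram(D, ids), min_module_size=15,
                                deep_split=4)
        assert len(part.module_ids) == 2
        assert (part.labels == 0).sum() == 0
        assert len(set(part.labels[:20])) == 1 and len(set(part.labels[20:])) == 1

    def test_isolated_noise_goes_to_grey(self):
        rng = np.random.default_rng(2)
        n_block, n_noise = 20, 10
        n = 2 * n_block + n_noise
        D = np.full((n, n), 0.95) + rng.random((n, n)) * 0.01
        D = (D + D.T) / 2
        D[:n_block, :n_block] = 0.05
        D[n_block : 2 * n_block, n_block : 2 * n_block] = 0.05
        np.fill_diagonal(D, 0.0)
        ids = [f"P{i:02d}" for i in range(n)]
        part = dynamic_tree_cut(cluster_dendrogram(D, ids), 15, 4)
        assert set(part.labels[2 * n_block :]) == {0}
        assert len(part.module_ids) == 2

    def test_modules_relabeled_by_decreasing_size(self, small_dataset):
        _, X, _, _ = small_dataset
        S = correlation_matrix(X.log2p1())
        T = tom_similarity(adjacency(S, 25))
        part = dynamic_tree_cut(cluster_dendrogram(T.dissimilarity, T.protein_ids))
        sizes = part.sizes()
        assert list(sizes.index) == sorted(sizes.index)
        assert (np.diff(sizes.values) <= 0).all()
        assert (sizes >= 15).all()


class TestEigenproteins:
    def test_rank_one_module_fully_explained(self):
        base = np.array([1.0, 4.0, 2.0, 6.0, 3.0])
        X = expr([base, 2 * base + 1, 0.5 * base + 2])
        part = ModulePartition(pd.Series([1, 1, 1], index=X.protein_ids))
        E = eigenproteins(X, part)
        assert E.variance_explained[1] == pytest.approx(1.0, abs=1e-12)
        std = (base - base.mean()) / base.std(ddof=1)
        v = E.profiles[1].to_numpy()
        assert abs(abs(np.corrcoef(v, std)[0, 1]) - 1) < 1e-12

    def test_variance_explained_matches_full_decomposition(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            X = random_expression(rng, n_proteins=14, n_samples=10)
            part = ModulePartition(
                pd.Series([1] * 7 + [2] * 7, index=X.protein_ids)
            )
            E = eigenproteins(X, part)
            for m in (1, 2):
                M = X.data.loc[part.members(m)].to_numpy()
                M = (M - M.mean(1, keepdims=True)) / M.std(1, ddof=1, keepdims=True)
                eig = np.linalg.eigvalsh(M @ M.T)[::-1]
                assert abs(E.variance_explained[m] - eig[0] / eig.sum()) < 1e-10

    def test_orientation_nonnegative_vs_mean_profile(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            X = random_expression(rng, n_proteins=6, n_samples=8)
            part = ModulePartition(pd.Series([1] * 6, index=X.protein_ids))
            E = eigenproteins(X, part)
            M = X.data.to_numpy()
            M = (M - M.mean(1, keepdims=True)) / M.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(E.profiles[1], M.mean(axis=0))[0, 1] >= -1e-12

    def test_unit_norm_scores(self):
        rng = np.random.default_rng(1)
        X = random_expression(rng, 8, 12)
        part = ModulePartition(pd.Series([1] * 8, index=X.protein_ids))
        E = eigenproteins(X, part)
        assert np.linalg.norm(E.profiles[1]) == pytest.approx(1.0, abs=1e-12)


class TestModuleMembership:
    def test_kme_matches_per_pair_correlation(self):
        rng = np.random.default_rng(21)
        X = random_expression(rng, 12, 10)
        part = ModulePartition(pd.Series([1] * 6 + [2] * 6, index=X.protein_ids))
        E = eigenproteins(X, part)
        kme = module_membership(X, E)
        for p in X.protein_ids:
            for m in (1, 2):
                direct = np.corrcoef(X.data.loc[p], E.profiles[m])[0, 1]
                assert abs(kme.loc[p, m] - direct) < 1e-12

    def test_rank_one_member_has_unit_membership(self):
        base = np.array([1.0, 4.0, 2.0, 6.0, 3.0])
        X = expr([base, 2 * base, 3 * base + 1])
        part = ModulePartition(pd.Series([1, 1, 1], index=X.protein_ids))
        kme = module_membership(X, eigenproteins(X, part))
        assert np.allclose(kme[1], 1.0, atol=1e-10)


class TestModuleTraitAssociation:
    def _eigen_from(self, vec, samples):
        v = np.asarray(vec, dtype=float)
        v = v / np.linalg.norm(v)
        return_profiles = pd.DataFrame({1: v}, index=samples)
        import pcenet.wgcna as w

        return w.EigenproteinSet(return_profiles, pd.Series({1: 1.0}))

    def test_perfect_association(self, cohort_traits):
        E = self._eigen_from(
            cohort_traits.traits["SqCC"].to_numpy(), cohort_traits.sample_ids
        )
        out = module_trait_association(E, cohort_traits)
        row = out[(out.module == 1) & (out.trait == "SqCC")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p == np.finfo(float).tiny
        assert row.significant

    def test_anti_trait_still_significant(self, cohort_traits):
        E = self._eigen_from(
            -cohort_traits.traits["SqCC"].to_numpy(), cohort_traits.sample_ids
        )
        out = module_trait_association(E, cohort_traits)
        row = out[(out.module == 1) & (out.trait == "SqCC")].iloc[0]
        assert row.r == pytest.approx(-1.0)
        assert row.significant

    def test_two_trait_symmetry(self, cohort_traits):
        rng = np.random.default_rng(17)
        E = self._eigen_from(rng.standard_normal(15), cohort_traits.sample_ids)
        out = module_trait_association(E, cohort_traits).set_index("trait")
        assert out.loc["SqCC", "r"] == pytest.approx(-out.loc["PPA", "r"], abs=1e-12)

    def test_r_and_p_match_reference_test(self, cohort_traits):
        rng = np.random.default_rng(23)
        y = cohort_traits.traits["SqCC"].to_numpy(dtype=float)
        for _ in range(50):
            e = rng.standard_normal(15)
            E = self._eigen_from(e, cohort_traits.sample_ids)
            row = module_trait_association(E, cohort_traits)
            row = row[row.trait == "SqCC"].iloc[0]
            ref_r, ref_p = pearsonr(E.profiles[1], y)
            assert row.r == pytest.approx(ref_r, abs=1e-12)
            assert row.p == pytest.approx(ref_p, rel=1e-10)

    def test_constant_trait_rejected(self, cohort_traits):
        import pandas as pd

        bad = cohort_traits.traits.copy()
        bad["flat"] = 1
        from pcenet.io import TraitTable

        t = TraitTable(bad)
        E = self._eigen_from(np.arange(15.0), t.sample_ids)
        with pytest.raises(ValueError, match="flat"):
            module_trait_association(E, t)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_independent_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(29)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), ref, rtol=0, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
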