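"""Hierarchical clustering, dynamic tree cut, eigengenes and the module
relationship tree."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from coexnet import (
    ExpressionMatrix,
    adjacency,
    bicor_matrix,
    cluster_genes,
    dynamic_cut,
    eigengenes,
    generate,
    module_tree,
    presence_filter,
    tom,
)
from coexnet.modules import EigengeneMatrix, ModuleAssignment
from coexnet.tom import TOMMatrix

from conftest import recovery_spec


def block_tom(sizes, within=0.9, between=0.02, rng=None, jitter=0.0):
    """TOM with planted diagonal blocks; optional jitter keeps it symmetric."""
    n = sum(sizes)
    T = np.full((n, n), between)
    start = 0
    for s in sizes:
        T[start : start + s, start : start + s] = within
        start += s
    if jitter and rng is not None:
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        T += (noise + noise.T) / 2
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return TOMMatrix([f"g{i:03d}" for i in range(n)], T)


def planted_pipeline(seed, deep_split=4, min_module_size=30):
    spec = recovery_spec(seed)
    m, truth = generate(spec)
    m, _ = presence_filter(m, m.n_samples // 2)
    T = tom(adjacency(bicor_matrix(m), 4))
    Z = cluster_genes(T)
    assign = dynamic_cut(
        Z, T.dissimilarity(), T.gene_ids,
        deep_split=deep_split, min_module_size=min_module_size,
    )
    return m, truth, T, assign


class TestClusterGenes:
    def test_two_genes_merge_at_one_minus_tom(self):
        T = TOMMatrix(["a", "b"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        Z = cluster_genes(T)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.7)

    def test_planted_blocks_form_disjoint_subtrees(self):
        T = block_tom([10, 10], rng=np.random.default_rng(0), jitter=0.01)
        Z = cluster_genes(T)
        two = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(two[:10])) == 1 and len(set(two[10:])) == 1
        assert two[0] != two[10]

    def test_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(1)
        T = block_tom([8, 12], rng=rng, jitter=0.02)
        perm = rng.permutation(20)
        Tp = TOMMatrix([T.gene_ids[i] for i in perm], T.T[np.ix_(perm, perm)])
        parts = fcluster(cluster_genes(T), t=2, criterion="maxclust")
        parts_p = fcluster(cluster_genes(Tp), t=2, criterion="maxclust")
        by_gene = dict(zip(T.gene_ids, parts))
        by_gene_p = dict(zip(Tp.gene_ids, parts_p))
        assert adjusted_rand_score(
            [by_gene[g] for g in T.gene_ids], [by_gene_p[g] for g in T.gene_ids]
        ) == pytest.approx(1.0)


class TestDynamicCut:
    def test_two_clean_blocks_give_two_full_modules(self):
        T = block_tom([40, 40], rng=np.random.default_rng(2), jitter=0.01)
        Z = cluster_genes(T)
        assign = dynamic_cut(Z, T.dissimilarity(), T.gene_ids, 4, 30)
        assert assign.n_modules == 2
        assert assign.n_unassigned() == 0
        sizes = assign.module_sizes()
        assert sorted(sizes.values()) == [40, 40]

    def test_min_size_gate_leaves_everything_grey(self):
        T = block_tom([40, 40], rng=np.random.default_rng(2), jitter=0.01)
        Z = cluster_genes(T)
        with pytest.warns(UserWarning, match="unassigned"):
            assign = dynamic_cut(Z, T.dissimilarity(), T.gene_ids, 4, 50)
        assert assign.n_modules == 0
        assert assign.n_unassigned() == 80

    def test_planted_six_module_recovery_at_deep_split_2_and_4(self):
        for deep_split in (2, 4):
            _, truth, _, assign = planted_pipeline(0, deep_split=deep_split)
            ari = adjusted_rand_score(
                [truth.module_of[g] for g in assign.gene_ids], assign.labels
            )
            assert ari >= 0.9

    def test_labels_contiguous_and_ordered_by_size(self):
        _, _, _, assign = planted_pipeline(1)
        sizes = assign.module_sizes()
        assert sorted(sizes) == list(range(1, assign.n_modules + 1))
        ordered = [sizes[lab] for lab in range(1, assign.n_modules + 1)]
        assert ordered == sorted(ordered, reverse=True)
        assert all(v >= 30 for v in sizes.values())

    def test_deeper_split_never_detects_fewer_modules_on_fixtures(self):
        for seed in (0, 1):
            _, _, T, _ = planted_pipeline(seed)
            Z = cluster_genes(T)
            counts = [
                dynamic_cut(Z, T.dissimilarity(), T.gene_ids, ds, 30).n_modules
                for ds in range(5)
            ]
            assert counts == sorted(counts)

    def test_parameter_validation(self):
        T = block_tom([10])
        Z = cluster_genes(T)
        with pytest.raises(ValueError):
            dynamic_cut(Z, T.dissimilarity(), T.gene_ids, 5, 30)
        with pytest.raises(ValueError):
            dynamic_cut(Z, T.dissimilarity(), T.gene_ids, 4, 1)


class TestEigengenes:
    def test_single_gene_module_is_its_standardized_profile(self):
        x = np.array([[1.0, 4.0, 2.0, 8.0]])
        m = ExpressionMatrix(["g0"], [f"s{j}" for j in range(4)], x)
        assign = ModuleAssignment(["g0"], np.array([1]), 4, 2)
        E = eigengenes(m, assign)
        z = (x[0] - x[0].mean()) / x[0].std()
        np.testing.assert_allclose(E.profiles[1], z / np.linalg.norm(z), atol=1e-12)
        assert E.explained_variance[1] == pytest.approx(1.0)

    def test_exact_rank_one_module_recovers_latent_profile(self):
        rng = np.random.default_rng(3)
        e = rng.standard_normal(12)
        u = rng.uniform(0.5, 1.0, size=6)
        X = np.abs(u[:, None] * e[None, :]) * 0 + u[:, None] * e[None, :]
        X = X - X.min()  # keep FPKM-like non-negativity
        m = ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"s{j}" for j in range(12)], X
        )
        assign = ModuleAssignment(m.gene_ids, np.ones(6, dtype=int), 4, 2)
        E = eigengenes(m, assign)
        r = np.corrcoef(E.profiles[1], e)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert E.explained_variance[1] == pytest.approx(1.0, abs=1e-10)

    def test_noisy_planted_module_recovery(self):
        m, truth, _, assign = planted_pipeline(0)
        E = eigengenes(m, assign)
        from collections import Counter

        for lab, prof in E.profiles.items():
            planted = Counter(
                truth.module_of[g] for g in assign.members(lab)
            ).most_common(1)[0][0]
            assert planted > 0
            r = np.corrcoef(prof, truth.eigengene_of[planted])[0, 1]
            assert abs(r) >= 0.9

    def test_gene_order_within_module_is_irrelevant(self):
        rng = np.random.default_rng(4)
        X = rng.gamma(2.0, 1.0, size=(8, 10))
        ids = [f"g{i}" for i in range(8)]
        m = ExpressionMatrix(ids, [f"s{j}" for j in range(10)], X)
        assign = ModuleAssignment(ids, np.ones(8, dtype=int), 4, 2)
        perm = rng.permutation(8)
        mp = ExpressionMatrix([ids[i] for i in perm], m.sample_ids, X[perm])
        E1 = eigengenes(m, assign)
        E2 = eigengenes(mp, assign)
        np.testing.assert_allclose(E1.profiles[1], E2.profiles[1], atol=1e-10)

    def test_constant_gene_module_raises_naming_module(self):
        X = np.array([[2.0, 2.0, 2.0], [1.0, 5.0, 3.0]])
        m = ExpressionMatrix(["flat", "ok"], ["s1", "s2", "s3"], X)
        assign = ModuleAssignment(["flat", "ok"], np.array([1, 1]), 4, 2)
        with pytest.raises(ValueError, match="module 1"):
            eigengenes(m, assign)

    def test_sign_convention_aligns_with_mean_profile(self):
        m, _, _, assign = planted_pipeline(1)
        E = eigengenes(m, assign)
        gene_index = {g: i for i, g in enumerate(m.gene_ids)}
        for lab, prof in E.profiles.items():
            X = m.values[[gene_index[g] for g in assign.members(lab)]]
            Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
            assert np.corrcoef(prof, Z.mean(axis=0))[0, 1] >= 0


class TestModuleTree:
    def _eig(self, profiles):
        return EigengeneMatrix(
            [f"s{j}" for j in range(len(next(iter(profiles.values()))))],
            {k: np.asarray(v, dtype=float) for k, v in profiles.items()},
            {k: 1.0 for k in profiles},
        )

    def test_identical_eigengenes_merge_at_zero(self):
        e = np.array([0.1, -0.5, 0.7, 0.2])
        labs, Z = module_tree(self._eig({1: e, 2: e.copy()}))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_eigengenes_merge_at_two(self):
        e = np.array([0.1, -0.5, 0.7, 0.2])
        labs, Z = module_tree(self._eig({1: e, 2: -e}))
        assert Z[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_similar_pair_merges_before_orthogonal_third(self):
        rng = np.random.default_rng(5)
        e1 = rng.standard_normal(40)
        e2 = e1 + 0.05 * rng.standard_normal(40)
        e3 = rng.standard_normal(40)
        labs, Z = module_tree(self._eig({1: e1, 2: e2, 3: e3}))
        # first merge joins modules 1 and 2 (leaf indices 0 and 1)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_requires_two_modules(self):
        with pytest.raises(ValueError):
            module_tree(self._eig({1: np.array([1.0, 2.0, 3.0])}))
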