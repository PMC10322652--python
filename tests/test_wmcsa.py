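import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from metchem import (
    ConcentrationMatrix,
    ContrastError,
    DegeneracyError,
    Dendrogram,
    EigenMetaboliteMatrix,
    ParameterError,
    all_branches,
    differential_modules,
    eigen_metabolite,
    wmcsa_summarize,
)


def balanced_tree_8():
    # heights chosen non-decreasing toward the root
    Z = np.array([
        [0, 1, 1.0, 2], [2, 3, 1.0, 2], [4, 5, 1.0, 2], [6, 7, 1.0, 2],
        [8, 9, 2.0, 4], [10, 11, 2.0, 4], [12, 13, 3.0, 8],
    ], dtype=float)
    return Dendrogram(Z, [f"m{i}" for i in range(8)])


def caterpillar_5():
    Z = np.array([
        [0, 1, 1.0, 2], [5, 2, 2.0, 3], [6, 3, 3.0, 4], [7, 4, 4.0, 5],
    ], dtype=float)
    return Dendrogram(Z, [f"m{i}" for i in range(5)])


def branch_count_oracle(Z, min_size):
    """Count internal nodes with >= min_size leaves straight off the linkage
    matrix, without any tree object."""
    n = Z.shape[0] + 1
    sizes = {}
    for row_idx, (a, b, _, _) in enumerate(Z):
        size = 0
        for child in (int(a), int(b)):
            size += 1 if child < n else sizes[child]
        sizes[n + row_idx] = size
    return sum(1 for s in sizes.values() if s >= min_size)


def make_conc(values, names, groups=None):
    n = values.shape[0]
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    if groups is None:
        groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return ConcentrationMatrix(
        pd.DataFrame(values, index=idx, columns=names),
        pd.Series(groups, index=idx, name="group"),
    )


class TestAllBranches:
    def test_balanced_tree_all_internal_nodes(self):
        modules = all_branches(balanced_tree_8(), min_size=2)
        assert len(modules) == 7  # n - 1 internal nodes
        assert modules.modules[1] == frozenset(f"m{i}" for i in range(8))

    def test_caterpillar_leaf_set_sizes(self):
        modules = all_branches(caterpillar_5(), min_size=3)
        sizes = sorted(len(m) for m in modules.modules.values())
        assert sizes == [3, 4, 5]

    def test_min_size_above_n_gives_empty_set(self, caplog):
        with caplog.at_level("WARNING"):
            modules = all_branches(caterpillar_5(), min_size=6)
        assert len(modules) == 0
        assert "min_size" in caplog.text

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ParameterError):
            all_branches(caterpillar_5(), min_size=1)

    def test_random_trees_match_traversal_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            pts = rng.standard_normal((n, 3))
            Z = linkage(pts, method="average")
            tree = Dendrogram(Z, [f"m{i}" for i in range(n)])
            min_size = int(rng.integers(2, 5))
            assert len(all_branches(tree, min_size)) == \
                branch_count_oracle(Z, min_size)

    def test_numbering_is_depth_first_and_nested(self):
        modules = all_branches(balanced_tree_8(), min_size=2)
        # depth-first from root: module 2 is the left half, nested in module 1
        assert modules.parent[2] == 1
        assert modules.modules[2] < modules.modules[1]


class TestEigenMetabolite:
    def test_rank_one_module(self, rng):
        # two perfectly (linearly) correlated members
        base = rng.standard_normal(10)
        conc = make_conc(np.column_stack([base, 2 * base + 1]), ["a", "b"])
        scores, ve, corr = eigen_metabolite(conc, {"a", "b"})
        assert ve == pytest.approx(1.0)
        assert abs(corr) == pytest.approx(1.0)

    def test_scores_zero_mean_and_sign_convention(self, rng):
        X = rng.standard_normal((12, 5))
        conc = make_conc(X, list("abcde"))
        scores, ve, corr = eigen_metabolite(conc, set("abcde"))
        assert abs(scores.mean()) < 1e-10
        assert corr >= 0
        assert 0 < ve <= 1

    def test_matches_svd_oracle(self, rng):
        X = rng.standard_normal((12, 6))
        conc = make_conc(X, list("abcdef"))
        scores, ve, _ = eigen_metabolite(conc, set("abcdef"))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        U, S, _ = np.linalg.svd(Xs, full_matrices=False)
        expected = U[:, 0] * S[0]
        if np.corrcoef(expected, scores)[0, 1] < 0:
            expected = -expected
        np.testing.assert_allclose(scores.values, expected, atol=1e-8)
        assert ve == pytest.approx(S[0] ** 2 / np.sum(S**2), abs=1e-12)

    def test_planted_pattern_recovery(self, rng):
        """Median correlation with the planted latent score >= 0.9 over 100
        replicates (loadings 1, noise sd 0.3, 24 samples, 5 members)."""
        corrs = []
        for _ in range(100):
            z = rng.standard_normal(24)
            X = z[:, None] + 0.3 * rng.standard_normal((24, 5))
            conc = make_conc(X, list("abcde"))
            scores, _, _ = eigen_metabolite(conc, set("abcde"))
            corrs.append(abs(np.corrcoef(scores, z)[0, 1]))
        assert np.median(corrs) >= 0.9

    def test_scale_invariance(self, rng):
        X = np.exp(rng.standard_normal((10, 4)))
        conc = make_conc(X, list("abcd"))
        scores, ve, _ = eigen_metabolite(conc, set("abcd"))
        X2 = X.copy()
        X2[:, 2] *= 10  # standardization removes per-metabolite scale
        scores2, ve2, _ = eigen_metabolite(make_conc(X2, list("abcd")), set("abcd"))
        np.testing.assert_allclose(scores.values, scores2.values, atol=1e-8)
        assert ve == pytest.approx(ve2, abs=1e-12)

    def test_constant_member_dropped_then_degenerate(self, rng, caplog):
        X = rng.standard_normal((8, 3))
        X[:, 1] = 5.0
        conc = make_conc(X, list("abc"))
        with caplog.at_level("WARNING"):
            _, ve, _ = eigen_metabolite(conc, set("abc"))
        assert "constant" in caplog.text
        X2 = np.column_stack([X[:, 0], np.full(8, 2.0)])
        with pytest.raises(DegeneracyError):
            eigen_metabolite(make_conc(X2, ["a", "b"]), {"a", "b"})

    def test_noise_members_never_raise_variance_explained(self, rng):
        """Adding pure-noise members to a planted module dilutes its first
        component (median over 20 replicates)."""
        deltas = []
        for _ in range(20):
            z = rng.standard_normal(24)
            planted = z[:, None] + 0.3 * rng.standard_normal((24, 4))
            noise = rng.standard_normal((24, 3))
            conc = make_conc(np.hstack([planted, noise]), list("abcdefg"))
            _, ve_small, _ = eigen_metabolite(conc, set("abcd"))
            _, ve_big, _ = eigen_metabolite(conc, set("abcdefg"))
            deltas.append(ve_big - ve_small)
        assert np.median(deltas) <= 0


class TestWmcsaSummarize:
    def test_one_row_per_module(self, rng):
        tree = balanced_tree_8()
        modules = all_branches(tree, min_size=2)
        conc = make_conc(rng.standard_normal((12, 8)), tree.labels)
        E = wmcsa_summarize(conc, modules)
        assert E.scores.shape == (7, 12)

    def test_nested_modules_reported_independently(self, rng):
        tree = balanced_tree_8()
        modules = all_branches(tree, min_size=2)
        conc = make_conc(rng.standard_normal((12, 8)), tree.labels)
        E = wmcsa_summarize(conc, modules)
        assert 1 in E.scores.index and 2 in E.scores.index
        assert modules.modules[2] < modules.modules[1]

    def test_sample_permutation_equivariance(self, rng):
        tree = balanced_tree_8()
        modules = all_branches(tree, min_size=3)
        X = rng.standard_normal((10, 8))
        conc = make_conc(X, tree.labels)
        E = wmcsa_summarize(conc, modules)
        perm = rng.permutation(10)
        conc_p = ConcentrationMatrix(conc.values.iloc[perm], conc.group.iloc[perm])
        E_p = wmcsa_summarize(conc_p, modules)
        np.testing.assert_allclose(
            E_p.scores.values, E.scores.values[:, perm], atol=1e-10
        )


class TestDifferentialModules:
    def make_E(self, scores, sample_ids):
        df = pd.DataFrame(scores, index=[1], columns=sample_ids)
        return EigenMetaboliteMatrix(
            df, pd.Series({1: 0.5}), pd.Series({1: 0.5})
        )

    def test_identical_scores_give_p_one(self):
        ids = [f"s{i}" for i in range(12)]
        E = self.make_E(np.ones((1, 12)), ids)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
        res = differential_modules(E, groups, ("A", "B"))
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "direction"] == "none"

    def test_strong_shift_detected(self, rng):
        ids = [f"s{i}" for i in range(12)]
        scores = np.concatenate([rng.standard_normal(6), rng.standard_normal(6) + 10])
        E = self.make_E(scores[None, :], ids)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
        res = differential_modules(E, groups, ("A", "B"))
        assert res.loc[0, "p_adjusted"] < 0.05
        assert res.loc[0, "direction"] == "down"

    def test_adjusted_never_below_raw(self, rng):
        ids = [f"s{i}" for i in range(12)]
        df = pd.DataFrame(rng.standard_normal((5, 12)),
                          index=range(1, 6), columns=ids)
        E = EigenMetaboliteMatrix(df, pd.Series(0.5, index=df.index),
                                  pd.Series(0.5, index=df.index))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
        res = differential_modules(E, groups, ("A", "B"))
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        assert res["p_value"].between(0, 1).all()

    def test_missing_contrast_level(self, rng):
        ids = [f"s{i}" for i in range(12)]
        E = self.make_E(rng.standard_normal((1, 12)), ids)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
        with pytest.raises(ContrastError):
            differential_modules(E, groups, ("A", "C"))
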