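"""CLR transform, PCA and PERMANOVA: identities, oracles, null behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from vulvasig.ordination import (
    clr_transform,
    default_pseudocount,
    pairwise_permanova,
    pca,
    permanova,
)


def frame(arr, prefix="f"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestClr:
    def test_hand_computed_example(self):
        out = clr_transform(frame([[4, 2, 2]]), pseudocount=0)
        expected = [(2 / 3) * np.log(2), -(1 / 3) * np.log(2), -(1 / 3) * np.log(2)]
        np.testing.assert_allclose(out.to_numpy()[0], expected, atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(20)
        out = clr_transform(frame(rng.integers(0, 50, size=(30, 12))), pseudocount=1)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_scale_invariance_without_zeros(self):
        rng = np.random.default_rng(21)
        x = rng.random((5, 8)) + 0.1
        a = clr_transform(frame(x), pseudocount=0)
        b = clr_transform(frame(3.7 * x), pseudocount=0)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_matches_reference_clr_on_positive_data(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(22)
        x = rng.random((6, 9)) + 0.5
        mine = clr_transform(frame(x), pseudocount=0)
        ref = skbio_comp.clr(x / x.sum(axis=1, keepdims=True))
        np.testing.assert_allclose(mine.to_numpy(), ref, atol=1e-10)

    def test_zero_cells_require_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(frame([[0, 1, 2]]), pseudocount=0)

    def test_default_pseudocount_rules(self):
        counts = frame([[0, 3, 5]])
        assert default_pseudocount(counts, "count") == 1.0
        rel = frame([[0.0, 0.2, 0.8]])
        assert default_pseudocount(rel, "relabund") == pytest.approx(0.1)


class TestPca:
    def test_rank_one_data(self):
        direction = np.array([1.0, 2.0, 3.0])
        data = frame(np.outer([0.0, 1.0, 2.0, 3.0], direction))
        res = pca(data)
        assert res.variance_explained[0] == pytest.approx(1.0)
        np.testing.assert_allclose(res.variance_explained[1:], 0.0, atol=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(23)
        res = pca(frame(rng.normal(size=(20, 6))))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_reconstruction_and_eigendecomposition_oracle(self):
        rng = np.random.default_rng(24)
        X = rng.normal(size=(20, 10))
        data = frame(X)
        res = pca(data)
        Xc = X - X.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xc, atol=1e-9)
        # independent oracle: eigendecomposition of the covariance matrix
        eigval, eigvec = np.linalg.eigh(Xc.T @ Xc)
        eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
        np.testing.assert_allclose(
            res.variance_explained, eigval[: len(res.variance_explained)] / eigval.sum(), atol=1e-9
        )
        for k in range(res.loadings.shape[1]):
            v, w = res.loadings.to_numpy()[:, k], eigvec[:, k]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(25)
        res = pca(frame(rng.normal(size=(15, 7))))
        L = res.loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_scores_columns_orthogonal(self):
        rng = np.random.default_rng(26)
        res = pca(frame(rng.normal(size=(12, 5))))
        S = res.scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca(frame(np.random.default_rng(0).normal(size=(4, 6))), n_components=5)


class TestPermanova:
    def test_exhaustive_enumeration_two_clean_groups(self):
        data = frame([[0.0], [0.0], [0.0], [0.0], [10.0], [10.0], [10.0], [10.0]])
        res = permanova(data, ["a"] * 4 + ["b"] * 4, method="exhaustive")
        assert res.n_permutations == 70  # C(8,4) distinct assignments
        assert res.p_perm == pytest.approx(2 / 70)

    def test_monte_carlo_within_3_se_of_exhaustive(self):
        rng = np.random.default_rng(27)
        data = frame(rng.normal(size=(8, 3)) + np.repeat([[0], [1.2]], 4, axis=0))
        groups = ["a"] * 4 + ["b"] * 4
        exact = permanova(data, groups, method="exhaustive")
        mc = permanova(data, groups, n_permutations=10_000, seed=1)
        se = np.sqrt(exact.p_perm * (1 - exact.p_perm) / 10_000)
        assert abs(mc.p_perm - exact.p_perm) <= 3 * se + 2 / 10_000

    def test_pseudo_f_matches_reference_implementation(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(28)
        data = frame(rng.normal(size=(18, 5)))
        groups = np.repeat(["a", "b", "c"], 6)
        mine = permanova(data, groups, n_permutations=99, seed=0)
        dm = skbio_dist.DistanceMatrix(
            squareform(pdist(data.to_numpy())), ids=[str(i) for i in range(18)]
        )
        ref = skbio_dist.permanova(dm, groups, permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(29)
        data = frame(rng.normal(size=(10, 4)))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        base = permanova(data, groups, n_permutations=9, seed=0)
        perm = rng.permutation(10)
        shuffled = permanova(data.iloc[perm], groups[perm], n_permutations=9, seed=0)
        assert shuffled.pseudo_F == pytest.approx(base.pseudo_F, abs=1e-10)

    def test_ss_total_identities(self):
        # centered-coordinate SS equals the pairwise-distance formulation
        rng = np.random.default_rng(30)
        X = rng.normal(size=(12, 6))
        d2 = squareform(pdist(X) ** 2)
        ss_pairwise = d2.sum() / (2 * 12)
        Xc = X - X.mean(axis=0)
        ss_centered = (Xc**2).sum()
        assert ss_pairwise == pytest.approx(ss_centered, abs=1e-9)

    def test_r2_grows_with_separation(self):
        rng = np.random.default_rng(31)
        noise = rng.normal(size=(16, 3))
        groups = ["a"] * 8 + ["b"] * 8
        shift = np.repeat([[0.0], [1.0]], 8, axis=0)
        r2 = [
            permanova(frame(noise + s * shift), groups, n_permutations=9, seed=0).R2
            for s in (0.5, 2.0, 8.0)
        ]
        assert r2[0] < r2[1] < r2[2]
        assert all(0 <= v <= 1 for v in r2)

    def test_small_group_rejected(self):
        data = frame(np.eye(3))
        with pytest.raises(ValueError, match=">= 2"):
            permanova(data, ["a", "a", "b"])

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(32)
        n_sim, rejected = 400, 0
        for _ in range(n_sim):
            data = frame(rng.normal(size=(20, 5)))
            groups = np.array(["a"] * 10 + ["b"] * 10)
            res = permanova(data, groups, n_permutations=199, seed=int(rng.integers(2**31)))
            rejected += res.p_perm <= 0.05
        assert 0.025 <= rejected / n_sim <= 0.075

    def test_pairwise_reruns_each_pair_with_bh(self):
        rng = np.random.default_rng(33)
        data = frame(np.vstack([rng.normal(size=(5, 3)), rng.normal(size=(5, 3)) + 4, rng.normal(size=(5, 3))]))
        groups = np.repeat(["a", "b", "c"], 5)
        pw = pairwise_permanova(data, groups, n_permutations=199, seed=0)
        assert len(pw) == 3
        assert ((pw["p_adj"] >= pw["p_raw"] - 1e-12) | np.isclose(pw["p_adj"], pw["p_raw"])).all()
        sep = pw[(pw["group_a"] == "a") & (pw["group_b"] == "b")]
        assert sep["p_raw"].iloc[0] <= 0.05
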