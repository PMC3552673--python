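import numpy as np
import pandas as pd
import pytest

from cdtox import (
    center_and_filter,
    cut_tree,
    hierarchical_cluster,
    pearson_dissimilarity,
    ward_cluster,
)
from cdtox.cluster_heatmap import lance_williams_linkage


def frame(rows, index=None, columns=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=index or [f"g{i}" for i in range(rows.shape[0])],
        columns=columns or [f"s{i}" for i in range(rows.shape[1])],
    )


class TestCenterAndFilter:
    def test_overall_mean_is_zero(self, default_sim):
        cm = center_and_filter(np.log2(default_sim.expression.signal + 1), 1.0)
        assert abs(cm.values.to_numpy().mean()) < 1e-10

    def test_constant_gene_excluded_even_at_zero_threshold(self):
        m = frame([[5, 5, 5, 5], [1, 2, 3, 4]])
        cm = center_and_filter(m, 0.0)
        assert list(cm.retained.index) == ["g1"]

    def test_all_equal_matrix_centers_to_zeros(self):
        cm = center_and_filter(frame([[3, 3], [3, 3]]), 0.5)
        assert (cm.values.to_numpy() == 0).all()
        assert cm.mask.sum() == 0

    def test_hand_computed_sd_mask(self):
        # per-gene SDs (ddof=1): g0: sd of (0,2,4)=2; g1: 0.1 spacing -> 0.1;
        # g2: (0,0.5,1) -> 0.5; g3: (0,3,6) -> 3
        m = frame([[0, 2, 4], [0, 0.1, 0.2], [0, 0.5, 1.0], [0, 3, 6]])
        cm = center_and_filter(m, 1.0)
        assert list(cm.retained.index) == ["g0", "g3"]
        assert cm.gene_sd["g0"] == pytest.approx(2.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            center_and_filter(frame([[1, 2], [3, 4]]), -0.1)


class TestPearsonDissimilarity:
    def test_identical_vectors_distance_zero(self):
        m = frame([[1, 2, 3, 4], [1, 2, 3, 4]])
        d = pearson_dissimilarity(m, axis="rows")
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_distance_two(self):
        m = frame([[1, 2, 3, 4], [4, 3, 2, 1]])
        d = pearson_dissimilarity(m, axis="rows")
        assert d.iloc[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_closed_form_value(self):
        # r((1,2,3,4),(1,2,3,5)) computed in closed form before the build
        x = np.array([1, 2, 3, 4.0]); y = np.array([1, 2, 3, 5.0])
        r = ((x - x.mean()) @ (y - y.mean())) / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        d = pearson_dissimilarity(frame([x, y]), axis="rows")
        assert d.iloc[0, 1] == pytest.approx(1 - r, abs=1e-12)
        assert d.iloc[0, 1] == pytest.approx(1 - 0.98270763, abs=1e-6)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        m = frame(rng.normal(size=(4, 6)))
        m2 = m * 3.7 + 11.0
        pd.testing.assert_frame_equal(
            pearson_dissimilarity(m, "rows"), pearson_dissimilarity(m2, "rows")
        )

    def test_zero_variance_vector_named(self):
        m = frame([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="g0"):
            pearson_dissimilarity(m, axis="rows")


def dist_frame(D, labels):
    return pd.DataFrame(np.asarray(D, float), index=labels, columns=labels)


class TestWardCluster:
    def test_two_leaves_single_merge_at_distance(self):
        d = dist_frame([[0, 3.0], [3.0, 0]], ["a", "b"])
        dn = ward_cluster(d)
        assert dn.merges.shape[0] == 1
        assert dn.heights[0] == pytest.approx(3.0)

    def test_nearest_pair_merges_first(self):
        d = dist_frame([[0, 1, 10], [1, 0, 10], [10, 10, 0]], list("ABC"))
        dn = ward_cluster(d)
        assert set(dn.merges[0, :2].astype(int)) == {0, 1}

    def test_heights_match_lance_williams_oracle(self):
        """Five-point fixture: scipy-backed Ward (D2) against the explicit
        Lance-Williams recurrence on squared dissimilarities."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 4))
        from scipy.spatial.distance import cdist

        D = cdist(X, X)
        dn = ward_cluster(dist_frame(D, list("abcde")))
        oracle = lance_williams_linkage(D, method="ward_d2")
        np.testing.assert_allclose(
            np.sort(dn.heights), np.sort(oracle[:, 2]), rtol=1e-10
        )

    def test_average_linkage_matches_oracle(self):
        rng = np.random.default_rng(9)
        from scipy.spatial.distance import cdist

        X = rng.normal(size=(6, 3))
        D = cdist(X, X)
        dn = hierarchical_cluster(dist_frame(D, list("abcdef")), "average")
        oracle = lance_williams_linkage(D, method="average")
        np.testing.assert_allclose(np.sort(dn.heights), np.sort(oracle[:, 2]), rtol=1e-10)

    def test_heights_nondecreasing(self, default_sim):
        cm = center_and_filter(np.log2(default_sim.expression.signal + 1), 0.5)
        d = pearson_dissimilarity(cm.retained, axis="columns")
        dn = ward_cluster(d)
        assert (np.diff(dn.heights) >= -1e-10).all()

    def test_row_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(4)
        from scipy.spatial.distance import cdist

        X = rng.normal(size=(7, 3))
        labels = [f"x{i}" for i in range(7)]
        D = dist_frame(cdist(X, X), labels)
        perm = rng.permutation(7)
        Dp = D.iloc[perm, perm]
        c1 = cut_tree(ward_cluster(D), 3)
        c2 = cut_tree(ward_cluster(Dp), 3)
        groups1 = {frozenset(c1.index[c1 == g]) for g in c1.unique()}
        groups2 = {frozenset(c2.index[c2 == g]) for g in c2.unique()}
        assert groups1 == groups2

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(d)

    def test_newick_export_parses(self):
        d = dist_frame([[0, 1, 5], [1, 0, 5], [5, 5, 0]], list("ABC"))
        nwk = ward_cluster(d).to_newick()
        assert nwk.endswith(";") and "A" in nwk and nwk.count("(") == 2


class TestCutTree:
    @pytest.fixture
    def dendro(self):
        d = dist_frame(
            [[0, 1, 8, 9], [1, 0, 8, 9], [8, 8, 0, 2], [9, 9, 2, 0]], list("abcd")
        )
        return ward_cluster(d)

    def test_k_equals_n(self, dendro):
        labels = cut_tree(dendro, 4)
        assert labels.nunique() == 4

    def test_k_one(self, dendro):
        assert cut_tree(dendro, 1).nunique() == 1

    def test_k_two_natural_split(self, dendro):
        labels = cut_tree(dendro, 2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    @pytest.mark.parametrize("k", [0, 5])
    def test_out_of_range_rejected(self, dendro, k):
        with pytest.raises(ValueError):
            cut_tree(dendro, k)
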