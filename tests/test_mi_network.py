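"""Tests for discretization, the plug-in MI estimator and module detection.

sklearn.metrics.mutual_info_score (natural log, converted to bits) and a
dictionary-based joint-histogram implementation written here serve as
independent oracles for the vectorized estimator.
"""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cdtox import (
    SimulationConfig,
    center_and_filter,
    detect_modules,
    discretize,
    entropy_bits,
    mi_adjacency,
    mi_distance,
    mutual_information,
    simulate_study,
)
from cdtox.mi_network import permutation_null_separation


def mi_oracle(x, y) -> float:
    """Plain-Python plug-in MI in bits from dictionaries of counts."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log2(pab * n * n / (px[a] * py[b]))
    return total


class TestDiscretize:
    def test_equal_frequency_halves(self):
        labels = discretize(np.arange(8.0), B=2)
        assert (labels == [0, 0, 0, 0, 1, 1, 1, 1]).all()

    def test_constant_gene_single_bin(self):
        assert (discretize(np.full(8, 2.5), B=3) == 0).all()

    def test_sort_and_split_oracle_with_ties(self):
        values = np.array([1, 2, 2, 3, 5, 8, 9, 9.0])
        labels = discretize(values, B=2)
        # stable rank split: first 4 in sorted (value, position) order -> bin 0
        assert (labels == [0, 0, 0, 0, 1, 1, 1, 1]).all()

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n, B in [(8, 3), (10, 4), (7, 2), (9, 5)]:
            labels = discretize(rng.normal(size=n), B=B)
            counts = np.bincount(labels, minlength=B)
            assert counts.max() - counts.min() <= 1

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            discretize(np.arange(4.0), B=5)


class TestDefaultBins:
    @pytest.mark.parametrize("n,B", [(2, 2), (8, 2), (9, 3), (16, 4), (24, 4)])
    def test_sqrt_rule(self, n, B):
        from cdtox.mi_network import default_bins

        assert default_bins(n) == B


class TestMutualInformation:
    def test_self_mi_equals_entropy(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert mutual_information(x, x, 2) == pytest.approx(1.0)
        assert entropy_bits(x) == pytest.approx(1.0)

    def test_exact_independence_zero(self):
        x = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        assert mutual_information(x, y, 2) == pytest.approx(0.0, abs=1e-15)

    def test_diagonal_joint_value(self):
        # joint counts [[3,1],[1,3]] over 8 samples: frozen plug-in value
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        expected = 0.75 * math.log2(1.5) + 0.25 * math.log2(0.5)
        assert expected == pytest.approx(0.18872, abs=1e-5)
        assert mutual_information(x, y, 2) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information([0, 1], [0, 1, 1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(2, 12), st.integers(2, 4), st.integers(0, 10_000))
    def test_equals_oracles_and_bounds(self, n, B, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, B, n)
        y = rng.integers(0, B, n)
        mi = mutual_information(x, y, B)
        assert mi == pytest.approx(mi_oracle(x, y), abs=1e-12)
        from sklearn.metrics import mutual_info_score

        assert mi == pytest.approx(mutual_info_score(x, y) / math.log(2), abs=1e-9)
        assert -1e-12 <= mi <= min(entropy_bits(x), entropy_bits(y)) + 1e-12


class TestMiAdjacency:
    def test_identical_genes_offdiag_equals_entropy(self):
        m = pd.DataFrame(
            [np.arange(8.0), np.arange(8.0)], index=["a", "b"],
            columns=[f"s{i}" for i in range(8)],
        )
        mim = mi_adjacency(m, B=2)
        assert mim.mi.loc["a", "b"] == pytest.approx(mim.entropy["a"])

    def test_matrix_is_exactly_symmetric(self):
        rng = np.random.default_rng(1)
        mim = mi_adjacency(rng.normal(size=(20, 8)), B=3)
        np.testing.assert_array_equal(mim.mi.to_numpy(), mim.mi.to_numpy().T)

    def test_matches_pairwise_estimator(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 10))
        mim = mi_adjacency(X, B=3)
        L = discretize(X, B=3)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mim.mi.iloc[i, j] == pytest.approx(
                    mutual_information(L[i], L[j], 3), abs=1e-12
                )

    def test_independent_genes_stay_near_permutation_bias_floor(self):
        """Mean off-diagonal MI of independent genes matches the small-sample
        bias estimated from permuted pairs."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 8))
        mim = mi_adjacency(X, B=3)
        off = mim.mi.to_numpy()[np.triu_indices(30, 1)]
        perm_mis = []
        L = discretize(X, B=3)
        for _ in range(100):
            i, j = rng.integers(0, 30, 2)
            perm_mis.append(
                mutual_information(rng.permutation(L[i]), rng.permutation(L[j]), 3)
            )
        floor = np.mean(perm_mis)
        assert off.mean() == pytest.approx(floor, abs=3 * np.std(perm_mis) / 10 + 0.05)


class TestMiDistance:
    def test_identical_genes_distance_zero(self):
        m = pd.DataFrame([np.arange(8.0)] * 2, index=["a", "b"])
        d = mi_distance(mi_adjacency(m, B=2))
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_mi_pair_distance_one(self):
        x = [0, 0, 1, 1, 0, 0, 1, 1]
        y = [0, 1, 0, 1, 0, 1, 0, 1]
        m = pd.DataFrame([x, y], index=["a", "b"], dtype=float)
        d = mi_distance(mi_adjacency(m, B=2))
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_three_gene_formula(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3, 9))
        mim = mi_adjacency(X, B=3)
        d = mi_distance(mim)
        H = mim.entropy.to_numpy()
        for i in range(3):
            for j in range(3):
                if i != j:
                    expected = 1 - mim.mi.iloc[i, j] / math.sqrt(H[i] * H[j])
                    assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_entropy_gene_flagged(self):
        m = pd.DataFrame([[1.0] * 8, list(range(8))], index=["flat", "ok"])
        d = mi_distance(mi_adjacency(m, B=2))
        assert d.attrs["zero_entropy"] == ["flat"]
        assert d.loc["flat", "ok"] == 1.0


class TestDetectModules:
    @staticmethod
    def _retained(study):
        mat = np.log2(study.expression.signal + 1.0)
        return center_and_filter(mat, sd_threshold=0.5).retained

    def test_planted_module_recovered(self, null_config):
        cfg = dict(null_config)
        cfg["module_specs"] = ((8, 3.0, "linear"),)
        hits = 0
        for seed in (1, 2, 3, 4, 5):
            study = simulate_study(SimulationConfig(seed=seed, **cfg))
            planted = set(study.truth.index[study.truth["module_id"] == 0])
            mods = detect_modules(mi_adjacency(self._retained(study)))
            top = set(mods[0].members) if mods else set()
            j = len(top & planted) / len(top | planted)
            hits += j >= 0.8
        assert hits >= 4

    def test_two_planted_modules_in_top_two(self, null_config):
        cfg = dict(null_config)
        cfg["module_specs"] = ((8, 3.0, "linear"), (12, 3.0, "linear"))
        hits = 0
        for seed in range(1, 11):
            study = simulate_study(SimulationConfig(seed=seed, **cfg))
            truth = study.truth
            mods = detect_modules(mi_adjacency(self._retained(study)))
            tops = [set(m.members) for m in mods[:2]]
            found = 0
            for mid in (0, 1):
                planted = set(truth.index[truth["module_id"] == mid])
                if any(len(t & planted) / len(t | planted) >= 0.8 for t in tops):
                    found += 1
            hits += found == 2
        assert hits >= 7

    def test_modules_are_disjoint_and_sorted(self, null_config):
        cfg = dict(null_config)
        cfg["module_specs"] = ((8, 3.0, "linear"), (12, 3.0, "linear"))
        study = simulate_study(SimulationConfig(seed=2, **cfg))
        mods = detect_modules(mi_adjacency(self._retained(study)))
        seps = [m.separation for m in mods]
        assert seps == sorted(seps, reverse=True)
        assert all(m.separation > 0 for m in mods)
        seen = set()
        for m in mods:
            assert seen.isdisjoint(m.members)
            seen.update(m.members)

    def test_gene_order_invariance(self, null_config):
        cfg = dict(null_config)
        cfg["module_specs"] = ((8, 3.0, "linear"),)
        study = simulate_study(SimulationConfig(seed=3, **cfg))
        kept = self._retained(study)
        rng = np.random.default_rng(0)
        shuffled = kept.iloc[rng.permutation(len(kept))]
        top1 = detect_modules(mi_adjacency(kept))[0]
        top2 = detect_modules(mi_adjacency(shuffled))[0]
        assert set(top1.members) == set(top2.members)
        assert top1.separation == pytest.approx(top2.separation, abs=1e-12)

    def test_null_data_below_permutation_threshold(self, null_config):
        study = simulate_study(SimulationConfig(seed=21, **null_config))
        kept = self._retained(study)
        mods = detect_modules(mi_adjacency(kept))
        obs = mods[0].separation if mods else 0.0
        null = permutation_null_separation(kept, n_permutations=40, rng=99)
        assert obs <= np.quantile(null, 0.95)

    def test_recovery_monotone_in_driver_strength(self, null_config):
        """Jaccard with the planted set does not degrade as the shared
        driver strengthens (3-point grid, fixed seeds)."""
        scores = []
        for strength in (0.5, 1.5, 3.0):
            cfg = dict(null_config)
            cfg["module_specs"] = ((8, strength, "linear"),)
            js = []
            for seed in (1, 2, 3, 4, 5, 6):
                study = simulate_study(SimulationConfig(seed=seed, **cfg))
                planted = set(study.truth.index[study.truth["module_id"] == 0])
                mods = detect_modules(mi_adjacency(self._retained(study)))
                top = set(mods[0].members) if mods else set()
                js.append(len(top & planted) / len(top | planted) if top | planted else 0.0)
            scores.append(np.mean(js))
        assert scores[0] <= scores[1] + 0.05
        assert scores[1] <= scores[2] + 0.05

    def test_min_size_validation(self):
        rng = np.random.default_rng(0)
        mim = mi_adjacency(rng.normal(size=(10, 8)), B=3)
        with pytest.raises(ValueError, match="min_size"):
            detect_modules(mim, min_size=2)
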