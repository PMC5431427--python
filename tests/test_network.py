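import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organnet import network
from organnet.errors import (
    BlockSizeError,
    ConfigError,
    DegenerateInputError,
    ValidationError,
)
from conftest import brute_force_tom


def frame(arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=names, columns=names)


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestPearson:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(5, 8)))
        cor = network.pearson_matrix(expr)
        np.testing.assert_allclose(np.diag(cor.to_numpy()), 1.0)

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        cor = network.pearson_matrix(expr)
        assert cor.at["a", "b"] == pytest.approx(-1.0)

    def test_hand_value(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]], index=["x", "y"])
        cor = network.pearson_matrix(expr)
        assert cor.at["x", "y"] == pytest.approx(0.5)

    def test_zero_variance_dropped_with_warning(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "flat"]
        )
        with pytest.warns(UserWarning):
            cor = network.pearson_matrix(expr)
        assert list(cor.index) == ["ok"]

    def test_zero_variance_strict_mode_raises(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "flat"]
        )
        with pytest.raises(DegenerateInputError, match="flat"):
            network.pearson_matrix(expr, drop_zero_variance=False)

    def test_too_few_samples(self):
        with pytest.raises(DegenerateInputError):
            network.pearson_matrix(pd.DataFrame([[1.0, 2.0]]))


class TestSignedAdjacency:
    def test_cor_one(self):
        assert network.signed_adjacency(np.array([[1.0]]), 20)[0, 0] == 1.0

    def test_cor_minus_one(self):
        assert network.signed_adjacency(np.array([[-1.0]]), 20)[0, 0] == 0.0

    def test_cor_zero(self):
        a = network.signed_adjacency(np.array([[0.0]]), 20)[0, 0]
        assert a == pytest.approx(0.5**20)
        assert a == pytest.approx(9.5367431640625e-07)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            network.signed_adjacency(np.array([[1.5]]), 20)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, c1, c2):
        a1 = float(network.signed_adjacency(np.array([[c1]]), 6)[0, 0])
        a2 = float(network.signed_adjacency(np.array([[c2]]), 6)[0, 0])
        assert 0.0 <= a1 <= 1.0
        if c1 < c2:
            assert a1 <= a2


class TestTOM:
    def test_zero_offdiagonal(self):
        a = np.eye(4)
        tom = network.tom_matrix(frame(a)).to_numpy()
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_n2_equals_adjacency(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        tom = network.tom_matrix(frame(a))
        assert tom.iat[0, 1] == pytest.approx(0.37)

    def test_three_genes_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = network.tom_matrix(frame(a))
        assert tom.iat[0, 1] == pytest.approx(0.5)

    def test_oracle_equivalence_small_batch(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = random_adjacency(rng, 12)
            got = network.tom_matrix(frame(a)).to_numpy()
            np.testing.assert_allclose(got, brute_force_tom(a), atol=1e-10)

    def test_symmetric_range(self):
        rng = np.random.default_rng(13)
        a = random_adjacency(rng, 15)
        tom = network.tom_matrix(frame(a)).to_numpy()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        assert (tom >= -1e-12).all() and (tom <= 1 + 1e-12).all()

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValidationError):
            network.tom_matrix(frame(a))


def block_dissimilarity(sizes, n_extra=0):
    """Perfect blocks: within-diss 0, between-diss 1."""
    n = sum(sizes) + n_extra
    d = np.ones((n, n))
    pos = 0
    for s in sizes:
        d[pos : pos + s, pos : pos + s] = 0.0
        pos += s
    np.fill_diagonal(d, 0.0)
    return frame(d)


class TestDetectModules:
    def test_two_separated_blocks(self):
        diss = block_dissimilarity([40, 35])
        part = network.detect_modules(diss, network.NetworkConfig(min_module_size=30))
        assert part.module_sizes == {1: 40, 2: 35}

    def test_small_block_unassigned(self):
        diss = block_dissimilarity([40, 10])
        part = network.detect_modules(diss, network.NetworkConfig(min_module_size=30))
        assert part.module_sizes == {1: 40}
        assert (part.module_of_gene == 0).sum() == 10

    def test_labels_sorted_by_size(self):
        diss = block_dissimilarity([31, 50, 44])
        part = network.detect_modules(diss, network.NetworkConfig(min_module_size=30))
        assert part.module_sizes == {1: 50, 2: 44, 3: 31}
        sizes = [part.module_sizes[m] for m in sorted(part.module_sizes)]
        assert sizes == sorted(sizes, reverse=True)

    def test_block_size_limit(self):
        diss = block_dissimilarity([40])
        config = network.NetworkConfig(max_block_size=10)
        with pytest.raises(BlockSizeError):
            network.detect_modules(diss, config)

    def test_bad_config(self):
        with pytest.raises(ConfigError):
            network.NetworkConfig(beta=0).validate()
        with pytest.raises(ConfigError):
            network.NetworkConfig(merge_cut_height=1.5).validate()


class TestEigengenes:
    def samples(self, n):
        return [f"s{j}" for j in range(n)]

    def test_two_identical_profiles(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr = pd.DataFrame(
            [profile, profile], index=["a", "b"], columns=self.samples(6)
        )
        labels = pd.Series([1, 1], index=["a", "b"])
        eig = network.module_eigengenes(expr, labels)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.loc[1].to_numpy(), z, atol=1e-10)

    def test_orientation_against_mean_profile(self):
        rng = np.random.default_rng(21)
        expr = pd.DataFrame(
            rng.normal(size=(6, 8)) + rng.normal(size=8) * 2,
            index=[f"g{i}" for i in range(6)],
            columns=self.samples(8),
        )
        labels = pd.Series(1, index=expr.index)
        eig = network.module_eigengenes(expr, labels)
        z = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True)) / expr.to_numpy().std(
            1, ddof=1, keepdims=True
        )
        r = np.corrcoef(eig.loc[1].to_numpy(), z.mean(axis=0))[0, 1]
        assert r >= 0

    def test_flipping_all_members_changes_nothing_up_to_sign(self):
        rng = np.random.default_rng(22)
        expr = pd.DataFrame(
            rng.normal(size=(5, 7)), index=[f"g{i}" for i in range(5)],
            columns=self.samples(7),
        )
        labels = pd.Series(1, index=expr.index)
        e1 = network.module_eigengenes(expr, labels).loc[1].to_numpy()
        e2 = network.module_eigengenes(-expr, labels).loc[1].to_numpy()
        r = abs(np.corrcoef(e1, e2)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_unit_variance(self):
        rng = np.random.default_rng(23)
        expr = pd.DataFrame(
            rng.normal(size=(9, 10)), index=[f"g{i}" for i in range(9)],
            columns=self.samples(10),
        )
        labels = pd.Series([1] * 5 + [2] * 4, index=expr.index)
        eig = network.module_eigengenes(expr, labels)
        np.testing.assert_allclose(eig.std(axis=1, ddof=1).to_numpy(), 1.0, atol=1e-9)

    def test_first_pc_optimality(self):
        rng = np.random.default_rng(24)
        for _ in range(10):
            z = rng.normal(size=(10, 6))
            z = (z - z.mean(1, keepdims=True)) / z.std(1, ddof=1, keepdims=True)
            expr = pd.DataFrame(
                z, index=[f"g{i}" for i in range(10)], columns=self.samples(6)
            )
            labels = pd.Series(1, index=expr.index)
            e = network.module_eigengenes(expr, labels).loc[1].to_numpy()
            e_unit = e / np.linalg.norm(e)
            var_e = ((z @ e_unit) ** 2).sum()
            for i in range(10):
                v = z[i] / np.linalg.norm(z[i])
                assert var_e >= ((z @ v) ** 2).sum() - 1e-8


class TestMergeModules:
    def samples(self, n):
        return [f"s{j}" for j in range(n)]

    def test_identical_eigengene_modules_merge(self):
        profile = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rows = [profile + 0.01 * i for i in range(4)]
        expr = pd.DataFrame(
            rows, index=["a", "b", "c", "d"], columns=self.samples(6)
        )
        labels = pd.Series([1, 1, 2, 2], index=expr.index)
        merged = network.merge_modules(expr, labels, merge_cut_height=0.2)
        assert len(merged.module_sizes) == 1
        assert merged.module_sizes[1] == 4

    def test_orthogonal_eigengenes_not_merged(self):
        p1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        p2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        expr = pd.DataFrame(
            [p1, p1, p2, p2], index=["a", "b", "c", "d"], columns=self.samples(6)
        )
        labels = pd.Series([1, 1, 2, 2], index=expr.index)
        merged = network.merge_modules(expr, labels, merge_cut_height=0.2)
        assert len(merged.module_sizes) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(30)
        expr = pd.DataFrame(
            rng.normal(size=(20, 8)),
            index=[f"g{i}" for i in range(20)],
            columns=self.samples(8),
        )
        labels = pd.Series([1] * 7 + [2] * 7 + [3] * 6, index=expr.index)
        once = network.merge_modules(expr, labels, merge_cut_height=0.25)
        twice = network.merge_modules(expr, once.module_of_gene, merge_cut_height=0.25)
        pd.testing.assert_series_equal(once.module_of_gene, twice.module_of_gene)
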