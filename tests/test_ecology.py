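from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from asvnet import ecology
from asvnet import synthetic as syn
from asvnet.ecology import DistanceMatrix, EcologyError
from asvnet.feature_table import FeatureTable


def table_from_rows(rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(rows))]
    cols = [f"a{j}" for j in range(len(rows[0]))]
    return FeatureTable(pd.DataFrame(rows, index=samples, columns=cols))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        dm = ecology.bray_curtis(table_from_rows([[1, 2, 3], [1, 2, 3]]))
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports_distance_one(self):
        dm = ecology.bray_curtis(table_from_rows([[5, 0], [0, 7]]))
        assert dm.values[0, 1] == 1.0

    def test_hand_arithmetic(self):
        # |1-3| + |2-0| over 1+3+2+0 = 4/6
        dm = ecology.bray_curtis(table_from_rows([[1, 2], [3, 0]]))
        assert dm.values[0, 1] == pytest.approx(4 / 6, abs=1e-12)

    def test_all_zero_sample_named_in_error(self):
        with pytest.raises(EcologyError, match="s1"):
            ecology.bray_curtis(table_from_rows([[1, 2], [0, 0]]))

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        table = table_from_rows(rng.integers(1, 30, size=(6, 10)).tolist())
        dm = ecology.bray_curtis(table)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()
        np.testing.assert_allclose(dm.values, dm.values.T)


class TestPcoa:
    def test_identical_samples_coincide(self):
        dm = ecology.bray_curtis(table_from_rows([[1, 2], [1, 2], [4, 1]]))
        coords, _ = ecology.pcoa(dm)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-10)

    def test_equilateral_configuration(self):
        mat = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(pd.DataFrame(mat, index=list("abc"),
                                         columns=list("abc")))
        coords, _ = ecology.pcoa(dm)
        c = coords.to_numpy()
        dists = [np.linalg.norm(c[i] - c[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        np.testing.assert_allclose(dists, dists[0], atol=1e-10)

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(7, 2))
        mat = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        ids = [f"s{i}" for i in range(7)]
        dm = DistanceMatrix(pd.DataFrame(mat, index=ids, columns=ids))
        coords, eigvals = ecology.pcoa(dm)
        c = coords.to_numpy()
        recovered = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        np.testing.assert_allclose(recovered, mat, atol=1e-8)
        # Euclidean input: no meaningful negative eigenvalues
        assert eigvals.min() > -1e-8


class TestPermanova:
    def _two_block_dm(self, per_group=2):
        # within-group distances 0, between-group 1
        n = 2 * per_group
        mat = np.ones((n, n))
        mat[:per_group, :per_group] = 0
        mat[per_group:, per_group:] = 0
        ids = [f"a{i}" for i in range(per_group)] + \
            [f"b{i}" for i in range(per_group)]
        return DistanceMatrix(pd.DataFrame(mat, index=ids, columns=ids)), \
            ["g1"] * per_group + ["g2"] * per_group

    def test_maximal_separation(self):
        dm, labels = self._two_block_dm(per_group=5)
        res = ecology.permanova(dm, labels, n_perm=999, seed=0)
        assert res.F > 1e6 or np.isinf(res.F)
        # only partition-preserving relabelings (2 * 5! * 5! / 10! of them)
        # can tie the observed statistic, so p sits near its floor
        assert res.p < 0.03

    def test_brute_force_oracle_n4(self):
        rng = np.random.default_rng(3)
        mat = rng.uniform(0.2, 1.0, size=(4, 4))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        ids = list("wxyz")
        dm = DistanceMatrix(pd.DataFrame(mat, index=ids, columns=ids))
        labels = ["g1", "g1", "g2", "g2"]

        # independent naive F: direct double loops over the definition
        def naive_f(lbls):
            n, k = 4, 2
            d2 = mat ** 2
            ss_total = sum(d2[i][j] for i in range(n) for j in range(i + 1, n)) / n
            ss_within = 0.0
            for g in set(lbls):
                idx = [i for i, l in enumerate(lbls) if l == g]
                pair_sum = sum(d2[i][j] for i in idx for j in idx if i < j)
                ss_within += pair_sum / len(idx)
            ss_between = ss_total - ss_within
            return (ss_between / (k - 1)) / (ss_within / (n - k))

        f_obs = naive_f(labels)
        res = ecology.permanova(dm, labels, n_perm=999, seed=1)
        assert res.F == pytest.approx(f_obs, rel=1e-12)

        # exhaustive relabeling: p over all 24 label orders
        exceed = sum(naive_f(p) >= f_obs for p in permutations(labels))
        p_exact = exceed / 24
        assert res.p == pytest.approx(p_exact, abs=0.05)

    def test_r2_partition(self):
        rng = np.random.default_rng(8)
        table = table_from_rows(rng.integers(1, 40, size=(8, 12)).tolist())
        dm = ecology.bray_curtis(table)
        labels = ["g1"] * 4 + ["g2"] * 4
        res = ecology.permanova(dm, labels, n_perm=99, seed=0)
        assert 0 <= res.R2 <= 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        table = table_from_rows(rng.integers(1, 40, size=(10, 8)).tolist())
        dm = ecology.bray_curtis(table)
        labels = ["g1"] * 5 + ["g2"] * 5
        r1 = ecology.permanova(dm, labels, n_perm=199, seed=7)
        r2 = ecology.permanova(dm, labels, n_perm=199, seed=7)
        assert r1 == r2

    def test_degenerate_grouping_rejected(self):
        dm, _ = self._two_block_dm()
        with pytest.raises(EcologyError):
            ecology.permanova(dm, ["g1"] * 4, n_perm=9)
        with pytest.raises(EcologyError):
            ecology.permanova(dm, ["g1", "g2", "g2", "g2"], n_perm=9)

    def test_power_exceeds_type_one_error(self):
        # planted group effect should reject decisively
        spec = syn.SyntheticSpec(n_samples_per_group=10,
                                 group_names=["A", "B"], n_asvs=30,
                                 module_sizes=[], effect_asvs=list(range(6)),
                                 effect_group="B", effect_size=6.0, seed=21)
        table, meta = syn.sample_counts(spec)
        dm = ecology.bray_curtis(table)
        res = ecology.permanova(dm, meta.groups(), n_perm=199, seed=0)
        assert res.p <= 0.01

    def test_pairwise_covers_all_pairs(self):
        rng = np.random.default_rng(10)
        table = table_from_rows(rng.integers(1, 40, size=(9, 8)).tolist())
        dm = ecology.bray_curtis(table)
        labels = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        out = ecology.permanova_pairwise(dm, labels, n_perm=49, seed=0)
        assert len(out) == 3
        assert set(zip(out["group_a"], out["group_b"])) == {
            ("g1", "g2"), ("g1", "g3"), ("g2", "g3")}


class TestPercentChange:
    def test_worked_example(self):
        assert ecology.percent_change(5.49, 2.37) == 57

    def test_no_change(self):
        assert ecology.percent_change(3.0, 3.0) == 0

    def test_total_loss(self):
        assert ecology.percent_change(3.0, 0.0) == 100

    def test_invalid_baseline(self):
        with pytest.raises(EcologyError):
            ecology.percent_change(0.0, 1.0)
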