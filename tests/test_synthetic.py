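import numpy as np
import pytest
from scipy import stats

from asvnet import synthetic as syn
from asvnet.synthetic import SyntheticSpec, SyntheticSpecError


class TestLatentCorrelation:
    def test_two_blocks(self):
        spec = SyntheticSpec(n_asvs=6, module_sizes=[3, 3], rho_within=0.8,
                             group_names=["G"])
        corr = syn.build_latent_correlation(spec)
        expected = np.zeros((6, 6))
        expected[:3, :3] = 0.8
        expected[3:, 3:] = 0.8
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(corr, expected)

    def test_single_asv_identity(self):
        spec = SyntheticSpec(n_asvs=1, module_sizes=[1], group_names=["G"])
        np.testing.assert_allclose(syn.build_latent_correlation(spec), [[1.0]])

    def test_connector_off_block_entries(self):
        spec = SyntheticSpec(n_asvs=4, module_sizes=[2], rho_within=0.5,
                             connector_asvs=[(3, [0])], rho_cross=0.75,
                             group_names=["G"])
        corr = syn.build_latent_correlation(spec)
        # exactly two 0.75 entries above the diagonal: connector to both
        # members of its foreign module
        upper = corr[np.triu_indices(4, k=1)]
        assert np.sum(upper == 0.75) == 2
        assert corr[3, 0] == corr[0, 3] == 0.75
        assert corr[3, 1] == 0.75

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(n_asvs=4, module_sizes=[2], rho_within=1.0,
                          group_names=["G"])
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(n_asvs=4, module_sizes=[2], rho_cross=1.2,
                          group_names=["G"])

    def test_module_sizes_exceeding_n_asvs_rejected(self):
        with pytest.raises(SyntheticSpecError, match="exceeds"):
            SyntheticSpec(n_asvs=3, module_sizes=[2, 2], group_names=["G"])

    def test_psd_after_repair(self):
        # a connector to two orthogonal blocks forces an eigenvalue repair
        spec = SyntheticSpec(n_asvs=20, module_sizes=[8, 8], rho_within=0.9,
                             connector_asvs=[(16, [0, 1])], rho_cross=0.9,
                             group_names=["G"])
        corr = syn.build_latent_correlation(spec)
        assert np.linalg.eigvalsh(corr).min() >= -1e-8
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)


class TestSampleCounts:
    def test_deterministic_under_seed(self):
        spec = SyntheticSpec(n_samples_per_group=5, group_names=["A", "B"],
                             n_asvs=12, module_sizes=[4], seed=9)
        t1, m1 = syn.sample_counts(spec)
        t2, m2 = syn.sample_counts(spec)
        assert t1 == t2
        assert m1.data.equals(m2.data)

    def test_counts_are_nonnegative_integers(self):
        spec = SyntheticSpec(n_samples_per_group=4, group_names=["G"],
                             n_asvs=10, module_sizes=[3], seed=2)
        table, _ = syn.sample_counts(spec)
        assert (table.counts >= 0).all()
        assert table.counts.dtype == np.int64

    def test_library_sizes_near_depth_mean(self):
        spec = SyntheticSpec(n_samples_per_group=30, group_names=["G"],
                             n_asvs=10, module_sizes=[3], depth_mean=5000,
                             seed=3)
        table, _ = syn.sample_counts(spec)
        totals = table.sample_totals()
        assert abs(totals.mean() - 5000) < 100  # Poisson(5000) sample mean

    def test_metadata_covers_table(self):
        spec = SyntheticSpec(n_samples_per_group=3,
                             group_names=["LT", "HTB"], n_asvs=5,
                             module_sizes=[], seed=1)
        table, meta = syn.sample_counts(spec)
        meta.check_covers(table)
        assert set(meta.groups()) == {"LT", "HTB"}
        assert meta.data.loc["HTB_s01", "temperature"] == "31C"
        assert meta.data.loc["HTB_s01", "treatment"] == "bacteria"

    def test_effect_group_shifts_means(self):
        spec = SyntheticSpec(n_samples_per_group=40, group_names=["A", "B"],
                             n_asvs=10, module_sizes=[], effect_asvs=[0, 1],
                             effect_group="B", effect_size=8.0, seed=4)
        table, meta = syn.sample_counts(spec)
        rel = table.data.div(table.data.sum(axis=1), axis=0)
        in_b = meta.groups() == "B"
        assert rel.loc[in_b.values, "ASV0000"].mean() > \
            2 * rel.loc[~in_b.values, "ASV0000"].mean()

    def test_rank_correlation_fidelity(self):
        # Monte-Carlo oracle: latent rho 0.9 between a planted pair should
        # give mean empirical Spearman above the 0.7 edge threshold and near
        # the copula value (6/pi) * arcsin(rho/2)
        rhos = []
        for rep in range(60):
            spec = SyntheticSpec(n_samples_per_group=20, group_names=["G"],
                                 n_asvs=10, module_sizes=[2], rho_within=0.9,
                                 seed=1000 + rep)
            table, _ = syn.sample_counts(spec)
            rhos.append(stats.spearmanr(table.counts[:, 0],
                                        table.counts[:, 1]).statistic)
        mean_rho = np.mean(rhos)
        theory = syn.gaussian_copula_spearman(0.9)
        assert mean_rho > 0.7
        assert abs(mean_rho - theory) < 0.12  # count noise attenuates slightly


class TestTruth:
    def _truth(self):
        spec = SyntheticSpec(n_samples_per_group=3, group_names=["G"],
                             n_asvs=8, module_sizes=[3, 2],
                             connector_asvs=[(6, [0])], rho_cross=0.5,
                             effect_asvs=[7], effect_group="G",
                             effect_size=2.0, seed=0)
        return syn.ground_truth(spec)

    def test_background_labeled_none(self):
        truth = self._truth()
        assert truth.module_of["ASV0006"] == "none"
        assert truth.module_of["ASV0000"] == "M0"

    def test_export_load_round_trip(self, tmp_path):
        truth = self._truth()
        syn.export_truth(truth, tmp_path)
        again = syn.load_truth(tmp_path)
        assert again.module_of == truth.module_of
        assert again.connector_set == truth.connector_set
        assert again.differential_set == truth.differential_set
        np.testing.assert_allclose(again.latent_correlation.to_numpy(),
                                   truth.latent_correlation.to_numpy())

    def test_empty_connector_set_allowed(self, tmp_path):
        spec = SyntheticSpec(n_samples_per_group=3, group_names=["G"],
                             n_asvs=4, module_sizes=[2], seed=0)
        truth = syn.ground_truth(spec)
        syn.export_truth(truth, tmp_path)
        assert syn.load_truth(tmp_path).connector_set == set()
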