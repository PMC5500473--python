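import numpy as np
import pytest
import scipy.linalg as sla

from mena.errors import ContractError
from mena.io import AbundanceTable
from mena.network import (CorrelationMatrix, RMTCorrelationNetwork,
                          build_network, correlations, edge_sign_counts,
                          nnsd_fit, scan_threshold, unfold_spectrum)
from mena.simulate import PlantedDesign, generate_table


def goe_matrix(n, rng):
    a = rng.standard_normal((n, n))
    return (a + a.T) / np.sqrt(2 * n)


class TestCorrelations:
    def _table(self, x):
        x = np.asarray(x)
        return AbundanceTable(
            otu_ids=[f"o{i}" for i in range(x.shape[0])],
            sample_ids=[f"s{j}" for j in range(x.shape[1])],
            counts=x)

    def test_self_correlation_one(self):
        t = self._table([[1, 5, 2, 9], [4, 2, 8, 1]])
        c = correlations(t, transform="none")
        assert c.values[0, 0] == 1.0

    def test_negated_profile_minus_one(self):
        t = self._table([[1, 5, 2, 9], [9, 5, 8, 1]])  # second = 10 - first
        c = correlations(t, transform="none")
        assert c.values[0, 1] == pytest.approx(-1.0)

    def test_planted_pairs_near_design_correlation(self):
        # count rounding / pseudocount / compositional closure attenuate the
        # planted log-scale correlation slightly; the module mean stays
        # within the sampling-error band of the design value
        table, truth = generate_table(
            PlantedDesign(n_otus=150, module_sizes=(30,) * 4, seed=1))
        c = correlations(table)
        ids = c.otu_ids
        members = [ids.index(o) for o in ids if truth.partition[o] == 0
                   and truth.role_labels[o] == "peripheral"]
        sub = np.abs(c.values[np.ix_(members, members)])
        iu, ju = np.triu_indices(len(members), 1)
        assert sub[iu, ju].mean() == pytest.approx(0.9, abs=0.15)

    def test_fewer_than_four_samples_rejected(self):
        t = self._table([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ContractError):
            correlations(t)

    def test_constant_profile_zeroed(self):
        t = self._table([[2, 2, 2, 2], [1, 5, 2, 9]])
        c = correlations(t, transform="none")
        assert c.values[0, 1] == 0.0
        assert c.values[0, 0] == 1.0


class TestUnfoldSpectrum:
    def test_equally_spaced_gives_unit_spacings(self):
        s = unfold_spectrum(np.linspace(0, 1, 100))
        assert np.allclose(s, 1.0, atol=1e-6)

    def test_mean_spacing_normalized(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            ev = np.sort(rng.normal(size=200))
            s = unfold_spectrum(ev)
            assert 0.95 <= s.mean() <= 1.05

    def test_too_few_eigenvalues_rejected(self):
        with pytest.raises(ContractError):
            unfold_spectrum(np.arange(10))

    def test_goe_spectrum_closer_to_wigner(self):
        rng = np.random.default_rng(12)
        s = unfold_spectrum(np.linalg.eigvalsh(goe_matrix(200, rng)))
        assert nnsd_fit(s, "goe").statistic < nnsd_fit(s, "poisson").statistic


class TestNnsdFit:
    def test_exponential_spacings_prefer_poisson(self):
        s = np.random.default_rng(3).exponential(1.0, 500)
        assert nnsd_fit(s, "poisson").statistic < nnsd_fit(s, "goe").statistic

    def test_model_quantile_midpoints_near_zero_statistic(self):
        q = -np.log(1 - (np.arange(500) + 0.5) / 500)
        fit = nnsd_fit(q, "poisson")
        assert fit.statistic < 1.0
        assert fit.pvalue > 0.99

    def test_superposed_blocks_prefer_poisson(self):
        rng = np.random.default_rng(7)
        m = sla.block_diag(goe_matrix(100, rng), goe_matrix(100, rng))
        s = unfold_spectrum(np.linalg.eigvalsh(m))
        assert nnsd_fit(s, "poisson").statistic < nnsd_fit(s, "goe").statistic


class TestScanThreshold:
    def test_identity_matrix_no_transition(self):
        c = CorrelationMatrix(otu_ids=[f"o{i}" for i in range(60)],
                              values=np.eye(60))
        scan = scan_threshold(c)
        assert scan.no_transition

    def test_synthetic_transition_and_monotonicity(self):
        table, _ = generate_table(
            PlantedDesign(n_otus=150, module_sizes=(30,) * 4, seed=0))
        scan = scan_threshold(correlations(table))
        assert not scan.no_transition
        assert 0.3 <= scan.chosen_threshold < 1.0
        assert all(a >= b for a, b in zip(scan.n_nodes, scan.n_nodes[1:]))


class TestBuildNetwork:
    def _corr(self):
        v = np.array([[1.0, 0.9, -0.8], [0.9, 1.0, 0.1], [-0.8, 0.1, 1.0]])
        return CorrelationMatrix(otu_ids=["a", "b", "c"], values=v)

    def test_signed_edges(self):
        g = build_network(self._corr(), 0.8)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert edge_sign_counts(g) == (1, 1)
        assert g.edges["a", "c"]["sign"] == -1
        assert g.edges["a", "b"]["weight"] == pytest.approx(0.9)

    def test_threshold_one_empty(self):
        g = build_network(self._corr(), 1.0)
        assert g.number_of_edges() == 0

    def test_sign_counts_sum_to_total(self):
        table, _ = generate_table(
            PlantedDesign(n_otus=150, module_sizes=(30,) * 4, seed=2))
        g = build_network(correlations(table), 0.6)
        pos, neg = edge_sign_counts(g)
        assert pos + neg == g.number_of_edges()
        assert neg > 0  # planted negative associations survive

    def test_edge_sets_nested_across_thresholds(self):
        table, _ = generate_table(
            PlantedDesign(n_otus=150, module_sizes=(30,) * 4, seed=3))
        c = correlations(table)
        e_low = set(map(frozenset, build_network(c, 0.5).edges))
        e_high = set(map(frozenset, build_network(c, 0.7).edges))
        assert e_high <= e_low


class TestRMTCorrelationNetworkEstimator:
    def test_sklearn_api(self):
        est = RMTCorrelationNetwork(min_nodes=30)
        params = est.get_params()
        assert params["st_min"] == 0.30
        est.set_params(step=0.02)
        assert est.step == 0.02

    def test_fit_on_matrix(self):
        table, _ = generate_table(
            PlantedDesign(n_otus=150, module_sizes=(30,) * 4, seed=4))
        X = table.counts.T  # samples x OTUs, sklearn orientation
        est = RMTCorrelationNetwork().fit(X)
        assert est.graph_.number_of_nodes() == est.n_nodes_ > 0
        assert est.threshold_ == est.scan_.chosen_threshold

    def test_fixed_threshold_skips_scan(self, tiny_table):
        table, _ = generate_table(
            PlantedDesign(n_otus=60, module_sizes=(15,) * 4, n_connectors=0,
                          seed=5))
        est = RMTCorrelationNetwork(threshold=0.8).fit(table)
        assert est.scan_ is None
        assert all(d["weight"] >= 0.8
                   for _, _, d in est.graph_.edges(data=True))
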