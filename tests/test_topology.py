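import networkx as nx
import numpy as np
import pytest

from _oracles import (brute_force_best_q, longhand_avg_cc, longhand_gd,
                      longhand_modularity)
from mena.errors import ContractError
from mena.io import AbundanceTable
from mena.simulate import PlantedDesign, generate_table, generate_toy_graph
from mena.topology import (FastGreedyCommunities, ModulePartition,
                           classify_role, fast_greedy_modules,
                           maslov_sneppen, modularity, module_membership,
                           network_indices, node_roles, null_model_test,
                           zi_pi)


def random_graph(seed, n_max=30):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.5)), seed=seed)
    if g.number_of_edges() == 0:
        g.add_edge(0, 1)
    return g


class TestModularity:
    def test_single_module_zero(self):
        g = nx.complete_graph(5)
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_two_triangles_true_partition(self):
        g, truth = generate_toy_graph("two_cliques", clique_size=3)
        assert modularity(g, truth.partition) == pytest.approx(0.5)

    def test_matches_longhand_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            g = random_graph(seed)
            assignment = {n: int(rng.integers(3)) for n in g.nodes}
            assert modularity(g, assignment) == pytest.approx(
                longhand_modularity(g, assignment), abs=1e-12)

    def test_missing_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ContractError):
            modularity(g, {0: 0, 1: 0})


class TestFastGreedy:
    def test_two_triangles_optimal(self):
        g, truth = generate_toy_graph("two_cliques", clique_size=3)
        part = fast_greedy_modules(g)
        assert part.modularity_q == pytest.approx(0.5)
        found = {frozenset(part.members(m)) for m in part.module_sizes}
        expected = {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        assert found == expected

    def test_complete_graph_single_module(self):
        part = fast_greedy_modules(nx.complete_graph(5))
        assert part.n_modules == 1
        assert part.modularity_q == pytest.approx(0.0)

    def test_ring_of_cliques_recovers_ground_truth(self):
        g, truth = generate_toy_graph("ring_of_cliques", n_cliques=4,
                                      clique_size=5)
        part = fast_greedy_modules(g)
        assert part.n_modules == 4
        found = {frozenset(part.members(m)) for m in part.module_sizes}
        expected = set()
        for m in set(truth.partition.values()):
            expected.add(frozenset(n for n, mm in truth.partition.items()
                                   if mm == m))
        assert found == expected

    def test_never_beats_brute_force_and_ties_on_cliques(self):
        for seed in range(8):
            g = random_graph(seed, n_max=8)
            part = fast_greedy_modules(g)
            best = brute_force_best_q(g)
            assert part.modularity_q <= best + 1e-9

    def test_deterministic(self):
        g = random_graph(11)
        p1 = fast_greedy_modules(g)
        p2 = fast_greedy_modules(g)
        assert p1.assignment == p2.assignment

    def test_empty_network_rejected(self):
        with pytest.raises(ContractError):
            fast_greedy_modules(nx.Graph())

    def test_comparable_to_networkx_cnm(self):
        # independent CNM implementation should find comparable modularity
        for seed in (0, 1, 2):
            g, _ = generate_toy_graph("ring_of_cliques", n_cliques=3,
                                      clique_size=4 + seed)
            part = fast_greedy_modules(g)
            nx_comms = nx.community.greedy_modularity_communities(g)
            nx_q = nx.community.modularity(g, nx_comms)
            assert part.modularity_q == pytest.approx(nx_q, abs=1e-9)

    def test_estimator_wrapper(self):
        g, _ = generate_toy_graph("two_cliques", clique_size=4)
        est = FastGreedyCommunities().fit(g)
        assert est.n_modules_ == 2
        assert est.modularity_ == est.partition_.modularity_q


class TestNetworkIndices:
    def test_path_graph_hand_computed(self):
        g = nx.path_graph(3)
        idx = network_indices(g)
        assert idx.avg_connectivity == pytest.approx(4 / 3)
        assert idx.gd == pytest.approx(4 / 3)
        assert idx.avg_cc == 0.0

    def test_triangle(self):
        idx = network_indices(nx.complete_graph(3))
        assert idx.gd == 1.0
        assert idx.avg_cc == 1.0
        assert idx.avg_connectivity == 2.0

    def test_two_components_within_pairs_only(self):
        g = nx.disjoint_union(nx.path_graph(2), nx.path_graph(2))
        assert network_indices(g).gd == 1.0

    def test_longhand_oracle_equivalence(self):
        for seed in range(20):
            g = random_graph(seed)
            part = fast_greedy_modules(g)
            idx = network_indices(g, part)
            assert idx.gd == pytest.approx(longhand_gd(g), abs=1e-9)
            assert idx.avg_cc == pytest.approx(longhand_avg_cc(g), abs=1e-9)
            assert idx.modularity_q == pytest.approx(
                longhand_modularity(g, part.assignment), abs=1e-9)


class TestZiPi:
    def test_all_edges_internal_pi_zero(self):
        g = nx.star_graph(4)  # center 0
        part = ModulePartition(assignment={n: 0 for n in g.nodes})
        zp = zi_pi(g, part)
        assert zp[0][1] == 0.0

    def test_even_spread_pi(self):
        g, truth = generate_toy_graph("star_plus_modules", n_modules=4,
                                      clique_size=4)
        part = ModulePartition(assignment=dict(truth.partition))
        hub = 16
        part.assignment[hub] = 0  # assign connector to a module
        part = ModulePartition(assignment=part.assignment)
        zp = zi_pi(g, part)
        assert zp[hub][1] == pytest.approx(0.75)

    def test_zi_sums_to_zero_within_modules(self):
        g = random_graph(5)
        part = fast_greedy_modules(g)
        zp = zi_pi(g, part)
        for m in part.module_sizes:
            zis = [zp[n][0] for n in part.members(m)]
            assert sum(zis) == pytest.approx(0.0, abs=1e-9)

    def test_isolated_node_zeroed(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        part = ModulePartition(assignment={0: 0, 1: 0, 2: 1})
        assert zi_pi(g, part)[2] == (0.0, 0.0)


class TestClassifyRole:
    @pytest.mark.parametrize("zi,pi,role", [
        (3.0, 0.5, "module_hub"),
        (2.5, 0.62, "peripheral"),
        (1.0, 0.75, "connector"),
        (2.6, 0.7, "network_hub"),
        (2.5, 0.63, "connector"),
        (2.51, 0.62, "module_hub"),
        (-1.0, 0.0, "peripheral"),
    ])
    def test_threshold_grid(self, zi, pi, role):
        assert classify_role(zi, pi) == role

    def test_total_function_on_networks(self):
        g = random_graph(9)
        part = fast_greedy_modules(g)
        roles = node_roles(g, part)
        assert len(roles) == g.number_of_nodes()
        assert all(r["role"] in {"peripheral", "connector", "module_hub",
                                 "network_hub"} for r in roles)


class TestModuleMembership:
    def _table(self, x):
        x = np.asarray(x)
        return AbundanceTable(
            otu_ids=[f"o{i}" for i in range(x.shape[0])],
            sample_ids=[f"s{j}" for j in range(x.shape[1])],
            counts=x)

    def test_identical_profiles_membership_one(self):
        t = self._table([[1, 5, 2, 9]] * 3)
        part = ModulePartition(assignment={"o0": 0, "o1": 0, "o2": 0})
        memb = module_membership(t, part, 0)
        assert all(v == pytest.approx(1.0) for v in memb.values())

    def test_negated_profile_membership_minus_one(self):
        t = self._table([[1, 5, 2, 9], [1, 5, 2, 9], [9, 5, 8, 1]])
        part = ModulePartition(assignment={"o0": 0, "o1": 0, "o2": 0})
        memb = module_membership(t, part, 0)
        assert memb["o0"] == pytest.approx(1.0)
        assert memb["o2"] == pytest.approx(-1.0)

    def test_planted_module_high_membership(self):
        table, truth = generate_table(
            PlantedDesign(n_otus=150, module_sizes=(30,) * 4, seed=6))
        part = ModulePartition(
            assignment={o: m for o, m in truth.partition.items() if m != -1})
        sub_ids = [o for o in table.otu_ids if o in part.assignment]
        idx = [table.otu_ids.index(o) for o in sub_ids]
        sub = AbundanceTable(otu_ids=sub_ids,
                             sample_ids=table.sample_ids,
                             counts=table.counts[idx])
        memb = module_membership(sub, part, 0)
        assert np.median(np.abs(list(memb.values()))) >= 0.8


class TestMaslovSneppen:
    def test_degree_sequence_preserved(self):
        for seed in range(10):
            g = random_graph(seed)
            nx.set_edge_attributes(g, 1, "sign")
            r = maslov_sneppen(g, swaps_per_edge=20, seed=seed)
            assert sorted(d for _, d in r.degree) == \
                sorted(d for _, d in g.degree)

    def test_sign_counts_preserved(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        for u, v in g.edges:
            g.edges[u, v]["sign"] = int(rng.choice([-1, 1]))
        pos_before = sum(1 for *_, d in g.edges(data=True) if d["sign"] > 0)
        r = maslov_sneppen(g, swaps_per_edge=50, seed=2)
        pos_after = sum(1 for *_, d in r.edges(data=True) if d["sign"] > 0)
        assert pos_before == pos_after

    def test_triangle_returned_unchanged(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, 1, "sign")
        r = maslov_sneppen(g, swaps_per_edge=10, seed=0)
        assert set(map(frozenset, r.edges)) == set(map(frozenset, g.edges))

    def test_deterministic_given_seed(self):
        g = random_graph(4)
        a = maslov_sneppen(g, swaps_per_edge=30, seed=9)
        b = maslov_sneppen(g, swaps_per_edge=30, seed=9)
        assert set(a.edges) == set(b.edges)


class TestNullModelTest:
    def test_ring_of_cliques_strong_structure(self):
        g, _ = generate_toy_graph("ring_of_cliques", n_cliques=4,
                                  clique_size=5)
        reps = null_model_test(g, n_random=50, swaps_per_edge=50, seed=42)
        z = {r.index: r.z_score for r in reps}
        assert z["modularity"] > 3

    def test_degenerate_rewires_flagged(self):
        g = nx.complete_graph(3)  # no legal swap: all rewires identical
        nx.set_edge_attributes(g, 1, "sign")
        reps = null_model_test(g, n_random=2, swaps_per_edge=10, seed=0)
        assert all(r.degenerate and r.p_value == 1.0 for r in reps)

    def test_reproducible_bit_for_bit(self):
        g, _ = generate_toy_graph("ring_of_cliques", n_cliques=3,
                                  clique_size=4)
        a = null_model_test(g, n_random=10, swaps_per_edge=20, seed=5)
        b = null_model_test(g, n_random=10, swaps_per_edge=20, seed=5)
        assert [(r.z_score, r.p_value) for r in a] == \
            [(r.z_score, r.p_value) for r in b]
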