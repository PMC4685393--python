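"""Two-stage module evaluation: empirical null, degree bins, topology test."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from netgwas import evaluate as ev
from netgwas import simulate as sim
from netgwas.errors import DataError, EstimationError, SamplingError
from netgwas.search import Module, module_score


class TestEmpiricalNull:
    def test_standard_normal_recovery(self):
        rng = np.random.default_rng(1)
        null = ev.fit_empirical_null(rng.normal(0, 1, 10_000))
        assert -0.05 <= null.mu <= 0.05
        assert 0.95 <= null.sigma <= 1.05

    def test_location_removed_scale_recovered(self):
        rng = np.random.default_rng(2)
        null = ev.fit_empirical_null(rng.normal(3, 2, 10_000))
        assert abs(null.mu) < 0.1
        assert 1.9 <= null.sigma <= 2.1

    def test_right_contamination_resistance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 10_000)
        scores[:500] = 8.0 + rng.normal(0, 0.5, 500)   # 5% right outliers
        null = ev.fit_empirical_null(scores)
        assert 0.9 <= null.sigma <= 1.15

    def test_mle_fallback_agrees_roughly(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(1, 1.5, 5_000)
        a = ev.fit_empirical_null(scores, method="central_matching")
        b = ev.fit_empirical_null(scores, method="mle")
        assert abs(a.sigma - b.sigma) < 0.15
        assert b.method == "mle"

    def test_constant_scores_raise(self):
        with pytest.raises(EstimationError):
            ev.fit_empirical_null(np.ones(100))


class TestNormalStagePvalues:
    def test_center_maps_to_half(self):
        null = ev.NullDistribution(0.0, 1.0, "central_matching", 100)
        scores = np.array([0.0, 1.0, 2.0, -1.0])
        p = ev.normal_stage_pvalues(scores + 5.0, null)  # median-centering removes +5
        assert p[np.argsort(scores)[-1]] == p.min()
        med_p = ev.normal_stage_pvalues(np.array([3.0, 3.0, 3.0, 4.0]), null)
        assert med_p[0] == pytest.approx(0.5)

    def test_quantile_value(self):
        null = ev.NullDistribution(0.0, 1.0, "central_matching", 100)
        # centered score 1.6449 at sigma 1 -> p = 0.05
        scores = np.array([0.0, -1.6449, 1.6449 * 2])
        centered = scores - np.median(scores)
        p = ev.normal_stage_pvalues(scores, null)
        assert p[2] == pytest.approx(stats.norm.sf(centered[2]), abs=1e-9)

    def test_monotone_decreasing_in_score(self):
        null = ev.NullDistribution(0.0, 2.0, "central_matching", 100)
        scores = np.linspace(-3, 3, 20)
        p = ev.normal_stage_pvalues(scores, null)
        assert np.all(np.diff(p) < 0)


class TestDegreeBins:
    def test_eight_node_quartiles(self):
        g = nx.Graph()
        for deg in range(1, 9):   # node d{deg} gets exactly degree deg
            for j in range(deg):
                g.add_edge(f"d{deg}", f"leaf{deg}_{j}")
        sub_degrees = {f"d{d}": d for d in range(1, 9)}
        bins = ev.assign_degree_bins(g)
        got = {n: bins.assignment[n] for n in sub_degrees}
        vals = np.array([d for _, d in g.degree()], dtype=float)
        expect = {n: int(np.sum(d > np.quantile(vals, [0.25, 0.5, 0.75])))
                  for n, d in sub_degrees.items()}
        assert got == expect

    def test_quartile_example_on_degree_sequence(self):
        # degrees 1..8 split into {1,2},{3,4},{5,6},{7,8}
        b = np.quantile(np.arange(1, 9, dtype=float), [0.25, 0.5, 0.75])
        binned = {d: int(np.sum(d > b)) for d in range(1, 9)}
        assert binned == {1: 0, 2: 0, 3: 1, 4: 1, 5: 2, 6: 2, 7: 3, 8: 3}

    def test_equal_degrees_single_bin(self):
        g = nx.cycle_graph(6)
        bins = ev.assign_degree_bins(g)
        assert set(bins.assignment.values()) == {0}

    def test_partition_covers_all_nodes(self, benchmark_dataset):
        g = benchmark_dataset.network
        bins = ev.assign_degree_bins(g)
        assert len(bins.assignment) == g.number_of_nodes()
        assert sum(bins.counts()) == g.number_of_nodes()


@pytest.fixture(scope="module")
def annotated():
    ds = sim.simulate_dataset(sim.SyntheticConfig(seed=23, signal_p_max=1.0,
                                                  n_mhc=0))
    g, _ = sim.annotate_dataset(ds)
    return g, ev.assign_degree_bins(g)


class TestTopologyPermutation:
    def test_extreme_module_attains_floor(self, annotated):
        g, bins = annotated
        genes = sorted(g.nodes)[:5]
        mod = Module(seed=genes[0], genes=frozenset(genes), score=1e6)
        p = ev.topo_permutation_pvalue(g, mod, bins, n_perm=1_000, seed=0)
        assert p == pytest.approx(1 / 1_001)

    def test_median_module_near_half(self, annotated):
        g, bins = annotated
        rng = np.random.default_rng(7)
        nodes = sorted(g.nodes)
        pick = [nodes[i] for i in rng.choice(len(nodes), 6, replace=False)]
        probe = Module(seed=pick[0], genes=frozenset(pick), score=0.0)
        # place the observed score at the empirical median of its own null
        p = ev.topo_permutation_pvalue(g, probe, bins, n_perm=100, seed=1)
        z = [g.nodes[n]["z"] for n in pick]
        mod = Module(seed=pick[0], genes=frozenset(pick), score=module_score(z))
        assert 0 < p <= 1
        p_self = ev.topo_permutation_pvalue(g, mod, bins, n_perm=100, seed=1)
        assert p_self > p or mod.score <= 0

    def test_reproducible_under_seed(self, annotated):
        g, bins = annotated
        genes = sorted(g.nodes)[10:16]
        z = [g.nodes[n]["z"] for n in genes]
        mod = Module(seed=genes[0], genes=frozenset(genes), score=module_score(z))
        p1 = ev.topo_permutation_pvalue(g, mod, bins, n_perm=500, seed=42)
        p2 = ev.topo_permutation_pvalue(g, mod, bins, n_perm=500, seed=42)
        assert p1 == p2

    def test_null_sampler_matches_degree_profile(self, annotated):
        g, bins = annotated
        rng = np.random.default_rng(11)
        nodes = sorted(g.nodes)
        pick = [nodes[i] for i in rng.choice(len(nodes), 8, replace=False)]
        profile = {}
        for n in pick:
            profile[bins.assignment[n]] = profile.get(bins.assignment[n], 0) + 1
        for _ in range(20):
            m = ev.sample_null_module(g, bins, profile, rng)
            assert len(m.genes) == 8
            got = {}
            for n in m.genes:
                got[bins.assignment[n]] = got.get(bins.assignment[n], 0) + 1
            assert got == profile

    def test_calibrated_on_null_modules(self, annotated):
        """p_topo for modules drawn from the degree-matched null is uniform."""
        g, bins = annotated
        pools = ev._bin_pools(g, bins)
        rng = np.random.default_rng(19)
        nodes = sorted(g.nodes)
        ps = []
        for _ in range(200):
            pick = rng.choice(len(nodes), size=8, replace=False)
            profile = {}
            for j in pick:
                b = bins.assignment[nodes[j]]
                profile[b] = profile.get(b, 0) + 1
            m = ev.sample_null_module(g, bins, profile, rng, _pools=pools)
            ps.append(ev.topo_permutation_pvalue(g, m, bins, n_perm=500,
                                                 seed=rng, _pools=pools))
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.09   # binomial 99% interval around 0.05, n=200

    def test_oversubscribed_bin_raises(self):
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for n in ("n0", "n1", "n2"):
            g.nodes[n].update(z=0.0, weighted=True)
        g.nodes["n3"].update(weighted=False)   # degree-1 bin: 2 genes, 1 weighted
        bins = ev.assign_degree_bins(g)
        mod = Module(seed="n0", genes=frozenset(["n0", "n3"]), score=0.0)
        with pytest.raises(SamplingError, match="bin"):
            ev.topo_permutation_pvalue(g, mod, bins, n_perm=10, seed=0)


class TestSelectAndMerge:
    def _evaluated(self, module, p_norm, p_topo):
        return ev.EvaluatedModule(module=module, score_centered=0.0,
                                  score_standardized=0.0, p_norm=p_norm,
                                  p_topo=p_topo, n_perm=100)

    @pytest.fixture
    def net(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
                          ("E", "F"), ("F", "G")])
        for n in g.nodes:
            g.nodes[n].update(weighted=True, z=0.0)
        g.add_node("S1")  # sigMHC singleton, no edges to candidates
        return g

    def test_union_of_survivors(self, net):
        m1 = Module("A", frozenset("ABC"), 3.0)
        m2 = Module("C", frozenset("CD"), 2.0)
        evaluated = [self._evaluated(m1, 0.01, 0.01),
                     self._evaluated(m2, 0.01, 0.01)]
        core, _ = ev.select_and_merge(evaluated, net, [])
        assert set(core.nodes) == {"A", "B", "C", "D"}

    def test_conjunction_rule_excludes(self, net):
        m1 = Module("A", frozenset("ABC"), 3.0)
        m2 = Module("E", frozenset("EF"), 2.0)
        evaluated = [self._evaluated(m1, 0.04, 0.2),   # fails stage 2
                     self._evaluated(m2, 0.01, 0.01)]
        core, _ = ev.select_and_merge(evaluated, net, [])
        assert set(core.nodes) == {"E", "F"}

    def test_sigmhc_singleton_in_extended(self, net):
        m1 = Module("A", frozenset("AB"), 3.0)
        evaluated = [self._evaluated(m1, 0.01, 0.01)]
        core, extended = ev.select_and_merge(evaluated, net, ["S1"])
        assert "S1" not in core
        assert "S1" in extended
        assert extended.degree("S1") == 0
        assert extended.nodes["S1"]["role"] == "sigMHC_gene"

    def test_empty_selection_yields_empty_graphs(self, net):
        m1 = Module("A", frozenset("AB"), 3.0)
        evaluated = [self._evaluated(m1, 0.5, None)]
        core, extended = ev.select_and_merge(evaluated, net, ["S1"])
        assert core.number_of_nodes() == 0
        assert set(extended.nodes) == {"S1"}
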