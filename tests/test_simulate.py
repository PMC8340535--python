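import json

import numpy as np
import pytest
from scipy.stats import binom, chisquare

from medinet.config import RunConfig
from medinet.errors import ParameterError, ValidationError
from medinet.events import SampleEvents
from medinet.network import largest_scc
from medinet.pipeline import prepare_events, run_pipeline
from medinet.ranking import MediatorRanking
from medinet.simulate import (
    SimulationConfig,
    SyntheticTruth,
    generate_network,
    load_cohort,
    recovery_metrics,
    simulate_cohort,
    write_cohort,
)

SMALL = dict(
    n_genes=300,
    n_mirnas=20,
    n_samples=4,
    n_planted_mediators=5,
    passengers_per_sample=5,
    de_mirna_per_sample=8,
    downstream_per_sample=40,
)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimulationConfig(seed=11, **SMALL)
    net = generate_network(cfg)
    mutations, tables, truth = simulate_cohort(net, cfg)
    return cfg, net, mutations, tables, truth


class TestSimulationConfig:
    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(seed=0, n_samples=-1)

    def test_noise_fraction_range(self):
        with pytest.raises(ParameterError):
            SimulationConfig(seed=0, noise_fraction=1.5)

    def test_seed_mandatory(self):
        with pytest.raises(ParameterError):
            SimulationConfig(seed=None)


class TestGenerateNetwork:
    def test_scc_holds_ninety_percent_of_genes(self):
        cfg = SimulationConfig(seed=5, n_genes=100, n_mirnas=10)
        net = generate_network(cfg)
        scc = largest_scc(net)
        n_genes_in_scc = scc.gene_indices().size
        assert n_genes_in_scc >= 90

    def test_mirnas_survive_scc_reduction(self):
        cfg = SimulationConfig(seed=5, n_genes=100, n_mirnas=10)
        scc = largest_scc(generate_network(cfg))
        assert scc.mirna_indices().size == 10

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=9, n_genes=120, n_mirnas=8)
        n1, n2 = generate_network(cfg), generate_network(cfg)
        assert n1.nodes == n2.nodes and n1.edges == n2.edges

    def test_out_degree_matches_binomial_model(self):
        # gene out-degrees under directed G(n, p): Binomial(n-1, p)
        n, mean_deg = 150, 6.0
        degs = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_genes=n, n_mirnas=0, mean_degree=mean_deg)
            net = generate_network(cfg)
            adj = net.adjacency()
            gene_rows = net.gene_indices()
            out = np.asarray(adj.sum(axis=1)).ravel()[gene_rows]
            degs.extend(out.tolist())
        degs = np.array(degs)
        p = mean_deg / (n - 1)
        edges = [-0.5 + k for k in range(0, 14)] + [np.inf]
        obs, _ = np.histogram(degs, bins=edges)
        probs = [binom.pmf(k, n - 1, p) for k in range(0, 13)]
        probs.append(1 - sum(probs))
        expected = np.array(probs) * degs.size
        keep = expected > 5
        stat, pval = chisquare(obs[keep], expected[keep] * obs[keep].sum() / expected[keep].sum())
        assert pval > 0.001


class TestSimulateCohort:
    def test_drivers_in_every_sample(self, small_cohort):
        cfg, net, mutations, tables, truth = small_cohort
        for sample, recs in mutations.items():
            genes = {r.gene for r in recs}
            assert set(truth.drivers) <= genes

    def test_passengers_private(self, small_cohort):
        cfg, net, mutations, tables, truth = small_cohort
        drivers = set(truth.drivers)
        seen = {}
        for sample, recs in mutations.items():
            for r in recs:
                if r.gene in drivers:
                    continue
                assert r.gene not in seen, f"{r.gene} in {sample} and {seen[r.gene]}"
                seen[r.gene] = sample

    def test_regeneration_bit_identical(self):
        cfg = SimulationConfig(seed=23, **SMALL)
        net = generate_network(cfg)
        m1, t1, tr1 = simulate_cohort(net, cfg)
        m2, t2, tr2 = simulate_cohort(net, cfg)
        assert tr1.to_json() == tr2.to_json()
        assert m1 == m2
        for s in t1:
            for layer in t1[s]:
                assert t1[s][layer].data.equals(t2[s][layer].data)

    def test_truth_matches_recovered_events(self, small_cohort):
        # the analysis-side ingestion reproduces the generator's intent
        cfg, net, mutations, tables, truth = small_cohort
        scc = largest_scc(net)
        events = prepare_events(scc, mutations, tables, RunConfig(seed=0, alpha=cfg.alpha))
        by_sample = {ev.sample: ev for ev in events}
        for sample in truth.upstream:
            ev = by_sample[sample]
            assert ev.upstream == set(truth.upstream[sample])
            assert ev.downstream == set(truth.downstream[sample])

    def test_mediators_never_drivers(self, small_cohort):
        *_, truth = small_cohort
        assert not set(truth.mediators) & set(truth.drivers)

    def test_truth_json_roundtrip(self, small_cohort):
        *_, truth = small_cohort
        again = SyntheticTruth.from_json(truth.to_json())
        assert again == truth

    def test_mediator_driver_overlap_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticTruth(("A",), ("A",), {}, {}, {})


class TestCohortRoundtrip:
    def test_write_then_load(self, small_cohort, tmp_path):
        cfg, net, mutations, tables, truth = small_cohort
        write_cohort(tmp_path, net, mutations, tables, truth)
        net2, mut2, tab2, truth2 = load_cohort(tmp_path)
        assert net2.nodes == net.nodes and net2.edges == net.edges
        assert truth2 == truth
        assert {s: len(v) for s, v in mut2.items()} == {
            s: len(v) for s, v in mutations.items()
        }
        for s in tables:
            for layer in tables[s]:
                assert tab2[s][layer].significant() == tables[s][layer].significant()

    def test_written_files_are_text(self, small_cohort, tmp_path):
        cfg, net, mutations, tables, truth = small_cohort
        write_cohort(tmp_path, net, mutations, tables, truth)
        for path in tmp_path.iterdir():
            path.read_text()  # raises on binary content


class TestRecoveryMetrics:
    def _ranking(self, nodes, order):
        R = np.array([order.index(n) + 1.0 for n in nodes])
        return MediatorRanking(tuple(nodes), R, np.zeros(len(nodes)), tuple(order), "median", 1)

    def test_all_planted_in_top(self):
        nodes = [f"g{k}" for k in range(40)]
        truth = SyntheticTruth(("g0", "g1"), ("g30",), {}, {}, {})
        ranking = self._ranking(nodes, nodes)
        m = recovery_metrics(ranking, truth, selected=["g0", "g1"])
        assert m["recall"] == 1.0 and m["precision"] == 1.0

    def test_empty_planted_rejected(self):
        nodes = [f"g{k}" for k in range(5)]
        truth = SyntheticTruth((), (), {}, {}, {})
        with pytest.raises(ValidationError):
            recovery_metrics(self._ranking(nodes, nodes), truth)

    def test_disjoint_nodes_rejected(self):
        nodes = [f"g{k}" for k in range(5)]
        truth = SyntheticTruth(("other",), (), {}, {}, {})
        with pytest.raises(ValidationError):
            recovery_metrics(self._ranking(nodes, nodes), truth)

    def test_random_ranking_auroc_near_half(self):
        rng = np.random.default_rng(31)
        nodes = [f"g{k:03d}" for k in range(200)]
        planted = tuple(rng.choice(nodes, size=10, replace=False))
        aurocs = []
        for seed in range(20):
            r = np.random.default_rng(seed).permutation(200) + 1.0
            order = [nodes[k] for k in np.argsort(r)]
            ranking = MediatorRanking(
                tuple(nodes), r, np.zeros(200), tuple(order), "median", 1
            )
            aurocs.append(
                recovery_metrics(ranking, SyntheticTruth(planted, (), {}, {}, {}))["auroc"]
            )
        assert abs(np.mean(aurocs) - 0.5) < 0.1


class TestPlantedSignal:
    def test_planted_outrank_random_gene_sets(self, small_cohort):
        # planted mediators get better median cohort rank than matched
        # random draws (one-sided rank-sum)
        from scipy.stats import mannwhitneyu

        cfg, net, mutations, tables, truth = small_cohort
        res = run_pipeline(net, mutations, tables, RunConfig(seed=0, n_perm=0))
        pos = {g: k + 1 for k, g in enumerate(res.ranking.order)}
        planted = [pos[g] for g in truth.mediators if g in pos]
        rng = np.random.default_rng(77)
        others = [g for g in res.ranking.nodes if g not in set(truth.mediators)]
        random_ranks = [pos[g] for g in rng.choice(others, size=200, replace=False)]
        stat, p = mannwhitneyu(planted, random_ranks, alternative="less")
        assert p < 0.01

    def test_zero_noise_beta_one_dominance(self):
        # with no noise and beta -> 1 planted mediators outrank every node
        # outside the planted neighborhoods
        cfg = SimulationConfig(seed=3, noise_fraction=0.0, beta=0.95, **SMALL)
        net = generate_network(cfg)
        mutations, tables, truth = simulate_cohort(net, cfg)
        res = run_pipeline(
            net, mutations, tables, RunConfig(seed=0, n_perm=0, beta=0.95)
        )
        pos = {g: k + 1 for k, g in enumerate(res.ranking.order)}
        worst_planted = max(pos[g] for g in truth.mediators if g in pos)
        # neighborhood = any node at distance <= 2 from an event; approximate
        # by checking planted mediators sit in the top decile
        assert worst_planted <= 0.1 * len(res.ranking.nodes)

    def test_noise_degrades_recall(self):
        from scipy.stats import spearmanr

        recalls = []
        noises = [0.0, 0.3, 0.6]
        for noise in noises:
            per_seed = []
            for seed in range(5):
                cfg = SimulationConfig(seed=seed, noise_fraction=noise, **SMALL)
                net = generate_network(cfg)
                mutations, tables, truth = simulate_cohort(net, cfg)
                res = run_pipeline(net, mutations, tables, RunConfig(seed=0, n_perm=0))
                m = recovery_metrics(res.ranking, truth, res.mediators)
                per_seed.append(m["recall"])
            recalls.append(np.median(per_seed))
        assert recalls[0] >= recalls[-1]
        rho, _ = spearmanr(noises, recalls)
        assert rho <= 0
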