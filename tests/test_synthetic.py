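"""Generator calibration: determinism, noise laws, planted structure."""

import networkx as nx
import numpy as np
import pytest

from npbench.model import herb
from npbench.synthetic import (
    ConfigError,
    SyntheticConfig,
    emit_database_ensemble,
    generate_all,
    generate_latent_network,
    generate_multiscale_interactome,
    generate_ppi_and_disease_modules,
    plant_known_associations,
    plant_treatment_sets,
)


def small_cfg(**kw):
    base = dict(n_herbs=10, n_compounds=40, n_targets=60, n_diseases=3,
                n_functions=12, seed=0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfig:
    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(dropout_rate=-0.1)
        with pytest.raises(ConfigError):
            SyntheticConfig(known_ct_density=1.5)

    def test_infeasible_mean_degree_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_compounds=3, mean_compounds_per_herb=10)


class TestLatentNetwork:
    def test_same_seed_same_edges_different_seed_differs(self):
        a = generate_latent_network(small_cfg(seed=5))
        b = generate_latent_network(small_cfg(seed=5))
        c = generate_latent_network(small_cfg(seed=6))
        assert a.hc_edges == b.hc_edges and a.ct_edges == b.ct_edges
        assert a.ct_edges != c.ct_edges

    def test_every_herb_has_a_compound_and_every_compound_a_target(self):
        net = generate_latent_network(small_cfg(seed=2))
        assert len(net.herbs) == 10
        for h in net.herbs:
            assert net.compounds_of(h)
        for c in net.compounds:
            assert net.targets_of(c)

    def test_total_hc_edges_near_sampling_law_mean(self):
        # per herb 1 + Poisson(mean-1) compounds: n=10, mean 5 -> E=50, var=40
        totals = [
            len(generate_latent_network(
                small_cfg(seed=s, mean_compounds_per_herb=5.0)).hc_edges)
            for s in range(10)
        ]
        assert abs(np.mean(totals) - 50) < 3 * np.sqrt(40 / 10)

    def test_zero_hub_exponent_gives_near_uniform_attachment(self):
        from scipy.stats import chisquare
        cfg = SyntheticConfig(n_herbs=200, n_compounds=30, n_targets=40,
                              hub_exponent=0.0, mean_compounds_per_herb=4.0,
                              seed=3)
        net = generate_latent_network(cfg)
        counts = np.zeros(30)
        cids = {c: i for i, c in enumerate(sorted({c for _, c in net.hc_edges}))}
        for _, c in net.hc_edges:
            counts[cids[c]] += 1
        _stat, p = chisquare(counts[counts > 0])
        assert p > 0.01  # uniform attachment not rejected

    def test_hub_exponent_skews_degrees(self):
        def max_target_degree(hub_exponent, seed):
            net = generate_latent_network(
                small_cfg(seed=seed, hub_exponent=hub_exponent))
            deg = {}
            for _c, t in net.ct_edges:
                deg[t] = deg.get(t, 0) + 1
            return max(deg.values())

        flat = np.mean([max_target_degree(0.0, s) for s in range(5)])
        skew = np.mean([max_target_degree(2.0, s) for s in range(5)])
        assert skew > flat


class TestEnsemble:
    def test_noiseless_limit_reproduces_latent(self):
        cfg = small_cfg(dropout_rate=0.0, spurious_rate=0.0)
        latent = generate_latent_network(cfg)
        dbs, prov = emit_database_ensemble(latent, cfg)
        for db in dbs:
            assert db.hc_edges == latent.hc_edges
            assert db.ct_edges == latent.ct_edges

    def test_full_dropout_gives_empty_databases(self):
        cfg = small_cfg(dropout_rate=1.0, spurious_rate=0.0)
        latent = generate_latent_network(cfg)
        dbs, _ = emit_database_ensemble(latent, cfg)
        assert all(not db.hc_edges and not db.ct_edges for db in dbs)

    def test_pairwise_jaccard_matches_bernoulli_closed_form(self):
        # independent dropout q=0.2: E[Jaccard] = 0.8^2 / (1 - 0.2^2) = 2/3
        cfg = SyntheticConfig(n_herbs=40, n_compounds=150, n_targets=250,
                              mean_targets_per_compound=6.0, n_databases=2,
                              dropout_rate=0.2, spurious_rate=0.0,
                              ct_noise_factor=1.0, seed=8)
        latent = generate_latent_network(cfg)
        jac = []
        for s in range(5):
            cfg2 = SyntheticConfig(**{**cfg.to_dict(), "seed": 8 + s})
            dbs, _ = emit_database_ensemble(latent, cfg2)
            a, b = dbs[0].ct_edges, dbs[1].ct_edges
            jac.append(len(a & b) / len(a | b))
        n = len(latent.ct_edges)
        sigma = np.sqrt(2 / 3 * (1 - 2 / 3) / n)  # coarse per-replicate scale
        assert abs(np.mean(jac) - 2 / 3) < 3 * sigma

    def test_provenance_true_edges_are_exactly_latent_intersection(self):
        cfg = small_cfg(dropout_rate=0.3, spurious_rate=0.2)
        latent = generate_latent_network(cfg)
        dbs, prov = emit_database_ensemble(latent, cfg)
        for db, flags in zip(dbs, prov):
            for layer, edges, latent_edges in (
                    ("hc", db.hc_edges, latent.hc_edges),
                    ("ct", db.ct_edges, latent.ct_edges)):
                for e in edges:
                    assert (layer, e) in flags  # bookkeeping is complete
                true_edges = {e for e in edges if flags[(layer, e)] == "true"}
                assert true_edges == edges & latent_edges
                spurious = {e for e in edges if flags[(layer, e)] == "spurious"}
                assert spurious.isdisjoint(latent_edges)


class TestKnownAssociations:
    def test_zero_density_gives_empty_labels(self):
        cfg = small_cfg(known_ct_density=0.0, known_ht_density=0.0)
        latent = generate_latent_network(cfg)
        known = plant_known_associations(latent, cfg)
        assert not known.compound_target and not known.herb_target

    def test_full_density_null_mode_labels_all_latent_ct_pairs(self):
        cfg = small_cfg(signal_mode="null", known_ct_density=1.0)
        latent = generate_latent_network(cfg)
        known = plant_known_associations(latent, cfg)
        assert known.compound_target == latent.ct_edges

    def test_null_mode_label_count_matches_binomial(self):
        cfg = SyntheticConfig(n_herbs=80, n_compounds=400, n_targets=500,
                              mean_targets_per_compound=6.0,
                              signal_mode="null", known_ct_density=0.013,
                              seed=9)
        latent = generate_latent_network(cfg)
        n = len(latent.ct_edges)
        counts = []
        for s in range(5):
            cfg2 = SyntheticConfig(**{**cfg.to_dict(), "seed": 9 + s})
            counts.append(len(plant_known_associations(latent, cfg2).compound_target))
        expect = n * 0.013
        sigma = np.sqrt(n * 0.013 * 0.987 / 5)
        assert abs(np.mean(counts) - expect) < 3 * sigma

    def test_labels_are_subsets_of_latent_relations(self):
        for mode in ("hub_noise", "null"):
            cfg = small_cfg(signal_mode=mode, known_ct_density=0.2,
                            known_ht_density=0.2)
            latent = generate_latent_network(cfg)
            known = plant_known_associations(latent, cfg)
            assert known.compound_target <= latent.ct_edges
            reachable = {(h, t) for h in latent.herbs
                         for t in latent.herb_targets(h)}
            assert known.herb_target <= reachable


class TestPpiAndModules:
    def test_module_size_exact_and_locality_one_connected(self):
        cfg = small_cfg(disease_locality=1.0, disease_module_size=8)
        ppi, modules = generate_ppi_and_disease_modules(cfg)
        assert len(modules) == cfg.n_diseases
        for members in modules.values():
            assert len(members) == 8
            sub = ppi.nx.subgraph(members)
            assert nx.is_connected(sub)

    def test_zero_locality_modules_look_like_random_sets(self):
        cfg = SyntheticConfig(n_targets=150, n_diseases=6, disease_locality=0.0,
                              disease_module_size=10, seed=12)
        ppi, modules = generate_ppi_and_disease_modules(cfg)
        rng = np.random.default_rng(0)
        nodes = sorted(ppi.nodes())

        def density(members):
            return ppi.nx.subgraph(members).number_of_edges()

        observed = np.mean([density(m) for m in modules.values()])
        null = [
            np.mean([density({nodes[i] for i in
                              rng.choice(len(nodes), 10, replace=False)})
                     for _ in range(6)])
            for _ in range(200)
        ]
        # permutation test: observed density typical of random sets
        p = (np.sum(np.array(null) >= observed) + 1) / 201
        assert 0.01 < p

    def test_ppi_is_connected(self):
        ppi, _ = generate_ppi_and_disease_modules(small_cfg())
        assert nx.is_connected(ppi.nx)


class TestMultiscaleInteractome:
    def test_hierarchy_is_a_tree(self):
        cfg = small_cfg()
        ppi, modules = generate_ppi_and_disease_modules(cfg)
        msi = generate_multiscale_interactome(cfg, ppi)
        up = [(a, b) for a, b, t in msi.edges() if t == "hierarchy_up"]
        down = [(a, b) for a, b, t in msi.edges() if t == "hierarchy_down"]
        assert len(up) == cfg.n_functions - 1
        assert len(down) == cfg.n_functions - 1
        g = nx.Graph(up)
        g.add_nodes_from(n for n in msi.nodes if n.namespace == "function")
        assert nx.is_tree(g)

    def test_single_function_star(self):
        cfg = small_cfg(n_functions=1, mean_annotations_per_protein=2.0)
        ppi, _ = generate_ppi_and_disease_modules(cfg)
        msi = generate_multiscale_interactome(cfg, ppi)
        fns = {n for n in msi.nodes if n.namespace == "function"}
        assert len(fns) == 1
        annotated = {a for a, b, t in msi.edges() if t == "protein_function"}
        assert annotated  # all annotations go to the single function

    def test_function_mediated_sets_are_more_distant_than_proximal(self):
        def median_distance(mode, seed):
            cfg = small_cfg(signal_mode=mode, seed=seed, n_targets=100)
            ppi, modules = generate_ppi_and_disease_modules(cfg)
            trt = plant_treatment_sets(cfg, ppi, modules)
            dists = []
            for d, module in modules.items():
                lengths = nx.multi_source_dijkstra_path_length(
                    ppi.nx, module, weight=None)
                ent = herb(f"TRT-{d.value}")
                dists += [lengths.get(t, np.inf) for t in trt[ent]]
            return np.median(dists)

        med_fm = np.median([median_distance("function_mediated", s) for s in range(3)])
        med_px = np.median([median_distance("proximal", s) for s in range(3)])
        assert med_fm > med_px


class TestDeterminism:
    def test_full_dataset_determinism_and_seed_sensitivity(self):
        a = generate_all(small_cfg(seed=21))
        b = generate_all(small_cfg(seed=21))
        c = generate_all(small_cfg(seed=22))
        assert a.truth.latent.ct_edges == b.truth.latent.ct_edges
        assert [d.ct_edges for d in a.databases] == [d.ct_edges for d in b.databases]
        assert a.truth.known.herb_target == b.truth.known.herb_target
        assert a.ppi.edges() == b.ppi.edges()
        assert a.truth.latent.ct_edges != c.truth.latent.ct_edges
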