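"""Correlation networks: construction, metrics, dissimilarity, Ward clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chemotyper import (
    CorrelationNetwork,
    TableState,
    ValidationError,
    build_network,
    degree_histogram,
    network_dissimilarity,
    network_metrics,
    ward_cluster,
)
from chemotyper.netcomp import NetworkComparison

from conftest import make_metadata, make_table


def net_from_edges(label, nodes, edges, r=0.9):
    return CorrelationNetwork(
        label, list(nodes),
        {tuple(sorted(e)): (r, 1e-4, 1e-3) for e in edges},
        n_samples=10,
    )


K4 = net_from_edges("k4", "abcd", itertools.combinations("abcd", 2))
STAR = net_from_edges("star", "abcd", [("a", "b"), ("a", "c"), ("a", "d")])


class TestBuildNetwork:
    def test_proportional_metabolites_linked_with_r_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rng = np.random.default_rng(0)
        X = np.stack([base, 2 * base] + [rng.standard_normal(6) for _ in range(4)],
                     axis=1)
        table = make_table(X, state=TableState.LOG_SCALED)
        meta = make_metadata(table.sample_ids)
        net = build_network(table, meta, {"genotype": "g1"})
        assert ("M1", "M2") in net.edges
        r, p, q = net.edges[("M1", "M2")]
        assert r == pytest.approx(1.0)

    def test_independent_noise_rarely_produces_edges(self):
        """50 independent metabolites at n=12: BH keeps the network empty."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = make_table(rng.standard_normal((12, 50)),
                               state=TableState.LOG_SCALED)
            meta = make_metadata(table.sample_ids)
            net = build_network(table, meta, {"genotype": "g1"})
            hits += net.n_edges > 0
        assert hits <= 1

    def test_small_stratum_rejected(self):
        table = make_table(np.random.default_rng(1).standard_normal((3, 5)),
                           state=TableState.LOG_SCALED)
        meta = make_metadata(table.sample_ids)
        with pytest.raises(ValidationError, match=">= 4"):
            build_network(table, meta, {"genotype": "g1"})

    def test_zero_variance_metabolite_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 4))
        X[:, 0] = 3.14
        table = make_table(X, state=TableState.LOG_SCALED)
        meta = make_metadata(table.sample_ids)
        with pytest.warns(UserWarning, match="zero-variance"):
            net = build_network(table, meta, {"genotype": "g1"})
        assert all("M1" not in e for e in net.edges)
        assert "M1" in net.nodes  # stays in the universe at degree 0

    def test_edges_shrink_as_threshold_tightens(self, study):
        loose = build_network(study.processed, study.metadata,
                              {"genotype": "varA", "condition": "hypoxia"},
                              q_threshold=0.05)
        tight = build_network(study.processed, study.metadata,
                              {"genotype": "varA", "condition": "hypoxia"},
                              q_threshold=0.01)
        assert set(tight.edges) <= set(loose.edges)

    def test_planted_blocks_recovered(self, study_bank):
        """Within-block edge recall >= 0.8; null pairs essentially never link."""
        recalls, false_rates = [], []
        for study in study_bank.values():
            all_pairs = study.truth.block_pairs()
            n_null = (370 * 369) // 2 - len(all_pairs)
            for geno in ("varA", "varB"):
                for cond in ("normoxia", "hypoxia"):
                    net = build_network(
                        study.processed, study.metadata,
                        {"genotype": geno, "condition": cond},
                    )
                    expected = study.truth.block_pairs(cond)
                    edges = set(net.edges)
                    recalls.append(len(edges & expected) / len(expected))
                    false_rates.append(len(edges - all_pairs) / n_null)
        assert np.mean(recalls) >= 0.8
        assert np.mean(false_rates) <= 0.05


class TestNetworkMetrics:
    def test_complete_graph_k4(self):
        m = network_metrics(K4)
        assert (m.density, m.diameter) == (1.0, 1)
        assert m.heterogeneity == pytest.approx(0.0)
        assert m.centralization == pytest.approx(0.0)

    def test_star_four_nodes(self):
        m = network_metrics(STAR)
        assert m.density == pytest.approx(0.5)
        assert m.diameter == 2
        assert m.heterogeneity == pytest.approx(np.sqrt(0.75) / 1.5, abs=1e-9)
        assert m.centralization == pytest.approx(1.0)

    def test_handshake_lemma_on_generated_network(self, study):
        net = build_network(study.processed, study.metadata,
                            {"genotype": "varA", "condition": "hypoxia"})
        m = network_metrics(net)
        assert m.degrees.sum() == 2 * (m.n_edges_pos + m.n_edges_neg)

    def test_edgeless_conventions(self):
        empty = net_from_edges("e", "abc", [])
        m = network_metrics(empty)
        assert (m.diameter, m.heterogeneity, m.density) == (0, 0.0, 0.0)
        assert m.pos_neg_ratio is None

    def test_invariant_to_node_relabelling(self):
        relabelled = net_from_edges(
            "star2", ["w", "x", "y", "z"], [("w", "x"), ("w", "y"), ("w", "z")]
        )
        a, b = network_metrics(STAR), network_metrics(relabelled)
        for attr in ("density", "diameter", "heterogeneity", "centralization"):
            assert getattr(a, attr) == getattr(b, attr)

    def test_self_edges_rejected(self):
        with pytest.raises(ValidationError, match="self-edge"):
            CorrelationNetwork("x", ["a"], {("a", "a"): (0.9, 0.0, 0.0)}, 5)


class TestDegreeHistogram:
    def test_star_counts(self):
        hist = degree_histogram(STAR)
        assert dict(zip(hist["degree"], hist["count"])) == {1: 3, 3: 1}

    def test_total_equals_node_count(self, study):
        net = build_network(study.processed, study.metadata,
                            {"genotype": "varA", "condition": "normoxia"})
        hist = degree_histogram(net)
        assert hist["count"].sum() == len(net.nodes)

    def test_hypoxia_networks_have_heavier_degree_tail(self, study_bank):
        """Stress-induced co-regulation concentrates connectivity."""
        diffs = []
        for study in study_bank.values():
            nets = {
                cond: build_network(study.processed, study.metadata,
                                    {"genotype": "varA", "condition": cond})
                for cond in ("normoxia", "hypoxia")
            }
            deg = {c: n.degree_vector().to_numpy() for c, n in nets.items()}
            q90 = np.quantile(np.concatenate(list(deg.values())), 0.9)
            diffs.append((deg["hypoxia"] > q90).mean()
                         - (deg["normoxia"] > q90).mean())
        assert np.mean(diffs) > 0


class TestDissimilarity:
    def test_identical_networks_are_zero_under_both_methods(self):
        for method in ("bray_curtis_degrees", "jaccard_edges"):
            comp = network_dissimilarity([K4, K4.__class__(
                "k4b", K4.nodes, dict(K4.edges), K4.n_samples)], method=method)
            assert comp.matrix[0, 1] == pytest.approx(0.0)

    def test_edge_disjoint_networks_have_jaccard_one(self):
        a = net_from_edges("a", "abcd", [("a", "b")])
        b = net_from_edges("b", "abcd", [("c", "d")])
        comp = network_dissimilarity([a, b], method="jaccard_edges")
        assert comp.matrix[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_example(self):
        from scipy.spatial.distance import braycurtis

        # |1-3|+|2-2|+|3-1| = 4 over 1+2+3+3+2+1 = 12
        assert braycurtis([1, 2, 3], [3, 2, 1]) == pytest.approx(1 / 3)

    def test_bray_curtis_on_degree_vectors(self):
        # a: path p-q-r gives degrees (1,2,1,0); b: star at p gives (3,1,1,1)
        a = net_from_edges("a", "pqrs", [("p", "q"), ("q", "r")])
        b = net_from_edges("b", "pqrs", [("p", "q"), ("p", "r"), ("p", "s")])
        comp = network_dissimilarity([a, b], method="bray_curtis_degrees")
        # |1-3|+|2-1|+|1-1|+|0-1| = 4 over 4+6 = 10
        assert comp.matrix[0, 1] == pytest.approx(0.4)

    def test_bounds_symmetry_and_zero_diagonal(self, study):
        nets = [
            build_network(study.processed, study.metadata,
                          {"genotype": g, "condition": c},
                          stratum_label=f"{g}_{c}")
            for g in ("varA", "varB") for c in ("normoxia", "hypoxia")
        ]
        for method in ("bray_curtis_degrees", "jaccard_edges"):
            comp = network_dissimilarity(nets, method=method)
            d = comp.matrix
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_both_edgeless_compare_as_zero_with_warning(self):
        a, b = net_from_edges("a", "xy", []), net_from_edges("b", "xy", [])
        with pytest.warns(UserWarning, match="edgeless"):
            comp = network_dissimilarity([a, b], method="jaccard_edges")
        assert comp.matrix[0, 1] == 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            network_dissimilarity([K4, STAR], method="cosine")


def brute_force_ward(d):
    """Exhaustive Ward.D2 agglomeration (Lance–Williams on squared distances)."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    d2 = d.astype(float) ** 2
    active = dict(enumerate(d2))
    dist = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), val = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((min(i, j), max(i, j), np.sqrt(val)))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        sizes[new] = ni + nj
        clusters[new] = clusters.pop(i) + clusters.pop(j)
        new_dist = {}
        for k in clusters:
            if k == new:
                continue
            nk = sizes[k]
            dik = dist.get((min(i, k), max(i, k)))
            djk = dist.get((min(j, k), max(j, k)))
            dij = val
            new_dist[(min(new, k), max(new, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        dist = {
            key: v for key, v in dist.items() if i not in key and j not in key
        }
        dist.update(new_dist)
    return merges


class TestWardCluster:
    def test_duplicate_pairs_merge_first(self):
        d = np.array(
            [[0.0, 0.0, 0.9, 0.9],
             [0.0, 0.0, 0.9, 0.9],
             [0.9, 0.9, 0.0, 0.0],
             [0.9, 0.9, 0.0, 0.0]]
        )
        comp = NetworkComparison(["a1", "a2", "b1", "b2"], d, "jaccard_edges")
        linkage, newick = ward_cluster(comp)
        first_two = {frozenset(linkage[0, :2].astype(int)),
                     frozenset(linkage[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        assert newick.endswith(";") and "a1" in newick

    def test_matches_exhaustive_ward_on_small_instances(self):
        rng = np.random.default_rng(0)
        for n in (3, 4):
            for _ in range(5):
                pts = rng.standard_normal((n, 2))
                d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
                comp = NetworkComparison([f"x{i}" for i in range(n)], d, "test")
                linkage, _ = ward_cluster(comp)
                expected = brute_force_ward(d)
                got_heights = linkage[:, 2]
                exp_heights = [h for _, _, h in expected]
                np.testing.assert_allclose(got_heights, exp_heights, rtol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.5], [0.4, 0.0]])
        comp = NetworkComparison(["a", "b"], d, "test")
        with pytest.raises(ValidationError, match="symmetric"):
            ward_cluster(comp)

    def test_top_split_separates_conditions(self, study_bank):
        """Submergence restructures correlations more than genotype does."""
        from scipy.cluster.hierarchy import fcluster

        ok = 0
        for study in study_bank.values():
            nets = [
                build_network(study.processed, study.metadata,
                              {"genotype": g, "condition": c},
                              stratum_label=f"{g}_{c}")
                for g in ("varA", "varB") for c in ("normoxia", "hypoxia")
            ]
            for method in ("bray_curtis_degrees", "jaccard_edges"):
                comp = network_dissimilarity(nets, method=method)
                linkage, _ = ward_cluster(comp)
                two = fcluster(linkage, 2, criterion="maxclust")
                sides = {}
                for cl, label in zip(two, comp.labels):
                    sides.setdefault(cl, set()).add(label.split("_")[1])
                ok += all(len(v) == 1 for v in sides.values())
        assert ok >= 2 * len(study_bank) - 1  # allow one marginal instance


class TestSignMixing:
    def test_pos_neg_ratio_decreases_with_sign_mixing(self):
        """More sign-flipped block members, lower positive:negative ratio."""
        from scipy.stats import spearmanr

        from chemotyper import GeneratorConfig, generate_dataset, preprocess_pipeline

        grid = [1 / 12, 2 / 12, 3 / 12, 4 / 12, 5 / 12]
        means = []
        for frac in grid:
            ratios = []
            for seed in (11, 12, 13, 14):
                cfg = GeneratorConfig(
                    seed=seed,
                    sign_mixing_fraction={"normoxia": 0.0, "hypoxia": frac},
                )
                table, meta, _, _, _ = generate_dataset(cfg)
                proc, _ = preprocess_pipeline(table, meta)
                net = build_network(proc, meta,
                                    {"genotype": "varA", "condition": "hypoxia"})
                ratios.append(network_metrics(net).pos_neg_ratio)
            means.append(np.mean(ratios))
        rho = spearmanr(grid, means).statistic
        assert rho < -0.9
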