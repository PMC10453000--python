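import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from grnpipe.grn import (
    ClassGRN,
    WeightedNetwork,
    assign_subnetworks,
    class_template_scores,
    detect_communities,
    enrichment_pvalue,
    export_network,
    grn_metrics,
    reconstruct_network,
    validate_gold_standard,
)
from grnpipe.synthetic import SimulationConfig, generate_gold_standard, simulate_corpus
from grnpipe.preprocess import normalize_total


class TestTemplateScores:
    def test_planted_marker_maximal_for_own_class(self, small_corpus):
        scores = class_template_scores(small_corpus["norm"], small_corpus["labels"])
        truth = small_corpus["truth"]
        for cls in truth.classes:
            for g in truth.class_genes(cls):
                row = scores.loc[g]
                assert row.idxmax() == cls
                assert row[cls] > 0

    def test_constant_gene_scores_zero(self):
        expr = pd.DataFrame(
            {"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 9.0], "s4": [5.0, 8.0]},
            index=["flat", "var"],
        )
        labels = pd.Series(["A", "A", "B", "B"], index=expr.columns)
        scores = class_template_scores(expr, labels)
        assert (scores.loc["flat"] == 0).all()

    def test_hand_computed_pearson(self):
        # values (1,2,9,10) against indicator of class A on samples (B,B,A,A)
        expr = pd.DataFrame([[1.0, 2.0, 9.0, 10.0]], index=["g"], columns=list("wxyz"))
        labels = pd.Series(["B", "B", "A", "A"], index=list("wxyz"))
        scores = class_template_scores(expr, labels)
        assert scores.loc["g", "A"] == pytest.approx(8.0 / math.sqrt(65.0))
        assert scores.loc["g", "B"] == pytest.approx(-8.0 / math.sqrt(65.0))

    def test_small_class_rejected(self):
        expr = pd.DataFrame(np.ones((2, 3)), columns=list("abc"))
        labels = pd.Series(["A", "A", "B"], index=list("abc"))
        with pytest.raises(ValueError, match="< 2 samples"):
            class_template_scores(expr, labels)


class TestReconstructNetwork:
    def test_empty_gold_standard(self, small_corpus):
        net = reconstruct_network(small_corpus["norm"], [], 2.0)
        assert len(net) == 0
        assert net.genes == []

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            validate_gold_standard([("a", "a")])

    def test_null_simulation_retention(self, rng):
        # i.i.d. noise genes, 200 samples: <= 10% of decoy edges survive z=2
        genes = [f"g{i}" for i in range(60)]
        expr = pd.DataFrame(
            rng.lognormal(4, 0.5, size=(60, 200)), index=genes
        )
        gold = [(genes[i], genes[i + 30]) for i in range(30)]
        net = reconstruct_network(expr, gold, z_threshold=2.0)
        assert len(net) <= 0.10 * len(gold)

    def test_perfect_pair_retained_with_max_weight(self, rng):
        genes = [f"g{i}" for i in range(40)]
        mat = rng.lognormal(4, 0.5, size=(40, 100))
        mat[1] = mat[0] * 2.0  # perfectly rank-correlated pair
        expr = pd.DataFrame(mat, index=genes)
        gold = [("g0", "g1")] + [(genes[i], genes[i + 19]) for i in range(2, 19)]
        net = reconstruct_network(expr, gold, z_threshold=2.0)
        assert ("g0", "g1") in set(zip(net.edges["tf"], net.edges["target"]))
        top = net.edges.sort_values("weight").iloc[-1]
        assert (top["tf"], top["target"]) == ("g0", "g1")

    def test_absent_gene_skipped_with_warning(self, small_corpus, caplog):
        gold = [("TF01_1", "not_a_gene")] + small_corpus["gold"][:5]
        with caplog.at_level("WARNING"):
            net = reconstruct_network(small_corpus["norm"], gold, 2.0)
        assert any("absent" in r.message for r in caplog.records)
        assert "not_a_gene" not in net.genes

    def test_monotone_pruning(self, small_corpus):
        norm, gold = small_corpus["norm"], small_corpus["gold"]
        edges_by_thr = {
            thr: set(
                zip(*(reconstruct_network(norm, gold, thr).edges[c] for c in ("tf", "target")))
            )
            for thr in (1.0, 2.0, 3.0)
        }
        assert edges_by_thr[3.0] <= edges_by_thr[2.0] <= edges_by_thr[1.0]

    def test_all_edges_from_gold(self, small_corpus):
        net = reconstruct_network(small_corpus["norm"], small_corpus["gold"], 2.0)
        gold_set = set(small_corpus["gold"])
        assert all(
            (a, b) in gold_set for a, b in zip(net.edges["tf"], net.edges["target"])
        )


def _two_hub_network():
    edges = pd.DataFrame(
        [("h1", f"a{i}", 0.9, 3.0) for i in range(4)]
        + [("h2", f"b{i}", 0.9, 3.0) for i in range(4)],
        columns=["tf", "target", "rho", "weight"],
    )
    return WeightedNetwork(edges, 2.0)


class TestCommunities:
    def test_disconnected_hubs_match_components(self):
        net = _two_hub_network()
        part = detect_communities(net, seed=0)
        assert len(set(part.values())) == 2
        assert len({part[g] for g in ["h1", "a0", "a1", "a2", "a3"]}) == 1
        assert part["h1"] != part["h2"]

    def test_empty_network_empty_partition(self):
        net = WeightedNetwork(pd.DataFrame(columns=["tf", "target", "rho", "weight"]), 2.0)
        assert detect_communities(net) == {}

    def test_deterministic_under_seed(self, small_corpus):
        net = reconstruct_network(small_corpus["norm"], small_corpus["gold"], 2.0)
        assert detect_communities(net, seed=3) == detect_communities(net, seed=3)

    @pytest.mark.parametrize("method", ["infomap", "leiden"])
    def test_planted_partition_recovery(self, method):
        # one hub per class so communities should match planted classes
        cfg = SimulationConfig(
            n_classes=3,
            n_tfs_per_class=1,
            targets_per_tf=8,
            n_background_genes=100,
            samples_per_class=20,
            hub_effect=4.0,
            noise_sd=0.5,
            decoy_pairs=10,
            seed=13,
        )
        gold, truth = generate_gold_standard(cfg)
        _, expr = simulate_corpus(cfg, truth)
        net = reconstruct_network(normalize_total(expr), gold, 2.0)
        part = detect_communities(net, seed=0, method=method)
        class_of = {}
        for cls in truth.classes:
            for g in truth.class_genes(cls):
                class_of[g] = cls
        genes = [g for g in part if g in class_of]
        assert len(genes) >= 0.8 * len(class_of)
        ari = adjusted_rand_score(
            [class_of[g] for g in genes], [part[g] for g in genes]
        )
        assert ari >= 0.9

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="community method"):
            detect_communities(_two_hub_network(), method="nope")


class TestAssignment:
    def _templates(self, genes, class_genes):
        data = {}
        for cls, members in class_genes.items():
            data[cls] = [1.0 if g in members else 0.0 for g in genes]
        return pd.DataFrame(data, index=genes)

    def test_matching_community_assigned(self):
        genes = [f"g{i}" for i in range(30)]
        templates = self._templates(genes, {"A": set(genes[:10]), "B": set(genes[10:20])})
        partition = {g: 0 for g in genes[:10]}
        partition.update({g: 1 for g in genes[10:20]})
        edges = pd.DataFrame(
            [("g0", "g1", 0.9, 3.0), ("g10", "g11", 0.9, 3.0)],
            columns=["tf", "target", "rho", "weight"],
        )
        net = WeightedNetwork(edges, 2.0)
        grns = assign_subnetworks(partition, templates, net, top_k=10, alpha=0.05)
        assert set(grns["A"].genes) == set(genes[:10])
        assert set(grns["B"].genes) == set(genes[10:20])

    def test_background_community_unassigned(self):
        genes = [f"g{i}" for i in range(40)]
        templates = self._templates(genes, {"A": set(genes[:5]), "B": set(genes[5:10])})
        partition = {g: 0 for g in genes[20:30]}  # pure background genes
        net = WeightedNetwork(
            pd.DataFrame([("g20", "g21", 0.5, 2.5)], columns=["tf", "target", "rho", "weight"]),
            2.0,
        )
        grns = assign_subnetworks(partition, templates, net, top_k=5, alpha=0.05)
        assert grns["A"].genes == []
        assert grns["B"].genes == []

    def test_hypergeometric_p_matches_brute_force(self):
        # exhaustive tail sum of the hypergeometric pmf on a 20-gene universe
        M, K, N, k = 20, 6, 8, 4
        brute = sum(
            math.comb(K, x) * math.comb(M - K, N - x) / math.comb(M, N)
            for x in range(k, min(K, N) + 1)
        )
        assert enrichment_pvalue(k, M, K, N) == pytest.approx(brute, rel=1e-12)

    def test_community_maps_to_one_class(self, pipeline_result):
        seen: dict[int, str] = {}
        for cls, grn in pipeline_result["class_grns"].items():
            for cid in grn.communities:
                assert cid not in seen, f"community {cid} in {seen[cid]} and {cls}"
                seen[cid] = cls

    def test_planted_recovery_jaccard(self, pipeline_result):
        truth = pipeline_result["truth"]
        for cls, grn in pipeline_result["class_grns"].items():
            planted = set(truth.class_genes(cls))
            got = set(grn.genes)
            jac = len(planted & got) / len(planted | got)
            assert jac >= 0.7, f"{cls}: Jaccard {jac:.2f}"


class TestMetricsAndExport:
    def _toy_grn(self):
        edges = pd.DataFrame(
            [("t", "a", 0.8, 3.0), ("t", "b", 0.7, 2.5), ("u", "b", 0.6, 2.2)],
            columns=["tf", "target", "rho", "weight"],
        )
        return ClassGRN(label="A", genes=["t", "u", "a", "b"], edges=edges)

    def test_targets_per_tf(self):
        metrics = grn_metrics({"A": self._toy_grn()})
        assert metrics.targets_per_tf["A"]["t"] == 2
        assert metrics.targets_per_tf["A"]["u"] == 1
        assert metrics.regulators_per_target["A"]["b"] == 2

    def test_conservation_invariant(self, pipeline_result):
        metrics = pipeline_result["metrics"]
        for _, row in metrics.summary.iterrows():
            cls = row["class"]
            assert metrics.targets_per_tf[cls].sum() == row["n_edges"]
            assert metrics.regulators_per_target[cls].sum() == row["n_edges"]

    def test_empty_grn_zero_metrics(self):
        empty = ClassGRN(
            label="Z", genes=[], edges=pd.DataFrame(columns=["tf", "target", "rho", "weight"])
        )
        metrics = grn_metrics({"Z": empty})
        row = metrics.summary.iloc[0]
        assert row["n_nodes"] == row["n_edges"] == row["n_tfs"] == 0

    def test_export_round_trip(self, tmp_path):
        grn = self._toy_grn()
        grn.importances = pd.Series(
            [0.4, 0.3, 0.2, 0.1], index=["t", "u", "a", "b"]
        )
        path = tmp_path / "net.graphml"
        export_network(grn, path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(grn.genes)
        assert set(g.edges) == {("t", "a"), ("t", "b"), ("u", "b")}
        assert g.nodes["t"]["importance"] == pytest.approx(0.4)
        assert g.edges[("t", "a")]["weight"] == pytest.approx(3.0)

    def test_influence_equals_degree_oracle(self, tmp_path):
        grn = self._toy_grn()
        path = tmp_path / "net.graphml"
        export_network(grn, path)
        g = nx.read_graphml(path)
        for node in g.nodes:
            assert g.nodes[node]["influence"] == g.degree(node)

    def test_empty_grn_exports_valid_graphml(self, tmp_path):
        empty = ClassGRN(
            label="Z", genes=[], edges=pd.DataFrame(columns=["tf", "target", "rho", "weight"])
        )
        path = tmp_path / "empty.graphml"
        export_network(empty, path)
        g = nx.read_graphml(path)
        assert len(g) == 0
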