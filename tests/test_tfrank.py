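"""Heat-diffusion ranking: closed forms, dense-series oracle, selection rules."""

import math

import numpy as np
import pytest

from trninfer.datatypes import (
    ACTIVATES,
    INHIBITS,
    PipelineParams,
    RegulatoryAssociation,
    RegulonDB,
    UNRESOLVED,
    ValidationError,
)
from trninfer.tfrank import (
    TFWeight,
    build_graph,
    documented_regulators,
    select_upstream,
    tfrank,
    top_ranked,
    upstream_edge_sign,
)


def _regulon(pairs):
    return RegulonDB([RegulatoryAssociation(r, t) for r, t in pairs])


class TestBuildGraph:
    def test_single_edge_reverse_weight(self):
        g = build_graph(_regulon([("A", "g1")]))
        M = g.reverse_transition.toarray()
        assert M[g.index["A"], g.index["g1"]] == 1.0

    def test_two_regulators_split_equally(self):
        g = build_graph(_regulon([("A", "g1"), ("B", "g1")]))
        M = g.reverse_transition.toarray()
        assert M[g.index["A"], g.index["g1"]] == 0.5
        assert M[g.index["B"], g.index["g1"]] == 0.5

    def test_reverse_weights_sum_to_one_per_target(self):
        rng = np.random.default_rng(4)
        tfs = [f"T{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(12)]
        pairs = {(tfs[rng.integers(5)], genes[rng.integers(12)]) for _ in range(30)}
        g = build_graph(_regulon(pairs))
        colsums = np.asarray(g.reverse_transition.sum(axis=0)).ravel()
        np.testing.assert_allclose(colsums, 1.0)

    def test_empty_regulon_rejected(self):
        with pytest.raises(ValidationError):
            build_graph(RegulonDB())


def _dense_series_oracle(graph, seeds, alpha, terms=30):
    """Independent brute force: dense matrix powers summed to `terms`."""
    n = len(graph.nodes)
    M = graph.reverse_transition.toarray()
    s = np.zeros(n)
    for g in seeds:
        s[graph.index[g]] = 1.0 / len(seeds)
    w = np.zeros(n)
    Mj = np.eye(n)
    for j in range(1, terms + 1):
        Mj = Mj @ M
        w += (alpha**j / math.factorial(j)) * (Mj @ s)
    return w


class TestTFRank:
    def test_chain_closed_form(self):
        g = build_graph(_regulon([("TF1", "g1")]))
        (w,) = tfrank(g, {"g1"})
        assert w.tf == "TF1"
        assert w.weight == pytest.approx(math.exp(0.25) - 1.0, rel=1e-9)

    def test_more_seed_targets_means_more_weight(self):
        g = build_graph(_regulon([("TF1", "g1"), ("TF1", "g2"), ("TF2", "g1")]))
        weights = {w.tf: w.weight for w in tfrank(g, {"g1", "g2"})}
        assert weights["TF1"] > weights["TF2"]

    def test_unreachable_tf_has_zero_weight(self):
        g = build_graph(_regulon([("TF1", "g1"), ("TF2", "g9")]))
        weights = {w.tf: w.weight for w in tfrank(g, {"g1"})}
        assert weights["TF2"] == 0.0

    def test_matches_dense_series_on_random_small_graphs(self):
        rng = np.random.default_rng(8)
        params = PipelineParams()
        for trial in range(60):
            nodes = [f"n{i}" for i in range(rng.integers(2, 7))]
            pairs = set()
            for _ in range(rng.integers(1, 9)):
                a, b = rng.choice(nodes, size=2, replace=False)
                pairs.add((a, b))
            graph = build_graph(_regulon(pairs))
            k = rng.integers(1, len(graph.nodes) + 1)
            seeds = set(rng.choice(graph.nodes, size=k, replace=False))
            oracle = _dense_series_oracle(graph, seeds, 0.25)
            got = {w.tf: w.weight for w in tfrank(graph, seeds, params)}
            for tf, weight in got.items():
                assert weight == pytest.approx(oracle[graph.index[tf]], abs=1e-10)

    def test_permutation_symmetry_of_seed_labels(self):
        pairs = [("A", "g1"), ("A", "g2"), ("B", "g2"), ("B", "g3")]
        g = build_graph(_regulon(pairs))
        w1 = tfrank(g, {"g1", "g3"})
        # relabel: swap the roles of g1 and g3 (B and A mirror each other)
        mirrored = {w.tf: w.weight for w in w1}
        assert mirrored["A"] == pytest.approx(mirrored["B"])

    def test_adding_documented_seed_never_decreases_weight(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            tfs = [f"T{i}" for i in range(3)]
            genes = [f"g{i}" for i in range(8)]
            pairs = {(tfs[rng.integers(3)], genes[rng.integers(8)]) for _ in range(12)}
            graph = build_graph(_regulon(pairs))
            regulon = graph.regulon
            tf = tfs[0]
            targets = sorted(regulon.targets_of(tf))
            if not targets:
                continue
            others = [g for g in genes if g in graph.index and g not in targets]
            if not others:
                continue
            base_seeds = {others[0]}
            w0 = {w.tf: w.weight for w in tfrank(graph, base_seeds)}
            # adding one of tf's documented targets: total heat grows and the
            # new seed feeds tf directly, so tf's absolute share cannot drop
            # after rescaling to equal per-seed heat
            w1 = {w.tf: w.weight for w in tfrank(graph, base_seeds | {targets[0]})}
            assert w1[tf] * 2 >= w0[tf] - 1e-12  # per-seed heat halves with 2 seeds

    def test_weights_scale_linearly_with_seed_heat(self):
        g = build_graph(_regulon([("A", "g1"), ("B", "g1"), ("A", "g2")]))
        w1 = {w.tf: w.weight for w in tfrank(g, {"g1"})}
        w2 = {w.tf: w.weight for w in tfrank(g, {"g1", "g2"})}
        oracle = _dense_series_oracle(g, {"g1", "g2"}, 0.25)
        for tf in ("A", "B"):
            assert w2[tf] == pytest.approx(oracle[g.index[tf]], abs=1e-12)

    def test_empty_seed_set_rejected(self):
        g = build_graph(_regulon([("A", "g1")]))
        with pytest.raises(ValidationError):
            tfrank(g, set())

    def test_seed_fraction_definition(self):
        g = build_graph(_regulon([("A", "g1"), ("A", "g2"), ("B", "g1")]))
        weights = {w.tf: w for w in tfrank(g, {"g1", "g2"})}
        assert weights["A"].seed_target_fraction == 1.0
        assert weights["B"].seed_target_fraction == 0.5


class TestTopRanked:
    def _weights(self, specs):
        return [TFWeight(tf, w, f) for tf, w, f in specs]

    def test_unconstrained_top_k(self):
        ws = self._weights([(f"T{i}", 10 - i, 0.5) for i in range(10)])
        assert top_ranked(ws) == [f"T{i}" for i in range(6)]

    def test_fraction_boundary_is_strict(self):
        ws = self._weights([("A", 5.0, 0.40), ("B", 4.0, 0.41)])
        assert top_ranked(ws) == ["B"]

    def test_exhaustion_returns_fewer(self):
        ws = self._weights([("A", 3.0, 0.9), ("B", 2.0, 0.9), ("C", 1.0, 0.1)])
        assert top_ranked(ws) == ["A", "B"]


class TestUpstreamSelection:
    def test_set_algebra_worked_example(self):
        got = select_upstream({"A", "B", "C", "D", "E", "F"}, {"B", "F", "G"},
                              {"F"}, "CORE")
        assert got == {"B"}

    def test_disjoint_sets_empty(self):
        assert select_upstream({"A"}, {"B"}, set(), "CORE") == set()

    def test_never_contains_core_or_downstream(self):
        rng = np.random.default_rng(14)
        names = [f"T{i}" for i in range(12)]
        for _ in range(50):
            top = set(rng.choice(names, size=6, replace=False))
            doc = set(rng.choice(names, size=5, replace=False))
            down = set(rng.choice(names, size=4, replace=False))
            core = names[rng.integers(12)]
            got = select_upstream(top, doc, down, core)
            assert not (got & down) and core not in got
            assert got <= (top & doc)

    def test_documented_regulators_lookup(self):
        reg = _regulon([("A", "SIN3"), ("B", "g9")])
        assert documented_regulators("SIN3", reg) == {"A"}
        assert documented_regulators("MIG1", reg) == set()

    def test_documented_regulators_matches_scan(self):
        rng = np.random.default_rng(15)
        tfs = [f"T{i}" for i in range(6)]
        targets = [f"g{i}" for i in range(10)] + tfs
        pairs = {(tfs[rng.integers(6)], targets[rng.integers(len(targets))])
                 for _ in range(40)}
        reg = _regulon(pairs)
        for t in targets:
            expected = {r for (r, x) in pairs if x == t}
            assert documented_regulators(t, reg) == expected


class TestUpstreamEdgeSign:
    def test_qpcr_overrides_documented_activation(self):
        e = upstream_edge_sign("ACE2", "SIN3", "activation", qpcr_fold=2.5)
        assert e.sign == INHIBITS
        assert "override" in e.provenance

    def test_weak_qpcr_keeps_documented_sign_unconfirmed(self):
        e = upstream_edge_sign("YAP1", "MIG1", "activation", qpcr_fold=-1.1)
        assert e.sign == ACTIVATES
        assert "unconfirmed" in e.provenance

    def test_documented_inhibition_passthrough(self):
        e = upstream_edge_sign("X", "Y", "inhibition")
        assert e.sign == INHIBITS

    def test_strong_negative_fold_means_activator(self):
        e = upstream_edge_sign("X", "Y", "unknown", qpcr_fold=-4.3)
        assert e.sign == ACTIVATES

    def test_unknown_sign_without_qpcr_flagged_unresolved(self):
        e = upstream_edge_sign("X", "Y", "unknown")
        assert e.sign == UNRESOLVED
        assert e.layer_pair == "upstream->core"
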