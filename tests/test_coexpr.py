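"""Co-expression edge conservation: sparsification, classes, randomization."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from girewire import DegreeTable, OrthologyMap, WeightedGeneNetwork
from girewire.coexpr import (
    RewiredLabeling,
    background_conservation,
    compare_classes,
    conservation_by_class,
    conservation_rate,
    degree_preserving_randomize,
    label_rewired,
    restrict_to_orthologs,
    sparsify_network,
)
from girewire.model import PredictionTable


def complete_network(n, rng):
    w = rng.uniform(size=(n, n))
    w = (w + w.T) / 2
    return WeightedGeneNetwork([f"g{i}" for i in range(n)], w)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration.

    Fix margins; sum probabilities of all tables as or less probable than
    the observed one.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    obs = hypergeom.pmf(a, n, row1, col1)
    p = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        px = hypergeom.pmf(x, n, row1, col1)
        if px <= obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestSparsify:
    def test_density_zero(self, rng):
        assert sparsify_network(complete_network(8, rng), 0) == set()

    def test_rank_invariance(self, rng):
        net = complete_network(12, rng)
        e1 = sparsify_network(net, 0.1)
        doubled = WeightedGeneNetwork(net.genes, net.weights * 2)
        assert sparsify_network(doubled, 0.1) == e1

    def test_density_never_exceeded(self, rng):
        for d in (0.02, 0.05, 0.2):
            net = complete_network(30, rng)
            edges = sparsify_network(net, d)
            assert len(edges) <= d * (30 * 29 / 2) + 1

    def test_all_tied_warns_empty(self):
        w = np.ones((4, 4))
        net = WeightedGeneNetwork(list("abcd"), w)
        with pytest.warns(UserWarning, match="tied"):
            assert sparsify_network(net, 0.5) == set()


class TestRestrict:
    def _nets(self, rng):
        net1 = complete_network(6, rng)
        genes2 = [f"h{i}" for i in range(6)]
        w = rng.uniform(size=(6, 6))
        net2 = WeightedGeneNetwork(genes2, (w + w.T) / 2)
        pairs = pd.DataFrame(
            {"gene_species1": [f"g{i}" for i in range(6)],
             "gene_species2": genes2,
             "relation": ["one_to_one"] * 5 + ["other"],
             "curated": False}
        )
        return net1, net2, OrthologyMap(pairs=pairs)

    def test_essential_and_many_to_one_excluded(self, rng):
        net1, net2, orth = self._nets(rng)
        sub1, sub2, mapping = restrict_to_orthologs(
            net1, net2, orth, essential1=set(), essential2={"h1"}
        )
        assert "g1" not in mapping  # essential in species 2
        assert "g5" not in mapping  # not one-to-one
        assert sub1.genes == sub2.genes

    def test_matches_intersection_oracle(self, rng):
        net1, net2, orth = self._nets(rng)
        ess1, ess2 = {"g0"}, {"h3"}
        _, _, mapping = restrict_to_orthologs(net1, net2, orth, ess1, ess2)
        expected = {
            f"g{i}" for i in range(5)
            if f"g{i}" not in ess1 and f"h{i}" not in ess2
        }
        assert set(mapping) == expected

    def test_empty_intersection_error(self, rng):
        net1, net2, orth = self._nets(rng)
        with pytest.raises(ValueError, match="no shared"):
            restrict_to_orthologs(net1, net2, orth,
                                  essential1={f"g{i}" for i in range(6)})


class TestLabeling:
    def _label(self, pred, obs, tau):
        genes1 = list(obs)
        orth = OrthologyMap(
            pairs=pd.DataFrame(
                {"gene_species1": genes1,
                 "gene_species2": [g + "_2" for g in genes1],
                 "relation": "one_to_one", "curated": False}
            )
        )
        dt1 = DegreeTable(species="s1", degrees=pd.Series(obs))
        pt = PredictionTable(
            species="s2",
            predictions=pd.Series({g + "_2": v for g, v in pred.items()}),
            n_trees_used=pd.Series({g + "_2": 100 for g in pred}),
        )
        return label_rewired(pt, dt1, orth, tau)

    def test_zero_difference_non_rewired(self):
        lab = self._label({"a": 10.0}, {"a": 10}, tau=55)
        assert lab.labels["a"] == "non_rewired"

    def test_above_tau_rewired(self):
        lab = self._label({"a": 56.0}, {"a": 0}, tau=55)
        assert lab.labels["a"] == "rewired"

    def test_between_bands_unlabeled(self):
        lab = self._label({"a": 40.0}, {"a": 0}, tau=80)
        assert lab.labels["a"] == "unlabeled"


class TestConservationByClass:
    def _labeling(self, rewired, non_rewired):
        labels = {g: "rewired" for g in rewired}
        labels.update({g: "non_rewired" for g in non_rewired})
        return RewiredLabeling(labels=pd.Series(labels, dtype=object), tau=55)

    def test_identical_edge_sets_rate_one(self):
        edges = {("a", "b"), ("b", "c")}
        lab = self._labeling({"a"}, {"b", "c"})
        for s in conservation_by_class(edges, set(edges), lab):
            if s.total:
                assert s.rate == 1.0

    def test_disjoint_edge_sets_rate_zero(self):
        lab = self._labeling(set(), {"a", "b", "c", "d"})
        out = conservation_by_class({("a", "b")}, {("c", "d")}, lab)
        nn = {s.edge_class: s for s in out}["NN"]
        assert nn.total == 2 and nn.rate == 0.0

    def test_random_pair_matches_set_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        rewired = set(rng.choice(genes, size=6, replace=False))
        unlabeled = {g for g in genes if g not in rewired and rng.random() < 0.1}
        non_rew = set(genes) - rewired - unlabeled
        all_pairs = list(combinations(sorted(genes), 2))
        e1 = {p for p in all_pairs if rng.random() < 0.3}
        e2 = {p for p in all_pairs if rng.random() < 0.3}
        lab = self._labeling(rewired, non_rew)
        out = {s.edge_class: s for s in conservation_by_class(e1, e2, lab)}

        def cls(p):
            if p[0] in unlabeled or p[1] in unlabeled:
                return None
            k = (p[0] in rewired) + (p[1] in rewired)
            return ("NN", "NR", "RR")[k]

        for c in ("NN", "NR", "RR"):
            union = [p for p in e1 | e2 if cls(p) == c]
            inter = [p for p in e1 & e2 if cls(p) == c]
            assert out[c].total == len(union)
            assert out[c].conserved == len(inter)
            if union:
                assert out[c].rate == pytest.approx(len(inter) / len(union))


class TestCompareClasses:
    def _summary(self, conserved, total, cls="RR"):
        from girewire.coexpr import EdgeClassSummary

        return EdgeClassSummary(cls, conserved, total, conserved / total, 0, 1, 55)

    def test_symmetric_table(self):
        odds, p = compare_classes(self._summary(5, 10), self._summary(5, 10, "NN"))
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in [(1, 9, 9, 1), (0, 5, 5, 0), (3, 2, 1, 6), (2, 2, 2, 2)]:
            _, p = compare_classes(self._summary(a, a + b), self._summary(c, c + d, "NN"))
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-8)

    def test_equal_rates_not_significant(self):
        _, p = compare_classes(self._summary(3, 9), self._summary(4, 12, "NN"))
        assert p >= 0.05


class TestRandomization:
    def test_degree_sequence_preserved(self, rng):
        g = nx.gnm_random_graph(25, 60, seed=7)
        edges = {tuple(sorted((f"n{a}", f"n{b}"))) for a, b in g.edges}
        out = degree_preserving_randomize(edges, swap_multiplier=20, seed=3)
        def degs(es):
            d = {}
            for a, b in es:
                d[a] = d.get(a, 0) + 1
                d[b] = d.get(b, 0) + 1
            return d
        assert degs(out) == degs(edges)
        assert len(out) == len(edges)

    def test_four_cycle_state_space_matches_bfs_oracle(self):
        # exhaustive enumeration: from a 4-cycle, double-edge swaps can only
        # reach 2-regular graphs on the same vertices -- the three labeled
        # 4-cycles -- and over many seeds every one of them is visited
        cycle = frozenset({("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")})

        def swaps(state):
            out = set()
            edges = sorted(state)
            for i in range(len(edges)):
                for j in range(len(edges)):
                    if i == j:
                        continue
                    (a, b), (c, d) = edges[i], edges[j]
                    for c2, d2 in ((c, d), (d, c)):
                        e1 = tuple(sorted((a, d2)))
                        e2 = tuple(sorted((c2, b)))
                        if e1[0] == e1[1] or e2[0] == e2[1] or e1 == e2:
                            continue
                        if e1 in state or e2 in state:
                            continue
                        out.add(frozenset(state - {edges[i], edges[j]} | {e1, e2}))
            return out

        reachable = {cycle}
        frontier = [cycle]
        while frontier:
            nxt = []
            for st in frontier:
                for new in swaps(st):
                    if new not in reachable:
                        reachable.add(new)
                        nxt.append(new)
            frontier = nxt
        assert len(reachable) == 3  # the three labeled 4-cycles

        seen = set()
        for seed in range(60):
            out = degree_preserving_randomize(set(cycle), swap_multiplier=20, seed=seed)
            seen.add(frozenset(out))
        assert seen == reachable

    def test_single_edge_identity(self):
        assert degree_preserving_randomize({("a", "b")}, 20, 0) == {("a", "b")}


class TestBackgroundConservation:
    def test_independent_networks_closed_form(self, rng):
        # two independent G(n, m) edge sets at density d: expected
        # conservation (intersection/union) ~ d / (2 - d)
        n, d = 60, 0.05
        pairs = list(combinations([f"g{i}" for i in range(n)], 2))
        m = int(d * len(pairs))
        def sample():
            idx = rng.choice(len(pairs), size=m, replace=False)
            return {pairs[i] for i in idx}
        rates = [
            background_conservation(sample(), sample(), 20, seed=k, n_reps=1)
            for k in range(15)
        ]
        assert np.mean(rates) == pytest.approx(d / (2 - d), abs=0.01)

    def test_identical_networks_background_below_one(self, rng):
        g = nx.gnm_random_graph(30, 80, seed=1)
        edges = {tuple(sorted((f"n{a}", f"n{b}"))) for a, b in g.edges}
        assert background_conservation(edges, edges, 20, 0, n_reps=2) < 1.0

    def test_hub_networks_exceed_independent_form(self, rng):
        # degree preservation keeps hub-hub pairs likely in both networks
        n = 40
        hub_edges1 = {tuple(sorted((f"g0", f"g{i}"))) for i in range(1, 30)}
        hub_edges2 = {tuple(sorted((f"g0", f"g{i}"))) for i in range(5, 34)}
        d = len(hub_edges1) / math.comb(n, 2)
        bg = background_conservation(hub_edges1, hub_edges2, 20, 0, n_reps=5)
        assert bg > d / (2 - d)

    def test_self_conservation_one_and_complement_zero(self, rng):
        genes = [f"g{i}" for i in range(10)]
        pairs = set(combinations(genes, 2))
        e1 = {p for p in pairs if rng.random() < 0.4}
        assert conservation_rate(e1, e1) == 1.0
        assert conservation_rate(e1, pairs - e1) == 0.0
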