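"""Cohesiveness clustering, match metrics and grid optimization."""

import itertools

import numpy as np
import pytest

import cofracnet as cf
from cofracnet.complexes import (ClusterParams, _graph, _merge_overlapping,
                                 cohesiveness, density, detect_complexes,
                                 match_metrics, omega, optimize_params)


def net_from(edges, **kw):
    return cf.ScoredNetwork(dict(edges), **kw)


def triangle(w=1.0):
    return net_from({("A", "B"): w, ("B", "C"): w, ("A", "C"): w})


class TestCohesiveness:
    def test_isolated_unit_triangle_is_one(self):
        g = _graph(triangle())
        assert cohesiveness(g, {"A", "B", "C"}, penalty=0.0) == pytest.approx(1.0)

    def test_triangle_with_one_outward_edge(self):
        net = net_from({("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1,
                        ("C", "D"): 1})
        g = _graph(net)
        assert cohesiveness(g, {"A", "B", "C"}, penalty=0.0) == pytest.approx(0.75)

    def test_large_penalty_drives_score_to_zero(self):
        g = _graph(triangle())
        assert cohesiveness(g, {"A", "B", "C"}, penalty=1e12) < 1e-9

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohesiveness(_graph(triangle()), set(), 2.0)


class TestDetectComplexes:
    def test_two_cliques_with_weak_bridge_recovered(self):
        """Two unit-weight 4-cliques joined by one weight-0.1 edge separate
        cleanly at d=0.2, o=0.8."""
        edges = {}
        left = ["A1", "A2", "A3", "A4"]
        right = ["B1", "B2", "B3", "B4"]
        for grp in (left, right):
            for a, b in itertools.combinations(grp, 2):
                edges[(a, b)] = 1.0
        edges[("A1", "B1")] = 0.1
        cat = detect_complexes(net_from(edges), ClusterParams(d=0.2, o=0.8))
        members = sorted(cat.complexes.values(), key=sorted)
        assert members == [frozenset(left), frozenset(right)]

    def test_single_triangle_min_size_three(self):
        cat = detect_complexes(triangle(), ClusterParams(d=0.2, o=0.8))
        assert list(cat.complexes.values()) == [frozenset("ABC")]

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        nodes = [f"N{i}" for i in range(12)]
        edges = {(a, b): float(rng.uniform(0.1, 1))
                 for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.5}
        net = net_from(edges)
        c1 = detect_complexes(net, ClusterParams())
        c2 = detect_complexes(net, ClusterParams())
        assert c1.complexes == c2.complexes

    def test_outputs_locally_optimal_and_match_brute_force(self):
        """On small random graphs, every detected group's cohesiveness equals
        an independent brute-force recomputation and no single-node move
        improves it."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 11))
            nodes = [f"N{i}" for i in range(n)]
            edges = {(a, b): float(rng.uniform(0.1, 1.0))
                     for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.4}
            if not edges:
                continue
            net = net_from(edges)
            params = ClusterParams(d=0.0, o=0.8, min_size=2)
            g = _graph(net)
            for members in detect_complexes(net, params).complexes.values():
                s = set(members)
                w_in = sum(d["weight"]
                           for _, _, d in g.subgraph(s).edges(data=True))
                w_b = sum(d["weight"] for a, b, d in g.edges(data=True)
                          if (a in s) != (b in s))
                brute = w_in / (w_in + w_b + params.penalty * len(s))
                score = cohesiveness(g, s, params.penalty)
                assert score == pytest.approx(brute, abs=1e-9)
                for u in set(g.nodes) - s:
                    assert cohesiveness(g, s | {u}, params.penalty) <= score + 1e-12
                if len(s) > 1:
                    for v in s:
                        assert cohesiveness(g, s - {v}, params.penalty) <= score + 1e-12

    def test_merge_pass_is_idempotent(self):
        rng = np.random.default_rng(6)
        nodes = [f"N{i}" for i in range(10)]
        edges = {(a, b): float(rng.uniform(0.2, 1))
                 for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.6}
        g = _graph(net_from(edges))
        params = ClusterParams(o=0.5)
        groups = [frozenset(nodes[:4]), frozenset(nodes[2:6]),
                  frozenset(nodes[7:])]
        merged = _merge_overlapping(g, groups, params)
        again = _merge_overlapping(g, merged, params)
        assert merged == again


class TestMatchMetrics:
    def test_identity_on_disjoint_reference(self):
        cat = cf.ComplexCatalog({"C1": frozenset("ABC"), "C2": frozenset("DEF")})
        rep = match_metrics(cat, cat)
        assert (rep.acc, rep.mmr, rep.overlap) == (1.0, 1.0, 1.0)
        assert rep.composite == pytest.approx(3.0)

    def test_disjoint_catalogs_score_zero(self):
        ref = cf.ComplexCatalog({"C1": frozenset("ABC")})
        pred = cf.ComplexCatalog({"P1": frozenset("XYZ")}, source="predicted")
        rep = match_metrics(pred, ref)
        assert (rep.acc, rep.mmr, rep.overlap) == (0.0, 0.0, 0.0)

    def test_half_overlap_example(self):
        """reference {A,B,C,D}, predicted {A,B}: omega = 4/8 = 0.5."""
        ref = cf.ComplexCatalog({"C1": frozenset("ABCD")})
        pred = cf.ComplexCatalog({"P1": frozenset("AB")}, source="predicted")
        rep = match_metrics(pred, ref)
        assert omega(frozenset("ABCD"), frozenset("AB")) == pytest.approx(0.5)
        assert rep.mmr == pytest.approx(0.5)
        assert rep.overlap == 1.0

    def test_mmr_equals_brute_force_matching(self):
        """Hungarian MMR equals exhaustive best one-to-one matching on
        small instances."""
        rng = np.random.default_rng(9)
        pool = [f"P{i}" for i in range(30)]
        for _ in range(10):
            refs = {f"C{i}": frozenset(rng.choice(pool, 4, replace=False))
                    for i in range(4)}
            preds = {f"Q{i}": frozenset(rng.choice(pool, 4, replace=False))
                     for i in range(4)}
            ref = cf.ComplexCatalog(refs)
            pred = cf.ComplexCatalog(preds, source="predicted")
            rep = match_metrics(pred, ref)
            rkeys, pkeys = sorted(refs), sorted(preds)
            best = 0.0
            for perm in itertools.permutations(range(4)):
                tot = sum(omega(refs[rkeys[i]], preds[pkeys[j]])
                          for i, j in enumerate(perm))
                best = max(best, tot)
            assert rep.mmr == pytest.approx(best / 4, abs=1e-12)

    def test_empty_catalog_rejected(self):
        cat = cf.ComplexCatalog({"C1": frozenset("ABC")})
        with pytest.raises(ValueError, match="non-empty"):
            match_metrics(cf.ComplexCatalog({}), cat)


class TestOptimizeParams:
    def test_single_cell_grid_returned(self):
        ref = cf.ComplexCatalog({"C1": frozenset("ABC")})
        res = optimize_params(triangle(), ref, d_grid=[0.3], o_grid=[0.6])
        assert (res.best_params.d, res.best_params.o) == (0.3, 0.6)
        assert len(res.grid) == 1

    def test_tie_breaks_to_higher_d_then_o(self):
        """A triangle is recovered identically in every cell, so all cells
        tie on composite and the (max d, max o) cell must win."""
        ref = cf.ComplexCatalog({"C1": frozenset("ABC")})
        res = optimize_params(triangle(), ref, d_grid=[0.2, 0.45],
                              o_grid=[0.5, 0.8])
        composites = {r.composite for _, _, r in res.grid}
        assert composites == {3.0}
        assert (res.best_params.d, res.best_params.o) == (0.45, 0.8)

    def test_best_cell_is_argmax(self, small_truth):
        net = cf.planted_network(small_truth, "WT")
        res = optimize_params(net, small_truth.catalogs["WT"],
                              d_grid=[0.2, 0.45], o_grid=[0.8])
        assert all(res.best_report.composite >= r.composite
                   for _, _, r in res.grid)

    def test_empty_grid_rejected(self):
        ref = cf.ComplexCatalog({"C1": frozenset("ABC")})
        with pytest.raises(ValueError, match="non-empty"):
            optimize_params(triangle(), ref, d_grid=[], o_grid=[0.5])
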