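"""Whole-network search: seeded growth, similarity, arbitration, covers."""

import numpy as np
import pytest

from oslom import Config, Cover, find_cover, gen_lpartition, gen_random, nmi_covers
from oslom.graph_io import Graph
from oslom.search import ModulePool, Searcher, similar
from oslom.cleanup import Cluster


class TestSimilar:
    def test_identical(self):
        assert similar({1, 2, 3}, {1, 2, 3})

    def test_disjoint(self):
        assert not similar({1, 2}, {3, 4})

    def test_min_denominator_rule(self):
        # overlap 3 over min(10, 4) = 3/4 > 1/2
        a = set(range(10))
        b = {0, 1, 2, 99}
        assert similar(a, b)
        assert similar(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            similar(set(), {1})


class TestModulePool:
    def test_majority_retention(self):
        pool = ModulePool()
        stable = Cluster({1, 2, 3, 4}, score=(0.1, 0.01))
        for sweep in range(3):
            pool.add(sweep, stable, 0.5)
        pool.add(0, Cluster({10, 11, 12}, score=(0.5, 0.5)), 0.5)
        kept = pool.retained(4)
        assert [c.members for c in kept] == [{1, 2, 3, 4}]

    def test_single_sweep_keeps_all(self):
        pool = ModulePool()
        pool.add(0, Cluster({1, 2}), 0.5)
        assert len(pool.retained(1)) == 1

    def test_biggest_representative_wins(self):
        pool = ModulePool()
        pool.add(0, Cluster({1, 2, 3}, score=(0.1, 0.2)), 0.5)
        pool.add(1, Cluster({1, 2, 3, 4}, score=(0.1, 0.3)), 0.5)
        pool.add(2, Cluster({1, 2, 3}, score=(0.1, 0.1)), 0.5)
        rep = pool.retained(3)[0]
        assert rep.members == {1, 2, 3, 4}


class TestGrowSeed:
    def test_isolated_vertex_empty(self, fast_cfg):
        g = Graph([("a", "b")], vertices=["a", "b", "c"])
        s = Searcher(g, fast_cfg, np.random.default_rng(0))
        assert not s.grow_seed(g.index["c"])

    def test_seed_in_strong_community_recovers_it(self, planted, fast_cfg):
        g, truth = planted
        comm = {g.index[v] for v in truth.clusters[0]}
        s = Searcher(g, fast_cfg, np.random.default_rng(3))
        hits = 0
        for v in sorted(comm)[:10]:
            c = s.grow_seed(v)
            if c and len(c.members & comm) >= len(comm) - 2 \
                    and len(c.members - comm) <= 2:
                hits += 1
        assert hits >= 7


class TestArbitrate:
    def test_true_submodules_preferred(self, planted, fast_cfg):
        g, truth = planted
        a = {g.index[v] for v in truth.clusters[0]}
        b = {g.index[v] for v in truth.clusters[1]}
        s = Searcher(g, fast_cfg, np.random.default_rng(5))
        wins = sum(len(s.arbitrate([set(a), set(b)])) == 2 for _ in range(5))
        assert wins >= 4

    def test_random_bisection_collapses_to_union(self, fast_cfg):
        g = gen_random("er", 80, avg_k=8, seed=44)
        rng = np.random.default_rng(7)
        s = Searcher(g, fast_cfg, rng)
        union_kept = 0
        for _ in range(5):
            perm = rng.permutation(g.n)
            a, b = set(perm[:40].tolist()), set(perm[40:].tolist())
            union_kept += len(s.arbitrate([a, b])) == 1
        assert union_kept >= 4

    def test_single_candidate_passthrough(self, planted, fast_cfg):
        g, truth = planted
        a = {g.index[v] for v in truth.clusters[0]}
        s = Searcher(g, fast_cfg, np.random.default_rng(1))
        assert s.arbitrate([a]) == [a]


class TestFindCover:
    def test_planted_partition_recovered(self, planted, fast_cfg):
        g, truth = planted
        cover = find_cover(g, fast_cfg, np.random.default_rng(2))
        assert nmi_covers(cover, truth) >= 0.9

    def test_deterministic_given_seed(self, planted, fast_cfg):
        g, truth = planted
        c1 = find_cover(g, fast_cfg, np.random.default_rng(9))
        c2 = find_cover(g, fast_cfg, np.random.default_rng(9))
        assert c1 == c2

    def test_cover_seeded_refinement_is_fixed_point(self, planted, fast_cfg):
        """Feeding the planted partition as the initial cover returns it
        (the two-step / snapshot-dynamics contract)."""
        g, truth = planted
        cover = find_cover(g, fast_cfg, np.random.default_rng(4), init=truth)
        assert nmi_covers(cover, truth) >= 0.95

    def test_init_with_unknown_vertices_rejected(self, planted, fast_cfg):
        g, _ = planted
        bad = Cover([{"definitely-not-a-vertex", g.ids[0]}],
                    vertices=set(g.ids) | {"definitely-not-a-vertex"})
        with pytest.raises(ValueError):
            find_cover(g, fast_cfg, np.random.default_rng(0), init=bad)

    def test_homeless_disjoint_from_clusters(self, planted, fast_cfg):
        g, _ = planted
        cover = find_cover(g, fast_cfg, np.random.default_rng(2))
        covered = set().union(*cover.clusters) if cover.clusters else set()
        assert not (cover.homeless & covered)
        assert cover.homeless | covered == set(g.ids)

    def test_directed_planted_partition_recovered(self, fast_cfg):
        """Orienting every edge of a planted partition at random must not
        hide the communities from the two-channel directed analysis."""
        g, truth = gen_lpartition(96, 3, 12.0, 0.1, seed=31)
        rng = np.random.default_rng(5)
        edges = []
        for (iu, iv) in g._wmap:
            u, v = g.ids[iu], g.ids[iv]
            edges.append((u, v) if rng.random() < 0.5 else (v, u))
        dg = Graph(edges, directed=True, vertices=g.ids)
        cover = find_cover(dg, fast_cfg, np.random.default_rng(3))
        assert nmi_covers(cover, truth) >= 0.85

    def test_weighted_partition_recovered(self, fast_cfg):
        """Communities whose internal edges carry heavy weights are recovered
        through the combined topology + weight channels."""
        g, truth = gen_lpartition(96, 3, 12.0, 0.2, seed=32)
        label = {v: i for i, c in enumerate(truth.clusters) for v in c}
        edges = []
        for (iu, iv) in g._wmap:
            u, v = g.ids[iu], g.ids[iv]
            w = 6.0 if label[u] == label[v] else 1.0
            edges.append((u, v, w))
        wg = Graph(edges, weighted=True, vertices=g.ids)
        weighted = find_cover(wg, fast_cfg, np.random.default_rng(4))
        assert nmi_covers(weighted, truth) >= 0.8

    def test_random_graph_yields_no_clusters(self, fast_cfg):
        g = gen_random("er", 150, avg_k=6, seed=77)
        cover = find_cover(g, fast_cfg, np.random.default_rng(6))
        nontrivial = {v for c in cover.clusters if 1 < len(c) < g.n for v in c}
        assert len(nontrivial) / g.n <= 0.05
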