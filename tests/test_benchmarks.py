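"""Synthetic generators and the evaluation metrics."""

import numpy as np
import pytest

from oslom import (BenchmarkSpec, Cover, Graph, gen_hierarchical,
                   gen_lpartition, gen_noisy, gen_planted, gen_random,
                   jaccard, matrix_distance, nmi_covers)


class TestGenRandom:
    def test_er_empty(self):
        g = gen_random("er", 100, avg_k=0.0, seed=1)
        assert g.E == 0

    def test_er_mean_degree(self):
        g = gen_random("er", 2000, avg_k=10.0, seed=2)
        se = np.sqrt(10.0 / 2000)  # SE of the mean degree
        assert abs(g.k.mean() - 10.0) < 3 * se + 0.15

    def test_powerlaw_truncation(self):
        g = gen_random("powerlaw", 500, gamma=2.5, max_k=50, seed=3)
        assert g.k.max() <= 50

    def test_deterministic(self):
        g1 = gen_random("er", 100, avg_k=5.0, seed=9)
        g2 = gen_random("er", 100, avg_k=5.0, seed=9)
        assert g1._wmap == g2._wmap

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            gen_random("smallworld", 10, avg_k=2)


class TestGenPlanted:
    def test_mu_zero_all_internal(self):
        spec = BenchmarkSpec(n=200, avg_k=10, max_k=20, mu=0.0, seed=4)
        g, truth = gen_planted(spec)
        label = {}
        for i, c in enumerate(truth.clusters):
            for v in c:
                label[v] = i
        cross = sum(1 for (iu, iv) in g._wmap
                    if label[g.ids[iu]] != label[g.ids[iv]])
        assert cross == 0

    def test_mixing_parameter_realized(self):
        spec = BenchmarkSpec(n=1000, avg_k=15, max_k=40, mu=0.3, seed=5)
        g, truth = gen_planted(spec)
        label = {}
        for i, c in enumerate(truth.clusters):
            for v in c:
                label[v] = i
        ext = np.zeros(g.n)
        for (iu, iv) in g._wmap:
            u, v = g.ids[iu], g.ids[iv]
            if label[u] != label[v]:
                ext[iu] += 1
                ext[iv] += 1
        frac = (ext[g.k > 0] / g.k[g.k > 0]).mean()
        assert abs(frac - 0.3) < 0.02

    def test_sizes_tile_n(self):
        spec = BenchmarkSpec(n=500, avg_k=12, max_k=30, mu=0.2, seed=6)
        _, truth = gen_planted(spec)
        assert sum(len(c) for c in truth.clusters) == 500
        assert all(len(c) >= 2 for c in truth.clusters)

    def test_overlap_memberships(self):
        spec = BenchmarkSpec(n=300, avg_k=14, max_k=30, mu=0.2,
                             overlap_fraction=0.1, memberships=2, seed=7)
        _, truth = gen_planted(spec)
        counts = truth.membership_counts()
        assert sum(1 for c in counts.values() if c >= 2) == 30

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkSpec(n=100, s_min=2, s_max=2, mu=1.5)


class TestGenLPartition:
    def test_equal_groups_and_mixing(self):
        g, truth = gen_lpartition(400, 4, 12.0, 0.1, seed=8)
        assert [len(c) for c in truth.clusters] == [100] * 4
        label = {v: i for i, c in enumerate(truth.clusters) for v in c}
        ext = sum(1 for (iu, iv) in g._wmap
                  if label[g.ids[iu]] != label[g.ids[iv]])
        assert abs(ext / g.E - 0.1) < 0.03

    def test_indivisible_n_rejected(self):
        with pytest.raises(ValueError):
            gen_lpartition(101, 4, 10.0, 0.1)


class TestGenHierarchical:
    def test_mixing_fractions_realized(self):
        spec = BenchmarkSpec(n=512, avg_k=16, max_k=32, mu1=0.1, mu2=0.2, seed=9)
        g, fine, coarse = gen_hierarchical(spec, 4, 4)
        micro = {v: i for i, c in enumerate(fine.clusters) for v in c}
        macro = {v: i for i, c in enumerate(coarse.clusters) for v in c}
        f1 = f2 = 0
        for (iu, iv) in g._wmap:
            u, v = g.ids[iu], g.ids[iv]
            if macro[u] != macro[v]:
                f1 += 1
            elif micro[u] != micro[v]:
                f2 += 1
        assert abs(f1 / g.E - 0.1) < 0.02
        assert abs(f2 / g.E - 0.2) < 0.02

    def test_mu2_zero_collapses_micro_to_single_level(self):
        spec = BenchmarkSpec(n=256, avg_k=12, max_k=24, mu1=0.1, mu2=0.0, seed=10)
        g, fine, coarse = gen_hierarchical(spec, 4, 4)
        micro = {v: i for i, c in enumerate(fine.clusters) for v in c}
        macro = {v: i for i, c in enumerate(coarse.clusters) for v in c}
        meso = sum(1 for (iu, iv) in g._wmap
                   if macro[g.ids[iu]] == macro[g.ids[iv]]
                   and micro[g.ids[iu]] != micro[g.ids[iv]])
        assert meso == 0

    def test_infeasible_mixture_rejected(self):
        spec = BenchmarkSpec(n=256, mu1=0.6, mu2=0.4, seed=1)
        with pytest.raises(ValueError):
            gen_hierarchical(spec, 4, 4)


class TestGenNoisy:
    def test_zero_noise_unchanged(self):
        g = gen_random("er", 100, avg_k=6, seed=11)
        truth = Cover([], vertices=set(g.ids))
        g2, _, noise = gen_noisy(g, truth, 0, seed=12)
        assert noise == set()
        assert g2.E == g.E

    def test_preferential_targets_have_high_degree(self):
        g = gen_random("powerlaw", 300, gamma=2.2, max_k=40, seed=13)
        truth = Cover([], vertices=set(g.ids))
        g2, _, noise = gen_noisy(g, truth, 100, seed=14)
        base_ids = set(g.ids)
        deg_of = dict(zip(g.ids, g.k))
        touched = []
        for (iu, iv) in g2._wmap:
            u, v = g2.ids[iu], g2.ids[iv]
            if (u in noise) != (v in noise):
                touched.append(deg_of[u if u in base_ids else v])
        assert np.mean(touched) > g.k.mean()

    def test_noise_outside_ground_truth(self):
        spec = BenchmarkSpec(n=200, avg_k=10, max_k=20, mu=0.2, seed=15)
        base, truth = gen_planted(spec)
        g2, truth2, noise = gen_noisy(base, truth, 50, seed=16)
        clustered = set().union(*truth2.clusters)
        assert not (noise & clustered)


class TestMetrics:
    def test_identical_inputs(self):
        cov = Cover([{"a", "b"}, {"c", "d"}], vertices={"a", "b", "c", "d"})
        assert nmi_covers(cov, cov) == 1.0
        assert jaccard({"a"}, {"a"}) == 1.0
        g = Graph([("a", "b", 2.0)], weighted=True)
        assert matrix_distance(g, g) == 0.0

    def test_jaccard_hand_count(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_all_in_one_cover_is_uninformative(self):
        spec = BenchmarkSpec(n=400, avg_k=12, max_k=30, mu=0.1, seed=17)
        _, truth = gen_planted(spec)
        blob = Cover([set(truth.vertices)], vertices=truth.vertices)
        assert nmi_covers(blob, truth) < 0.2

    def test_nmi_symmetric(self):
        verts = set(map(str, range(40)))
        a = Cover([set(map(str, range(20))), set(map(str, range(20, 40)))],
                  vertices=verts)
        b = Cover([set(map(str, range(15))), set(map(str, range(15, 40)))],
                  vertices=verts)
        assert nmi_covers(a, b) == pytest.approx(nmi_covers(b, a))

    def test_matrix_distance_range_and_normalization(self):
        g1 = Graph([("a", "b", 1.0)], weighted=True)
        g2 = Graph([("a", "b", 5.0)], weighted=True)
        # same pattern, different total weight -> distance 0 after normalizing
        assert matrix_distance(g1, g2) == pytest.approx(0.0)
        g3 = Graph([("a", "c", 1.0)], weighted=True, vertices=["a", "b", "c"])
        assert 0.0 <= matrix_distance(g1, g3) <= 2.0

    def test_disjoint_universes_rejected(self):
        a = Cover([{"a"}], vertices={"a"})
        b = Cover([{"z"}], vertices={"z"})
        with pytest.raises(ValueError):
            nmi_covers(a, b)
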