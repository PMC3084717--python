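"""Null-distribution machinery: exact pmf, bootstrap scores, channel merging.

The internal-degree law is anchored to a brute-force enumeration of the
perfect matchings of the external stub pool that are compatible with the
cluster's fixed internal degree (no further cluster-cluster pairs).
"""

from itertools import combinations
from math import comb, factorial

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, kstest

from oslom.graph_io import Graph
from oslom.significance import (StubContext, VertexScorer, bootstrap_r,
                                combine_scores, internal_degree_pmf,
                                internal_degree_tail, weight_score)


def matching_oracle(a: int, b: int, g: int) -> list[float]:
    """Enumerate constrained stub matchings; count candidate-cluster pairs.

    Stubs: a on the candidate, b on the cluster (which may not pair among
    themselves, since the cluster's internal degree is fixed), g on the rest.
    """
    labels = ["i"] * a + ["C"] * b + ["G"] * g

    counts: dict[int, int] = {}

    def rec(remaining: tuple, t: int):
        if not remaining:
            counts[t] = counts.get(t, 0) + 1
            return
        first = remaining[0]
        for j in range(1, len(remaining)):
            pair = {labels[first], labels[remaining[j]]}
            if pair == {"C"}:
                continue
            rest = remaining[1:j] + remaining[j + 1:]
            rec(rest, t + (pair == {"i", "C"}))

    rec(tuple(range(a + b + g)), 0)
    total = sum(counts.values())
    if total == 0:
        return []
    return [counts.get(t, 0) / total for t in range(min(a, b) + 1)]


def all_small_contexts(max_stubs: int = 12):
    for a in range(0, max_stubs + 1):
        for b in range(0, max_stubs + 1 - a):
            for g in range(0, max_stubs + 1 - a - b):
                tot = a + b + g
                if tot == 0 or tot % 2 or b > a + g:
                    continue
                yield a, b, g


class TestInternalDegreePmf:
    def test_matches_enumeration_oracle_small_pools(self):
        worst = 0.0
        for a, b, g in all_small_contexts(10):
            oracle = matching_oracle(a, b, g)
            if not oracle:
                continue
            pmf = internal_degree_pmf(StubContext(a, b, g))
            worst = max(worst, np.abs(pmf - np.array(oracle)).max())
        assert worst < 1e-12

    def test_matches_scipy_hypergeometric(self):
        for a, b, g in [(5, 12, 83), (20, 100, 2000), (3, 3, 4)]:
            pmf = internal_degree_pmf(StubContext(a, b, g))
            ref = hypergeom.pmf(np.arange(min(a, b) + 1), a + g, a, b)
            assert np.allclose(pmf, ref, atol=1e-12)

    def test_no_boundary_stubs_point_mass(self):
        pmf = internal_degree_pmf(StubContext(4, 0, 8))
        assert pmf.tolist() == [1.0]

    @given(st.integers(0, 30), st.integers(0, 40), st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_normalization(self, a, b, g):
        if (a + b + g) % 2 or a + b + g == 0 or b > a + g:
            return
        pmf = internal_degree_pmf(StubContext(a, b, g))
        assert abs(pmf.sum() - 1.0) < 1e-12
        assert (pmf >= 0).all()

    def test_parity_rejected(self):
        with pytest.raises(ValueError):
            StubContext(1, 1, 1)


class TestBootstrap:
    def test_interval_bounds(self, rng):
        tail = internal_degree_tail(StubContext(5, 12, 83))
        for kin in range(len(tail) - 1):
            r = bootstrap_r(kin, tail, rng)
            assert tail[kin + 1] <= r <= tail[kin]

    def test_uniform_when_kin_from_null(self, rng):
        ctx = StubContext(5, 12, 83)
        pmf = internal_degree_pmf(ctx)
        tail = internal_degree_tail(ctx)
        kins = rng.choice(len(pmf), size=30_000, p=pmf)
        rs = [bootstrap_r(int(k), tail, rng) for k in kins]
        assert kstest(rs, "uniform").pvalue > 0.01

    def test_point_mass_gives_uniform(self, rng):
        tail = internal_degree_tail(StubContext(4, 0, 8))
        rs = [bootstrap_r(0, tail, rng) for _ in range(5000)]
        assert kstest(rs, "uniform").pvalue > 0.01

    def test_requires_rng(self):
        tail = internal_degree_tail(StubContext(2, 2, 4))
        with pytest.raises(ValueError):
            bootstrap_r(0, tail, None)


class TestWeightScore:
    def test_harmonic_mean_exponential(self):
        # h = 2*2*6/(2+6) = 3, w = 3 -> exp(-1)
        assert weight_score(3.0, 2.0, 6.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_limits_and_monotonicity(self):
        assert weight_score(1e-12, 1.0, 1.0) == pytest.approx(1.0, abs=1e-9)
        assert weight_score(1.0, 2.0, 2.0) > weight_score(2.0, 2.0, 2.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weight_score(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            weight_score(1.0, -1.0, 1.0)


class TestCombineScores:
    def test_identity_for_one(self):
        assert combine_scores([0.37]) == 0.37

    def test_two_uniform_closed_form(self):
        # F_2(0.1) = 0.1 * (1 + ln 10)
        assert combine_scores([0.1, 1.0]) == pytest.approx(0.1 * (1 + np.log(10)),
                                                           abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_uniform_output_under_null(self, rng, k):
        out = [combine_scores(rng.random(k)) for _ in range(20_000)]
        assert kstest(out, "uniform").pvalue > 0.01

    def test_monotone_in_each_argument(self, rng):
        base = [0.3, 0.4]
        lo = combine_scores([0.2, 0.4])
        hi = combine_scores([0.5, 0.4])
        assert lo < combine_scores(base) < hi

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            combine_scores([])
        with pytest.raises(ValueError):
            combine_scores([0.1, 1.5])


class TestVertexScorer:
    def test_sequential_scores_iid_uniform_on_configuration_null(self):
        """Boundary scores of a fixed subset are jointly uniform on raw
        configuration-model multigraphs (scored sequentially)."""
        from collections import Counter

        rng = np.random.default_rng(99)
        deg = np.clip((rng.pareto(1.5, 120) + 1) * 3, 3, 20).astype(int)
        if deg.sum() % 2:
            deg[0] += 1
        rs_all = []
        for _ in range(150):
            stubs = np.repeat(np.arange(deg.size), deg)
            perm = rng.permutation(stubs)
            cnt = Counter()
            for u, v in zip(perm[0::2], perm[1::2]):
                if u != v:
                    cnt[(min(u, v), max(u, v))] += 1
            g = Graph([(u, v, float(c)) for (u, v), c in cnt.items()],
                      weighted=True, multiplicity_weights=True,
                      vertices=range(deg.size))
            scorer = VertexScorer(g, rng)
            _, rs = scorer.score_externals(set(range(6)))
            rs_all.extend(rs.tolist())
        assert kstest(rs_all, "uniform").pvalue > 0.01

    def test_marginal_matches_sequential_first(self, er_graph, rng):
        scorer = VertexScorer(er_graph, rng)
        members = set(range(8))
        r = scorer.r_of(50, members)
        assert 0.0 <= r <= 1.0

    def test_directed_two_channels(self, rng):
        g = Graph([(i, (i + 1) % 10) for i in range(10)]
                  + [(i, (i + 3) % 10) for i in range(10)], directed=True)
        scorer = VertexScorer(g, rng)
        _, rs = scorer.score_externals({0, 1, 2})
        assert rs.shape == (7,)
        assert ((0 <= rs) & (rs <= 1)).all()
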