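"""Configuration-model null probabilities and per-vertex uniform scores.

The null model is the configuration model: every vertex keeps its degree and
edge stubs are paired uniformly at random, with the internal degree of the
cluster ``C`` under scrutiny held fixed at its observed value.  Fixing the
internal degree means the ``kC_out`` free stubs of the cluster pair only with
stubs *outside* the cluster.  Writing ``a = k_i`` for the candidate vertex's
stubs and ``g = kG_out`` for the stubs of the rest of the graph, a counting
argument over the perfect matchings of the external stub pool (candidate and
rest-of-graph stubs may still pair among themselves; the number of matchings
of the leftover pool is the same for every allocation of the cluster's
partners) shows that the candidate's internal degree follows the
hypergeometric law

    P(k_in = t) = C(a, t) C(g, b - t) / C(a + g, b),     b = kC_out,

i.e. the cluster's free stubs sample the external stub pool without
replacement.  The expression is evaluated through log-gamma, so arbitrarily
large counts never overflow; correctness is anchored to a brute-force
enumeration of the constrained stub matchings on small pools (test suite).

Jointly, the internal degrees of all external vertices are multivariate
hypergeometric.  Scoring the candidates *sequentially* — each one against
the stubs not yet consumed by previously scored candidates — turns the
vector of scores into exactly independent Uniform(0,1) variables under the
null (chain rule plus the randomized probability integral transform), which
is what makes the order-statistics machinery downstream exactly calibrated.

Because the internal degree is discrete, its upper-tail probability is
turned into a continuous score ``r`` by the bootstrap: ``r`` is drawn
uniformly on ``[T(k_in + 1), T(k_in)]`` with ``T(x) = P(X >= x)``.  Taking,
e.g., interval midpoints instead would bias the scores and manufacture
significant clusters in random graphs.

Directed graphs contribute two channels (candidate out-stubs against the
cluster's free in-stubs, and vice versa), each hypergeometric in its own
bipartite pool.  Weighted graphs contribute a channel built from the null
law of edge weights (exponential with harmonic-mean scale).  Channels are
combined with the exact CDF of a product of independent uniforms, which is
again Uniform(0,1) under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from math import exp

from scipy.special import gammaln

from .graph_io import Graph

__all__ = ["StubContext", "internal_degree_pmf", "internal_degree_tail",
           "bootstrap_r", "weight_score", "combine_scores", "VertexScorer"]


@dataclass(frozen=True)
class StubContext:
    """Degree decomposition for one candidate-vs-cluster evaluation.

    k_i     : stub count of the candidate vertex
    kC_out  : free (external) stubs of the cluster
    kG_out  : stubs of the rest of the graph (everything but C and i)
    """

    k_i: int
    kC_out: int
    kG_out: int

    def __post_init__(self):
        if min(self.k_i, self.kC_out, self.kG_out) < 0:
            raise ValueError("stub counts must be non-negative")
        if (self.k_i + self.kC_out + self.kG_out) % 2:
            raise ValueError(
                "total external stub count must be even to admit a perfect matching")
        if self.kC_out > self.k_i + self.kG_out:
            raise ValueError("cluster stubs exceed the available external pool")


def _log_comb(n, k):
    with np.errstate(invalid="ignore"):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hyper_logpmf(t: np.ndarray, total: int, good: int, draws: int) -> np.ndarray:
    return (_log_comb(good, t) + _log_comb(total - good, draws - t)
            - _log_comb(total, draws))


def _hyper_tail(total: int, good: int, draws: int) -> np.ndarray:
    """Upper tail T with T[x] = P(X >= x) for x = 0..tmax+1 (T[-1] = 0)."""
    tmax = min(good, draws)
    t = np.arange(tmax + 1)
    with np.errstate(invalid="ignore"):
        logp = _hyper_logpmf(t, total, good, draws)
    p = np.exp(logp)
    p[~np.isfinite(logp)] = 0.0
    s = p.sum()
    if s <= 0:
        raise ValueError(f"infeasible hypergeometric ({total}, {good}, {draws})")
    p /= s
    tail = np.zeros(tmax + 2)
    tail[:-1] = p[::-1].cumsum()[::-1]
    tail[0] = 1.0
    return tail


def internal_degree_pmf(ctx: StubContext) -> np.ndarray:
    """Null pmf of the candidate's internal degree, index t = 0..min(k_i, kC_out).

    Hypergeometric: the cluster's kC_out free stubs sample the k_i + kG_out
    external stubs without replacement and t counts the hits on the candidate.
    """
    a, b, g = ctx.k_i, ctx.kC_out, ctx.kG_out
    tail = _hyper_tail(a + g, a, b)
    return np.maximum(tail[:-1] - tail[1:], 0.0)


def internal_degree_tail(ctx: StubContext) -> np.ndarray:
    """Upper tail T with T[x] = P(X >= x), length tmax + 2 (T[tmax+1] = 0)."""
    a, b, g = ctx.k_i, ctx.kC_out, ctx.kG_out
    return _hyper_tail(a + g, a, b)


def bootstrap_r(kin_obs: int, tail: np.ndarray, rng: np.random.Generator) -> float:
    """Randomized tail probability: uniform on [T(kin+1), T(kin)].

    When the observed internal degree is itself drawn from the null pmf the
    result is exactly Uniform(0,1).
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    kin_obs = min(max(int(kin_obs), 0), len(tail) - 2)
    hi = tail[kin_obs]
    lo = tail[kin_obs + 1]
    return min(max(float(lo + rng.random() * (hi - lo)), 0.0), 1.0)


def weight_score(w: float, avg_w_i: float, avg_w_j: float) -> float:
    """Upper-tail probability of an edge weight under the exponential null.

    The null scale is the harmonic mean ``h`` of the average incident weights
    of the two endpoints (more sensitive to the small value than the
    arithmetic mean), so ``r_w = exp(-w / h)``: close to 1 for weak edges and
    strictly decreasing in ``w``.
    """
    if w <= 0 or avg_w_i <= 0 or avg_w_j <= 0:
        raise ValueError("weights and average weights must be positive")
    h = 2.0 * avg_w_i * avg_w_j / (avg_w_i + avg_w_j)
    return float(np.exp(-w / h))


def _product_uniform_cdf(x: float, k: int) -> float:
    """F_k(x) = x * sum_{j<k} (-ln x)^j / j!, CDF of a product of k uniforms."""
    if x <= 0.0:
        return 0.0
    if k == 1:
        return float(min(1.0, x))
    lx = -np.log(x)
    acc = term = 1.0
    for j in range(1, k):
        term *= lx / j
        acc += term
    return float(min(1.0, x * acc))


def combine_scores(rs) -> float:
    """Collapse up to four channel scores into one Uniform(0,1) variable.

    Applies the exact CDF of a product of k independent uniforms to the
    product of the channels; k = 1 is the identity.
    """
    rs = list(rs)
    if not 1 <= len(rs) <= 4:
        raise ValueError("need between 1 and 4 scores")
    for r in rs:
        if not -1e-9 <= r <= 1.0 + 1e-9:
            raise ValueError(f"score {r} outside [0, 1]")
    rs = [min(max(float(r), 0.0), 1.0) for r in rs]
    if len(rs) == 1:
        return rs[0]
    return _product_uniform_cdf(float(np.prod(rs)), len(rs))


class VertexScorer:
    """Scores external vertices against a member set, with tail caching.

    One scorer is built per graph; hypergeometric tails are cached by
    (pool, candidate stubs, draws), shared across cleanup trials, sweeps and
    hierarchy levels.
    """

    def __init__(self, graph: Graph, rng: np.random.Generator):
        self.g = graph
        self.rng = rng
        self._tails: dict[tuple[int, int, int], np.ndarray] = {}
        # lgamma lookup: _lg[i] = log(i!), up to the total stub count
        top = max(4, graph.total_stubs * (2 if graph.directed else 1)) + 3
        self._lg = gammaln(np.arange(top + 1, dtype=float) + 1.0)
        if graph.weighted and not graph.multiplicity_weights:
            with np.errstate(divide="ignore", invalid="ignore"):
                self.avg_w = np.where(graph.k > 0, graph.s / np.maximum(graph.k, 1), 0.0)

    def _tail_fast(self, total: int, good: int, draws: int) -> np.ndarray:
        """Hypergeometric upper tail via the precomputed log-factorial table."""
        lg = self._lg
        tmax = min(good, draws)
        tmin = max(0, draws - (total - good))
        t = np.arange(tmin, tmax + 1)
        logp = (lg[good] - lg[t] - lg[good - t]
                + lg[total - good] - lg[draws - t] - lg[total - good - draws + t]
                - lg[total] + lg[draws] + lg[total - draws])
        p = np.exp(logp - logp.max())
        p /= p.sum()
        tail = np.zeros(tmax + 2)
        tail[tmin:-1] = p[::-1].cumsum()[::-1]
        tail[:tmin + 1] = 1.0
        tail[0] = 1.0
        return tail

    def _tail(self, total: int, good: int, draws: int) -> np.ndarray:
        key = (total, good, draws)
        t = self._tails.get(key)
        if t is None:
            t = self._tail_fast(total, good, draws)
            self._tails[key] = t
        return t

    # -- degree bookkeeping --------------------------------------------------
    def _boundary_counts(self, members: set[int]):
        """(kC_out, kG_out) in the undirected view, given the member set."""
        g = self.g
        m_stubs = g.internal_stubs(members)
        kC_out = int(sum(int(g.k[j]) for j in members)) - m_stubs
        kG_out = g.total_stubs - m_stubs - kC_out
        return kC_out, kG_out

    # -- single-vertex (marginal) score --------------------------------------
    def r_of(self, v: int, members: set[int], m_stubs: int | None = None) -> float:
        """Marginal uniform score of vertex ``v`` relative to ``members``."""
        g = self.g
        if v in members:
            raise ValueError("candidate must be external to the member set")
        rs: list[float] = []
        if g.directed:
            if m_stubs is None:
                m_stubs = sum(1 for (iu, iv) in g._wmap
                              if iu in members and iv in members)
            m_int = m_stubs
            kC_in_free = int(sum(g.k_in[j] for j in members)) - m_int
            kC_out_free = int(sum(g.k_out[j] for j in members)) - m_int
            pool_out = int(g.k_out.sum()) - int(sum(g.k_out[j] for j in members))
            pool_in = int(g.k_in.sum()) - int(sum(g.k_in[j] for j in members))
            kin_out = sum(1 for j in g.successors[v] if j in members)
            kin_in = sum(1 for j in g.predecessors[v] if j in members)
            rs.append(self._r_step(kin_out, pool_out, int(g.k_out[v]), kC_in_free))
            rs.append(self._r_step(kin_in, pool_in, int(g.k_in[v]), kC_out_free))
        else:
            if m_stubs is None:
                m_stubs = self.g.internal_stubs(members)
            kC_out = int(sum(int(g.k[j]) for j in members)) - m_stubs
            a = int(g.k[v])
            kG_out = g.total_stubs - m_stubs - kC_out - a
            kin = g.degree_between(v, members)
            rs.append(self._r_step(kin, a + kG_out, a, kC_out))
        if g.weighted and not g.multiplicity_weights:
            rs.append(self._weight_channel(v, members))
        return combine_scores(rs)

    def _weight_channel(self, v: int, members: set[int]) -> float:
        edge_scores = []
        for j, w in self.g.adj[v].items():
            if j in members:
                edge_scores.append(weight_score(w, self.avg_w[v], self.avg_w[j]))
        if not edge_scores:
            return float(self.rng.random())
        return _product_uniform_cdf(float(np.prod(edge_scores)), len(edge_scores)) \
            if len(edge_scores) > 1 else edge_scores[0]

    def _r_step(self, kin: int, pool: int, a: int, draws: int) -> float:
        """One sequential bootstrap draw; O(kin) via partial pmf sums.

        Only T(kin) and T(kin+1) are needed, i.e. the pmf at 0..kin; the
        hypergeometric pmf is analytically normalized so no full tail is
        built.  On restricted candidate pools the without-replacement
        invariant (remaining draws <= remaining pool) can be violated, so the
        counts are clamped; on the full external pool they are exact.
        """
        a = min(a, pool)
        draws = min(draws, pool)
        kin = min(kin, a, draws)
        lg = self._lg
        tmin = max(0, draws - (pool - a))
        kin = max(kin, tmin)
        # scalar loop: kin is almost always 0 or a small integer
        base = float(lg[a] + lg[pool - a] - lg[pool] + lg[draws] + lg[pool - draws])
        below = 0.0
        pk = 0.0
        for t in range(tmin, kin + 1):
            pk = exp(base - float(lg[t]) - float(lg[a - t]) - float(lg[draws - t])
                     - float(lg[pool - a - draws + t]))
            if t < kin:
                below += pk
        hi = max(0.0, 1.0 - below)   # T(kin)
        lo = max(0.0, hi - pk)       # T(kin + 1)
        return min(1.0, lo + self.rng.random() * (hi - lo))

    def _r_bulk(self, kin: np.ndarray, pool: np.ndarray, a: np.ndarray,
                draws: np.ndarray) -> np.ndarray:
        """Vectorized bootstrap draws for many (kin, pool, a, draws) rows."""
        m = kin.size
        if m == 0:
            return np.empty(0)
        a = np.minimum(a, pool)
        draws = np.minimum(draws, pool)
        kin = np.minimum(kin, np.minimum(a, draws))
        tmin = np.maximum(0, draws - (pool - a))
        kin = np.maximum(kin, tmin)
        lg = self._lg
        tmax = int(kin.max())
        t = np.arange(tmax + 1)[None, :]
        valid = (t >= tmin[:, None]) & (t <= kin[:, None])
        tc = np.where(valid, t, 0)
        with np.errstate(invalid="ignore"):
            logp = (lg[a][:, None] - lg[tc] - lg[(a[:, None] - tc)]
                    + lg[(pool - a)][:, None] - lg[np.maximum(draws[:, None] - tc, 0)]
                    - lg[np.maximum((pool - a - draws)[:, None] + tc, 0)]
                    - lg[pool][:, None] + lg[draws][:, None] + lg[(pool - draws)][:, None])
        p = np.where(valid, np.exp(logp), 0.0)
        pk = p[np.arange(m), kin]
        below = p.sum(axis=1) - pk
        hi = np.maximum(0.0, 1.0 - below)
        lo = np.maximum(0.0, hi - pk)
        return np.clip(lo + self.rng.random(m) * (hi - lo), 0.0, 1.0)

    # -- sequential scoring of a full candidate pool --------------------------
    def score_externals(self, members: set[int],
                        candidates: list[int] | None = None) -> tuple[list[int], np.ndarray]:
        """Score external vertices against ``members`` (sequential nulls).

        Candidates are processed in a random order; each candidate's null
        conditions on the cluster stubs already consumed by earlier ones, so
        under the configuration-model null the returned scores are exactly
        independent Uniform(0,1).  When ``candidates`` is None all non-member
        vertices are scored.  Returns (vertex indices, r values), unsorted.
        """
        g = self.g
        full_pool = candidates is None
        if candidates is None:
            mask = np.ones(g.n, dtype=bool)
            mask[list(members)] = False
            cand_arr = np.nonzero(mask)[0]
            candidates = cand_arr.tolist()
        else:
            cand_arr = np.asarray(candidates, dtype=np.int64)
        order = self.rng.permutation(len(candidates))
        rs = np.empty(len(candidates))
        weighted = g.weighted and not g.multiplicity_weights

        if g.directed:
            m_int = sum(1 for (iu, iv) in g._wmap
                        if iu in members and iv in members)
            kin_out_map: dict[int, int] = {}
            kin_in_map: dict[int, int] = {}
            for j in members:
                for u in g.predecessors[j]:
                    if u not in members:
                        kin_out_map[u] = kin_out_map.get(u, 0) + 1
                for u in g.successors[j]:
                    if u not in members:
                        kin_in_map[u] = kin_in_map.get(u, 0) + 1
            draws_out = int(sum(g.k_in[j] for j in members)) - m_int
            draws_in = int(sum(g.k_out[j] for j in members)) - m_int
            if full_pool:
                pool_out = int(g.k_out.sum()) - int(sum(g.k_out[j] for j in members))
                pool_in = int(g.k_in.sum()) - int(sum(g.k_in[j] for j in members))
            else:
                pool_out = int(sum(g.k_out[v] for v in candidates))
                pool_in = int(sum(g.k_in[v] for v in candidates))
                draws_out = min(draws_out, pool_out)
                draws_in = min(draws_in, pool_in)
            for pos in order:
                v = candidates[pos]
                a_out, a_in = int(g.k_out[v]), int(g.k_in[v])
                kin_out = min(kin_out_map.get(v, 0), a_out, draws_out)
                kin_in = min(kin_in_map.get(v, 0), a_in, draws_in)
                chan = [self._r_step(kin_out, pool_out, a_out, draws_out),
                        self._r_step(kin_in, pool_in, a_in, draws_in)]
                if weighted:
                    chan.append(self._weight_channel(v, members))
                rs[pos] = combine_scores(chan)
                pool_out -= a_out
                pool_in -= a_in
                draws_out -= kin_out
                draws_in -= kin_in
        else:
            m_stubs = g.internal_stubs(members)
            kin_map: dict[int, int] = {}
            for j in members:
                a_j = g.adj[j]
                if g.multiplicity_weights:
                    for u, w in a_j.items():
                        if u not in members:
                            kin_map[u] = kin_map.get(u, 0) + int(round(w))
                else:
                    for u in a_j:
                        if u not in members:
                            kin_map[u] = kin_map.get(u, 0) + 1
            draws = int(sum(int(g.k[j]) for j in members)) - m_stubs
            if full_pool:
                pool = g.total_stubs - m_stubs - draws
            else:
                pool = int(g.k[cand_arr].sum())
                draws = min(draws, pool)
            ordered_cands = cand_arr[order]
            a_vec = g.k[ordered_cands].astype(np.int64)
            kin_full = np.zeros(g.n, dtype=np.int64)
            if kin_map:
                ks, vs = zip(*kin_map.items())
                kin_full[list(ks)] = vs
            kin_vec = kin_full[ordered_cands]
            shift = np.zeros(len(order), dtype=np.int64)
            shift[1:] = np.cumsum(a_vec)[:-1]
            pool_vec = pool - shift
            shift[1:] = np.cumsum(kin_vec)[:-1]
            shift[0] = 0
            draws_vec = draws - shift
            feasible = (np.all(kin_vec <= np.minimum(a_vec, draws_vec))
                        and np.all(draws_vec <= pool_vec) and np.all(draws_vec >= 0))
            if feasible:
                # bulk path: the k_in = 0 candidates (the vast majority) need
                # only T(1) = 1 - P(0), computed vectorized from the lgamma table
                lg = self._lg
                zero = kin_vec == 0
                pb, db, av = pool_vec[zero], draws_vec[zero], a_vec[zero]
                full = pb - av - db < 0
                with np.errstate(invalid="ignore"):
                    lo = 1.0 - np.exp(lg[pb - av] - lg[np.maximum(pb - av - db, 0)]
                                      - lg[pb] + lg[pb - db])
                lo[full] = 1.0
                rz = lo + self.rng.random(lo.size) * (1.0 - lo)
                rs_seq = np.empty(len(order))
                rs_seq[zero] = rz
                nz = np.nonzero(~zero)[0]
                rs_seq[nz] = self._r_bulk(kin_vec[nz], pool_vec[nz],
                                          a_vec[nz], draws_vec[nz])
                if weighted:
                    for j in range(len(order)):
                        rs_seq[j] = combine_scores(
                            [rs_seq[j],
                             self._weight_channel(candidates[order[j]], members)])
                rs[order] = np.clip(rs_seq, 0.0, 1.0)
            else:
                for pos in order:
                    v = candidates[pos]
                    a = int(g.k[v])
                    kin = min(kin_map.get(v, 0), a, draws)
                    r = self._r_step(kin, pool, a, draws)
                    if weighted:
                        r = combine_scores([r, self._weight_channel(v, members)])
                    rs[pos] = r
                    pool -= a
                    draws -= kin
        return candidates, rs
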