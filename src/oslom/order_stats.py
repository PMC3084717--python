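"""Order statistics of uniform scores and the cluster score.

Under the configuration-model null the per-vertex scores ``r`` of the
``n`` external vertices of a cluster are independent Uniform(0,1) variables.
The probability that the q-th smallest of them is below an observed value is
the binomial upper tail

    Omega_q(r; n) = sum_{i=q}^{n} C(n, i) r^i (1-r)^(n-i)
                  = I_r(q, n - q + 1)        (regularized incomplete beta)

and the raw cluster score is ``c = min_q Omega_q(r_(q))``: the most
surprising rank of the boundary.  Each ``Omega_q(U_(q))`` is uniform
marginally, but the minimum over ranks is not, so its null cumulative
distribution ``Phi`` — which depends only on the size of the external pool —
is tabulated by Monte Carlo.  ``Phi(c)`` is the fitness that significant
clusters minimize.

To keep evaluation and tabulation mutually consistent (and hence ``Phi(c)``
exactly uniform under the null), the minimum runs over ranks ``q <= rank_cap``
on both sides, and large pools are bucketed onto a geometric grid of
effective sizes used identically when scoring and when tabulating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

from .graph_io import Graph
from .significance import VertexScorer

__all__ = ["omega_q", "min_order_statistic", "NullTable", "tabulate_null",
           "NullTableCache", "effective_pool", "cluster_score"]

RANK_CAP = 128          # ranks examined by the min statistic
POOL_EXACT_MAX = 64     # pools up to this size are never bucketed
POOL_GRID_RATIO = 1.03  # geometric spacing of bucketed pool sizes


def omega_q(r, q, n):
    """P(q-th smallest of n uniforms <= r); vectorized in any argument."""
    r = np.asarray(r, dtype=float)
    q = np.asarray(q)
    n = np.asarray(n)
    if np.any((q < 1) | (q > n)):
        raise ValueError("need 1 <= q <= n")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("r must lie in [0, 1]")
    out = betainc(q, n - q + 1, r)
    return float(out) if out.ndim == 0 else out


def min_order_statistic(rs_sorted, n: int | None = None,
                        rank_cap: int = RANK_CAP) -> tuple[float, int]:
    """Raw cluster score: min over ranks of Omega_q, and the argmin rank.

    ``rs_sorted`` must be non-decreasing; ``n`` defaults to its length.
    Ties break toward the smallest rank.
    """
    rs = np.asarray(rs_sorted, dtype=float)
    if rs.size == 0:
        raise ValueError("empty score list")
    if n is None:
        n = rs.size
    k = min(rs.size, n, rank_cap)
    q = np.arange(1, k + 1)
    om = omega_q(rs[:k], q, n)
    q_star = int(np.argmin(om))
    return float(om[q_star]), q_star + 1


@dataclass
class NullTable:
    """Monte-Carlo null distribution of the raw score c for one pool size."""

    n_ext: int
    samples: int
    seed: int
    cs: np.ndarray  # sorted raw scores under the null

    def phi(self, c: float) -> float:
        """Empirical cumulative probability of the raw score (linear interp)."""
        if c <= 0.0:
            return 0.0
        if c >= 1.0:
            return 1.0
        xs = self.cs
        m = xs.size
        # piecewise-linear CDF through (0,0), (x_i, i/(m+1)), (1,1)
        i = np.searchsorted(xs, c)
        x0 = 0.0 if i == 0 else xs[i - 1]
        x1 = 1.0 if i == m else xs[i]
        y0 = i / (m + 1)
        y1 = (i + 1) / (m + 1)
        if x1 == x0:
            return float(y1)
        return float(y0 + (y1 - y0) * (c - x0) / (x1 - x0))

    def quantile(self, p: float) -> float:
        """Raw-score threshold whose null cumulative probability is p."""
        return float(np.quantile(self.cs, p))


def tabulate_null(n_ext: int, samples: int = 10_000, seed: int = 0,
                  rank_cap: int = RANK_CAP) -> NullTable:
    """Tabulate the null distribution of c for a pool of n_ext uniforms.

    Only the smallest ``rank_cap`` order statistics matter, so they are
    generated directly through the Renyi representation
    ``U_(q) = 1 - exp(-sum_{j<=q} E_j / (n - j + 1))``.
    """
    if n_ext < 1:
        raise ValueError("n_ext must be >= 1")
    import warnings

    if samples < 1_000:
        warnings.warn("fewer than 1000 samples makes the tabulation coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    k = min(n_ext, rank_cap)
    q = np.arange(1, k + 1)
    e = rng.exponential(size=(samples, k)) / (n_ext - q + 1)[None, :]
    u = 1.0 - np.exp(-np.cumsum(e, axis=1))
    om = betainc(q[None, :], n_ext - q[None, :] + 1, u)
    cs = np.sort(om.min(axis=1))
    return NullTable(n_ext=n_ext, samples=samples, seed=seed, cs=cs)


def effective_pool(n_ext: int) -> int:
    """Bucketed pool size: exact up to POOL_EXACT_MAX, geometric above.

    The grid point never exceeds n_ext, so a pool can always be reduced to
    its bucket by uniform subsampling — which keeps the scores an iid uniform
    sample under the null, hence the calibration exact.
    """
    if n_ext <= POOL_EXACT_MAX:
        return max(1, n_ext)
    step = np.floor(np.log(n_ext / POOL_EXACT_MAX) / np.log(POOL_GRID_RATIO))
    return min(n_ext, int(np.floor(POOL_EXACT_MAX * POOL_GRID_RATIO ** step)))


# tables depend only on (samples, rank_cap, pool size), not on the graph or
# the run, so they are shared process-wide across searchers, hierarchy levels
# and repeated runs, and regenerate bit-identically in any process
_TABLE_STORE: dict[tuple, NullTable] = {}
_TABLE_SEED_BASE = 1_259  # fixed: tables are numerical devices, like a grid


class NullTableCache:
    """Cache of null tables, deterministic and shared across runs.

    The table seed is derived from the (bucketed) pool size alone, so the
    tabulation acts as a persistent constant: every run, in any process,
    sees the same table for the same pool size.
    """

    def __init__(self, seed: int | None = None, samples: int = 10_000,
                 rank_cap: int = RANK_CAP, bucket: bool = True):
        self.seed = _TABLE_SEED_BASE if seed is None else int(seed) % (2**31)
        self.samples = samples
        self.rank_cap = rank_cap
        self.bucket = bucket

    def pool_size(self, n_ext: int) -> int:
        return effective_pool(n_ext) if self.bucket else max(1, n_ext)

    def get(self, n_ext: int) -> NullTable:
        n_eff = self.pool_size(n_ext)
        key = (self.seed, self.samples, self.rank_cap, n_eff)
        t = _TABLE_STORE.get(key)
        if t is None:
            t = tabulate_null(n_eff, samples=self.samples,
                              seed=(self.seed * 1_000_003 + n_eff) % (2**31),
                              rank_cap=self.rank_cap)
            _TABLE_STORE[key] = t
        return t


def cluster_score(members: set[int], graph: Graph, scorer: VertexScorer,
                  tables: NullTableCache) -> tuple[float, float]:
    """Score a cluster: raw minimum statistic c and its null probability Phi(c).

    All external vertices are scored (non-neighbors enter with internal degree
    zero); a cluster with no external vertices is maximally compatible with
    the null and scores (1, 1).
    """
    if not members:
        raise ValueError("cluster must be non-empty")
    n_ext = graph.n - len(members)
    if n_ext == 0:
        return 1.0, 1.0
    table = tables.get(n_ext)
    n_eff = table.n_ext
    cands, rs = scorer.score_externals(members)
    if n_eff < len(cands):
        keep = scorer.rng.choice(len(cands), size=n_eff, replace=False)
        rs = rs[keep]
    rs.sort()
    c, _ = min_order_statistic(rs, n=n_eff, rank_cap=tables.rank_cap)
    return c, table.phi(c)
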