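"""Single-cluster analysis: significance-driven addition, pruning, trials.

A candidate cluster is "cleaned" in two phases.  The *add* phase scores every
external vertex, ranks the scores, and admits the largest prefix of ranks
whose order-statistic evidence would itself be significant at tolerance P
against the Monte-Carlo null of the minimum statistic — calibrating the
whole-group inclusion against the same null keeps the familywise false
acceptance rate at P.  The *prune* phase repeatedly removes the internally
least-supported member (highest score with respect to the rest of the
cluster) until the worst member is re-admitted by the add criterion; it may
empty the cluster entirely.

Because the bootstrap scores are random, the two phases are repeated over
several trials.  The cluster is judged significant when more than
``verdict_threshold`` of the trials return a non-empty result, and the final
members are the vertices present in more than ``freq_threshold`` of the
non-empty outcomes (their participation frequency f).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph_io import Graph
from .order_stats import NullTableCache, RANK_CAP, cluster_score, omega_q
from .significance import VertexScorer, combine_scores as combine

__all__ = ["Config", "Cluster", "add_phase", "prune_phase", "clean_cluster"]


@dataclass
class Config:
    """Tunable constants of the whole pipeline.

    P                  : significance tolerance for cluster acceptance.
    trials             : clean-up repetitions per cluster.
    verdict_threshold  : fraction of non-empty trials required to accept.
    freq_threshold     : participation-frequency cut for final membership.
    candidate_prefilter: only external vertices with r below this cut are
                         eligible for inclusion (speed knob; scores above it
                         are never significant in practice).
    cycles             : add+prune alternations per clean-up trial.
    q_exponent         : exponent of the power-law growth-size distribution.
    runs               : sweeps combined into the final cover.
    similarity_fraction: overlap/min-size ratio above which two clusters are
                         deemed the same module.
    null_samples       : Monte-Carlo sample count per null table.
    rank_cap           : boundary ranks examined by the minimum statistic.
    bucket_pools       : bucket large external pools onto a geometric grid.
    score_all_externals: score every non-member (not just neighbors), so the
                         observed statistic matches the tabulated null exactly.
    decompose_in_sweep : split clusters into minimal ones already inside each
                         sweep (used at supernetwork levels, where grown
                         clusters often merge neighboring groups).
    max_levels         : cap on hierarchical recursion depth (None = no cap).
    seed               : base seed; all randomness flows from it.
    """

    P: float = 0.1
    trials: int = 10
    verdict_threshold: float = 0.5
    freq_threshold: float = 0.5
    candidate_prefilter: float = 0.5
    cycles: int = 3
    q_exponent: float = -2.0
    runs: int = 4
    similarity_fraction: float = 0.5
    null_samples: int = 10_000
    rank_cap: int = RANK_CAP
    bucket_pools: bool = True
    score_all_externals: bool = True
    decompose_in_sweep: bool = False
    max_levels: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.P < 1.0:
            raise ValueError("P must lie in (0, 1)")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        for name in ("verdict_threshold", "freq_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def with_tolerance(self, P: float) -> "Config":
        return replace(self, P=P)


@dataclass
class Cluster:
    """A vertex set with its score and clean-up provenance."""

    members: set[int]
    score: tuple[float, float] = (1.0, 1.0)  # (c, Phi(c))
    f: dict[int, float] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self):
        return len(self.members)

    def __bool__(self):
        return bool(self.members)


def _threshold(tables: NullTableCache, n_ext: int, P: float) -> tuple[float, int]:
    table = tables.get(n_ext)
    return table.quantile(P), table.n_ext


def _accepted_prefix(members: set[int], graph: Graph, scorer: VertexScorer,
                     tables: NullTableCache, cfg: Config) -> list[int]:
    """Vertices admitted by the add criterion, best rank first (may be [])."""
    n_ext = graph.n - len(members)
    if n_ext == 0:
        return []
    c_P, n_eff = _threshold(tables, n_ext, cfg.P)
    if cfg.score_all_externals:
        cands, rs = scorer.score_externals(members)
        if n_eff < len(cands):
            # subsample to the bucketed pool size: under the null a uniform
            # subsample of iid uniforms is again iid, keeping calibration exact
            keep = scorer.rng.choice(len(cands), size=n_eff, replace=False)
            cands = [cands[i] for i in keep]
            rs = rs[keep]
    else:
        boundary = {j for v in members for j in graph.adj[v]} - members
        if not boundary:
            return []
        cands, rs = scorer.score_externals(members, sorted(boundary))
    order = np.argsort(rs, kind="stable")
    rs_sorted = rs[order]
    k = min(len(cands), n_eff, cfg.rank_cap)
    q = np.arange(1, k + 1)
    om = omega_q(rs_sorted[:k], q, n_eff)
    passing = (om < c_P) & (rs_sorted[:k] < cfg.candidate_prefilter)
    if not passing.any():
        return []
    q_star = int(np.max(np.nonzero(passing)[0])) + 1
    # bound one pass to roughly doubling the cluster: a chance fluctuation at
    # a deep rank must not avalanche a long prefix of null vertices in
    q_star = min(q_star, 2 * len(members) + 8)
    return [cands[i] for i in order[:q_star]]


def add_phase(members: set[int], graph: Graph, scorer: VertexScorer,
              tables: NullTableCache, cfg: Config) -> set[int]:
    """One addition pass: include the best q* external vertices, or none."""
    if not members:
        return set(members)
    added = _accepted_prefix(members, graph, scorer, tables, cfg)
    return set(members) | set(added)


def _member_scores(members: set[int], graph: Graph,
                   scorer: VertexScorer) -> dict[int, float]:
    """Score of each member with respect to the rest of the cluster.

    The degree decomposition of ``members - {v}`` is derived incrementally
    from the totals of the full member set, so each member costs O(deg).
    """
    g = graph
    out: dict[int, float] = {}
    if len(members) == 1:
        return {next(iter(members)): float(scorer.rng.random())}
    weighted = g.weighted and not g.multiplicity_weights
    if g.directed:
        m_int = sum(1 for (iu, iv) in g._wmap if iu in members and iv in members)
        kin_tot = int(sum(g.k_in[j] for j in members))
        kout_tot = int(sum(g.k_out[j] for j in members))
        all_out = int(g.k_out.sum())
        all_in = int(g.k_in.sum())
        for v in members:
            rest = members - {v}
            d_out = sum(1 for j in g.successors[v] if j in rest)
            d_in = sum(1 for j in g.predecessors[v] if j in rest)
            m_rest = m_int - d_out - d_in
            kC_in_free = kin_tot - int(g.k_in[v]) - m_rest
            kC_out_free = kout_tot - int(g.k_out[v]) - m_rest
            pool_out = all_out - (kout_tot - int(g.k_out[v]))
            pool_in = all_in - (kin_tot - int(g.k_in[v]))
            chan = [scorer._r_step(d_out, pool_out, int(g.k_out[v]), kC_in_free),
                    scorer._r_step(d_in, pool_in, int(g.k_in[v]), kC_out_free)]
            if weighted:
                chan.append(scorer._weight_channel(v, rest))
            out[v] = combine(chan)
    else:
        m_stubs = g.internal_stubs(members)
        k_sum = int(sum(int(g.k[j]) for j in members))
        order = sorted(members)
        kin_a = np.array([g.degree_between(v, members) for v in order])
        a_a = np.array([int(g.k[v]) for v in order])
        m_rest = m_stubs - 2 * kin_a
        kC_out = (k_sum - a_a) - m_rest
        kG_out = g.total_stubs - m_rest - kC_out - a_a
        rs = scorer._r_bulk(kin_a, a_a + kG_out, a_a, kC_out)
        if weighted:
            rs = [combine([r, scorer._weight_channel(v, members - {v})])
                  for v, r in zip(order, rs)]
        out = dict(zip(order, (float(r) for r in rs)))
    return out


def prune_phase(members: set[int], graph: Graph, scorer: VertexScorer,
                tables: NullTableCache, cfg: Config) -> set[int]:
    """Remove worst members until the worst one is itself significant.

    The re-admission check runs at the Bonferroni-corrected level P / |C|:
    the worst member is the extreme of |C| examined vertices, and — unlike
    the external candidates of the add phase — it was *selected into* the
    cluster, so testing it at the raw level would let locally optimized
    subsets of random graphs survive pruning.
    """
    members = set(members)
    while members:
        if len(members) == 1:
            # a single vertex is never a cluster on its own
            return set()
        scores = _member_scores(members, graph, scorer)
        worst = max(sorted(scores), key=scores.__getitem__)
        if scores[worst] >= cfg.candidate_prefilter:
            # members above the prefilter cut can never be re-admitted, so
            # they are shed in one batch instead of one rescan at a time
            members = {v for v in members
                       if scores[v] < cfg.candidate_prefilter}
            continue
        reduced = members - {worst}
        keep_cfg = cfg.with_tolerance(cfg.P / len(members))
        c_P, n_eff = _threshold(tables, graph.n - len(reduced), keep_cfg.P)
        # necessary condition: Omega_q is decreasing in q, so the loosest
        # test the worst member could face is at the deepest rank examined
        q_loose = min(cfg.rank_cap, n_eff)
        if omega_q(scores[worst], q_loose, n_eff) >= c_P:
            members = reduced
            continue
        accepted = _accepted_prefix(reduced, graph, scorer, tables, keep_cfg)
        if worst in accepted:
            return members
        members = reduced
    return members


def _one_trial(members: set[int], graph: Graph, scorer: VertexScorer,
               tables: NullTableCache, cfg: Config) -> set[int]:
    """One clean-up trial: alternate add and prune until a fixed point.

    A single add pass followed by pruning is repeated (bounded by
    ``cfg.cycles``): from a fragment of a strong community the alternation
    climbs to the full community, while on random graphs the prune step
    dismantles whatever a spurious add pass let in.
    """
    cur = set(members)
    for _ in range(cfg.cycles):
        grown = add_phase(cur, graph, scorer, tables, cfg)
        pruned = prune_phase(grown, graph, scorer, tables, cfg)
        if not pruned or pruned == cur:
            return pruned
        cur = pruned
    return cur


def clean_cluster(members: set[int], graph: Graph, scorer: VertexScorer,
                  tables: NullTableCache, cfg: Config,
                  provenance: str = "") -> tuple[bool, Cluster]:
    """Full single-cluster analysis, iterated to a fixed point.

    The trial-vote procedure is repeated from its own output until the
    membership stabilizes: when the input is a fragment, borderline members
    enter the climb late and land below the frequency cut, but re-cleaning
    from the nearly complete set recovers them, so a significant cluster is a
    fixed point of its own clean-up.
    """
    ok, cluster = _clean_once(members, graph, scorer, tables, cfg, provenance)
    for _ in range(2):
        if not ok or cluster.members == set(members):
            break
        members = set(cluster.members)
        ok, cluster = _clean_once(members, graph, scorer, tables, cfg, provenance)
    return ok, cluster


def _clean_once(members: set[int], graph: Graph, scorer: VertexScorer,
                tables: NullTableCache, cfg: Config,
                provenance: str = "") -> tuple[bool, Cluster]:
    """One round of cfg.trials clean-up repetitions plus the majority vote."""
    if cfg.trials < 1:
        raise ValueError("trials must be >= 1")
    counts: dict[int, int] = {}
    nonempty = 0
    max_empty = cfg.trials - int(np.floor(cfg.verdict_threshold * cfg.trials)) - 1
    empty = 0
    streak: set[int] | None = None
    for trial in range(cfg.trials):
        out = _one_trial(members, graph, scorer, tables, cfg)
        if out:
            nonempty += 1
            for v in out:
                counts[v] = counts.get(v, 0) + 1
            if trial == nonempty - 1:  # no empties so far
                streak = out if (streak is None or streak == out) else set()
                if trial + 1 >= min(4, cfg.trials) and streak:
                    # the first trials agree exactly: the vote has converged
                    score = cluster_score(streak, graph, scorer, tables)
                    return True, Cluster(set(streak), score=score,
                                         f={v: 1.0 for v in streak},
                                         provenance=provenance)
        else:
            empty += 1
            if empty > max_empty:
                # the verdict can no longer reach the required majority
                return False, Cluster(set(), provenance=provenance)
            if trial + 1 == empty == min(3, cfg.trials):
                # an opening streak of empties: genuine clusters essentially
                # never do this, so stop burning trials on a hopeless seed
                return False, Cluster(set(), provenance=provenance)
    if nonempty == 0 or nonempty / cfg.trials <= cfg.verdict_threshold:
        return False, Cluster(set(), provenance=provenance)
    f = {v: c / nonempty for v, c in counts.items()}
    final = {v for v, fv in f.items() if fv > cfg.freq_threshold}
    if not final:
        return False, Cluster(set(), f=f, provenance=provenance)
    score = cluster_score(final, graph, scorer, tables)
    return True, Cluster(final, score=score, f=f, provenance=provenance)
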