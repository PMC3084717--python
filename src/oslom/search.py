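"""Whole-network analysis: seeded growth, sweeps, arbitration, cover assembly.

Clusters are discovered by growing small significant groups around random
seed vertices and cleaning them; a full sweep visits every vertex not yet
covered by a discovered cluster.  Several independent sweeps are combined by
a majority vote over similar clusters, after which each survivor is checked
for significant internal structure (and similar survivors for a possible
union) — submodules are preferred only when each of them is significant at
the Bonferroni-adjusted level P / l inside the induced subgraph of their
union.  Vertices covered by no retained cluster are reported as homeless;
they are never force-assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cleanup import Cluster, Config, clean_cluster
from .graph_io import Cover, Graph
from .order_stats import NullTableCache
from .significance import VertexScorer

logger = logging.getLogger(__name__)

__all__ = ["Searcher", "ModulePool", "similar", "find_cover"]


def similar(a: set, b: set, similarity_fraction: float = 0.5) -> bool:
    """Practical same-module rule: overlap exceeds half the smaller cluster."""
    if not a or not b:
        raise ValueError("clusters must be non-empty")
    return len(a & b) / min(len(a), len(b)) > similarity_fraction


@dataclass
class ModulePool:
    """Clusters discovered across sweeps, grouped by similarity."""

    groups: list[list[tuple[int, Cluster]]] = field(default_factory=list)

    def add(self, sweep: int, cluster: Cluster, frac: float) -> None:
        for grp in self.groups:
            if similar(grp[0][1].members, cluster.members, frac):
                grp.append((sweep, cluster))
                return
        self.groups.append([(sweep, cluster)])

    def retained(self, n_sweeps: int) -> list[Cluster]:
        """Clusters (one representative per group) seen in a majority of sweeps."""
        out = []
        for grp in self.groups:
            sweeps = {s for s, _ in grp}
            if n_sweeps == 1 or len(sweeps) > n_sweeps / 2:
                rep = max(grp, key=lambda sc: (len(sc[1].members), -sc[1].score[1]))[1]
                out.append(rep)
        return out


class Searcher:
    """Runs the local-optimization pipeline on one graph."""

    def __init__(self, graph: Graph, cfg: Config, rng: np.random.Generator):
        self.g = graph
        self.cfg = cfg
        self.rng = rng
        self.scorer = VertexScorer(graph, rng)
        self.tables = NullTableCache(samples=cfg.null_samples,
                                     rank_cap=cfg.rank_cap, bucket=cfg.bucket_pools)
        # growth-size distribution: P(q) ~ q^q_exponent on q_min..q_max.
        # Groups below ~5 vertices almost never survive cleaning, so the
        # support starts at 4 added vertices; it is capped at the rank cap
        # because larger groups are reached by the add phase climbing from a
        # planted core (and whole-community agglomerates by the supernetwork).
        qmax = max(1, min(graph.n - 1, cfg.rank_cap))
        qmin = min(4, max(1, graph.n // 8), qmax)
        w = np.arange(qmin, qmax + 1, dtype=float) ** cfg.q_exponent
        self._q_min = qmin
        self._q_cdf = np.cumsum(w / w.sum())

    # -- seeded growth -------------------------------------------------------
    def _draw_q(self) -> int:
        return int(np.searchsorted(self._q_cdf, self.rng.random()) + self._q_min)

    def grow_seed(self, v: int) -> Cluster:
        """Grow a group around vertex v, then clean it."""
        g = self.g
        if len(g.adj[v]) == 0:
            return Cluster(set(), provenance=f"seed:{g.ids[v]}")
        members = {v}
        q = self._draw_q()
        for _ in range(q):
            boundary = sorted({j for u in members for j in g.adj[u]} - members)
            if not boundary:
                break
            _, rs = self.scorer.score_externals(members, boundary)
            members.add(boundary[int(np.argmin(rs))])
        _, cluster = clean_cluster(members, g, self.scorer, self.tables,
                                   self.cfg, provenance=f"seed:{g.ids[v]}")
        return cluster

    # -- internal structure & arbitration -------------------------------------
    def _internal_clusters(self, members: set[int], P: float,
                           whole_budget: int = 3) -> list[set[int]]:
        """Significant clusters inside the induced subgraph (single sweep).

        Every uncovered subgraph vertex gets one seed attempt, so a genuine
        decomposition is fully enumerated.  A grown cluster that cleans up to
        the whole subgraph is evidence of *no* internal structure; a few such
        outcomes end the scan early.
        """
        if len(members) < 4:
            return []
        sub, old_of = self.g.subgraph(members)
        sub_cfg = self.cfg.with_tolerance(P)
        inner = Searcher(sub, sub_cfg, self.rng)
        clusters: list[set[int]] = []
        covered: set[int] = set()
        whole = 0
        for v in self.rng.permutation(sub.n):
            if int(v) in covered:
                continue
            c = inner.grow_seed(int(v))
            covered.add(int(v))
            if not c:
                continue
            if len(c.members) >= sub.n:
                whole += 1
                if whole >= whole_budget:
                    break
                continue
            mapped = {old_of[i] for i in c.members}
            if any(similar(mapped, prev, self.cfg.similarity_fraction)
                   for prev in clusters):
                covered |= c.members
                continue
            clusters.append(mapped)
            covered |= c.members
        return clusters

    def arbitrate(self, candidates: list[set[int]]) -> list[set[int]]:
        """Choose between l candidate submodules and their union.

        Each candidate is cleaned inside the induced subgraph of the union,
        neglecting the rest of the network; the submodules win only if every
        cleaned candidate is significant at the Bonferroni level P / l.
        """
        ell = len(candidates)
        if ell < 2:
            return candidates
        union: set[int] = set()
        for c in candidates:
            union |= c
        sub, old_of = self.g.subgraph(union)
        new_of = {o: i for i, o in enumerate(old_of)}
        sub_cfg = self.cfg.with_tolerance(self.cfg.P / ell)
        inner_scorer = VertexScorer(sub, self.rng)
        inner_tables = NullTableCache(samples=sub_cfg.null_samples,
                                      rank_cap=sub_cfg.rank_cap,
                                      bucket=sub_cfg.bucket_pools)
        cleaned: list[set[int]] = []
        for c in candidates:
            if len(c) >= len(union):
                return [union]
            ok, cl = clean_cluster({new_of[v] for v in c}, sub, inner_scorer,
                                   inner_tables, sub_cfg)
            if not ok:
                return [union]
            cleaned.append({old_of[i] for i in cl.members})
        return cleaned

    def _decompose_minimal(self, cluster: Cluster, depth: int = 0) -> list[Cluster]:
        """Split a cluster into minimal significant submodules, if any."""
        if depth >= 4 or len(cluster.members) < 4:
            return [cluster]
        chosen: list[set[int]] = []
        for _ in range(3):  # inner sweep and arbitration are stochastic
            subs = self._internal_clusters(cluster.members, self.cfg.P)
            subs = [s for s in subs if 1 < len(s) < len(cluster.members)]
            # give the unexplained remainder its own chance: partial coverage
            # would otherwise strand missing submodules as homeless vertices
            remainder = cluster.members - set().union(*subs) if subs else set()
            if len(remainder) >= 8:
                extra = self._internal_clusters(remainder, self.cfg.P)
                extra = [s for s in extra if 1 < len(s) < len(cluster.members)]
                subs.extend(extra)
                if extra:
                    remainder -= set().union(*extra)
            if subs and len(remainder) >= 2:
                # the remainder may be a single whole submodule, which the
                # inner sweep cannot report; admit it if it cleans up as
                # significant inside the cluster's own subgraph
                sub_g, old_of = self.g.subgraph(cluster.members)
                new_of = {o: i for i, o in enumerate(old_of)}
                inner = Searcher(sub_g, self.cfg, self.rng)
                ok, cl = clean_cluster({new_of[v] for v in remainder}, sub_g,
                                       inner.scorer, inner.tables, self.cfg)
                if ok and len(cl.members) < sub_g.n:
                    subs.append({old_of[i] for i in cl.members})
            if len(subs) < 2:
                continue
            chosen = self.arbitrate(subs)
            if len(chosen) >= 2:
                break
        if len(chosen) < 2:
            return [cluster]
        # the submodules were cleaned inside the induced subgraph; re-cleaning
        # them against the whole network would just climb back to the union
        from .order_stats import cluster_score

        out: list[Cluster] = []
        for s in chosen:
            sc = cluster_score(s, self.g, self.scorer, self.tables)
            sub_cluster = Cluster(set(s), score=sc,
                                  provenance=cluster.provenance + "|sub")
            out.extend(self._decompose_minimal(sub_cluster, depth + 1))
        return out if out else [cluster]

    # -- sweeps & assembly -----------------------------------------------------
    def _sweep(self, init_clusters: list[set[int]] | None,
               territory: set[int] | None = None) -> list[Cluster]:
        """One full pass of seeded growth.

        ``territory`` restricts the seeds to the given vertex set: late
        sweeps can only confirm clusters that already have a majority chance,
        so they need not re-explore vertices no discovered group touches.
        """
        g = self.g
        found: list[Cluster] = []
        covered: set[int] = set()
        if territory is not None:
            covered |= set(range(g.n)) - territory
        if init_clusters:
            for c in init_clusters:
                ok, cl = clean_cluster(c, g, self.scorer, self.tables,
                                       self.cfg, provenance="init")
                if ok and not any(similar(cl.members, p.members,
                                          self.cfg.similarity_fraction)
                                  for p in found):
                    found.append(cl)
                    covered |= cl.members
        for v in self.rng.permutation(g.n):
            v = int(v)
            if v in covered:
                continue
            c = self.grow_seed(v)
            if not c:
                covered.add(v)
                continue
            parts = ([c] if not self.cfg.decompose_in_sweep
                     else self._decompose_minimal(c))
            for part in parts:
                twin = next((i for i, p in enumerate(found)
                             if similar(part.members, p.members,
                                        self.cfg.similarity_fraction)), None)
                if twin is not None:
                    # same module found again: keep the bigger version
                    # (ties broken by the smaller score)
                    p = found[twin]
                    if (len(part.members), -part.score[1]) > (len(p.members),
                                                              -p.score[1]):
                        found[twin] = part
                    continue
                found.append(part)
            covered |= c.members | {v}
        return found

    def find_cover(self, init: Cover | None = None) -> Cover:
        g, cfg = self.g, self.cfg
        init_clusters = None
        if init is not None:
            unknown = {v for c in init.clusters for v in c} - set(g.index)
            if unknown:
                raise ValueError(f"init cover references unknown vertices: "
                                 f"{sorted(unknown)[:5]}")
            init_clusters = [{g.index[v] for v in c} for c in init.clusters]

        pool = ModulePool()
        empty_sweeps = 0
        n_sweeps = 0
        need = int(np.floor(cfg.runs / 2)) + 1  # appearances for a majority
        for s in range(cfg.runs):
            territory = None
            if cfg.runs - s < need:
                # a group first seen now can no longer reach a majority:
                # only revisit the territory of the groups already found
                territory = {v for grp in pool.groups for _, c in grp
                             for v in c.members}
                if init_clusters:
                    territory |= {v for c in init_clusters for v in c}
                if not territory:
                    break
            found = self._sweep(init_clusters, territory=territory)
            n_sweeps += 1
            logger.info("sweep %d: %d cluster(s)", s, len(found))
            if not found:
                empty_sweeps += 1
                # once a majority of sweeps is empty nothing can be retained
                if empty_sweeps > cfg.runs / 2:
                    break
                continue
            for c in found:
                pool.add(s, c, cfg.similarity_fraction)

        retained = pool.retained(n_sweeps if n_sweeps > 1 else 1)

        # minimal-cluster decomposition
        minimal: list[Cluster] = []
        for c in retained:
            minimal.extend(self._decompose_minimal(c))

        # union checks for similar pairs among survivors
        final = self._resolve_similar(minimal)

        clusters = [{g.ids[i] for i in c.members} for c in final]
        scores = [c.score[1] for c in final]
        return Cover(clusters, vertices=set(g.ids), scores=scores)

    def _resolve_similar(self, clusters: list[Cluster]) -> list[Cluster]:
        clusters = sorted(clusters, key=lambda c: (-len(c.members), c.score[1]))
        out: list[Cluster] = []
        for c in clusters:
            merged = False
            for i, p in enumerate(out):
                if c.members == p.members:
                    merged = True
                    break
                if similar(c.members, p.members, self.cfg.similarity_fraction):
                    union = c.members | p.members
                    structure = self._internal_clusters(union, self.cfg.P / 2)
                    structure = [s for s in structure if 1 < len(s) < len(union)]
                    if len(structure) < 2:
                        ok, cl = clean_cluster(union, self.g, self.scorer,
                                               self.tables, self.cfg,
                                               provenance="merge")
                        if ok:
                            out[i] = cl
                            merged = True
                            break
                    # union has structure: systematically prefer the bigger,
                    # which is p (out is sorted by size)
                    merged = True
                    break
            if not merged:
                out.append(c)
        return out


def find_cover(graph: Graph, cfg: Config | None = None,
               rng: np.random.Generator | None = None,
               init: Cover | None = None) -> Cover:
    """Detect the significant cover of a graph (functional entry point)."""
    cfg = cfg or Config()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return Searcher(graph, cfg, rng).find_cover(init=init)
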