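"""Supernetwork construction and recursive hierarchical detection.

After a cover has been found, each cluster becomes a supervertex and the
inter-cluster edges are aggregated into integer-weighted superedges, on which
the significance machinery runs again (superedge weights act as edge
multiplicities).  An original edge whose endpoints belong to ``m_i`` and
``m_j`` clusters contributes ``1 / (m_i * m_j)`` (times its weight, for
weighted graphs) to every cluster pair it straddles; intra-cluster
contributions are discarded and the aggregated weights are rounded to the
nearest integer, half away from zero, dropping superedges that round to zero.
Homeless vertices ride along as singleton supervertices so that upper levels
can still absorb them, which is why branches of the hierarchy can have
different depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cleanup import Config
from .graph_io import Cover, Graph
from .search import Searcher

logger = logging.getLogger(__name__)

__all__ = ["Hierarchy", "build_supernetwork", "detect_hierarchy"]


@dataclass
class Hierarchy:
    """Covers per level (0 = finest, over original vertex IDs) + supernetworks."""

    levels: list[Cover] = field(default_factory=list)
    supernets: list[Graph] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.levels)


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def build_supernetwork(cover: Cover, graph: Graph, *,
                       keep_homeless: bool = True,
                       keep_direction: bool = True
                       ) -> tuple[Graph, dict[str, set[str]]]:
    """Coarse-grain a graph by a cover.

    Returns the supernetwork and the map supervertex ID -> original vertices.
    Cluster supervertices are named ``m<i>``; homeless singletons keep the
    original vertex ID prefixed with ``h:``.
    """
    for c in cover.clusters:
        if not c:
            raise ValueError("cover clusters must be non-empty")
    membership: dict[str, list[str]] = {}
    expand: dict[str, set[str]] = {}
    for i, c in enumerate(cover.clusters):
        name = f"m{i}"
        expand[name] = set(c)
        for v in c:
            membership.setdefault(v, []).append(name)
    if keep_homeless:
        for v in sorted(cover.homeless):
            name = f"h:{v}"
            expand[name] = {v}
            membership[v] = [name]

    directed = graph.directed and keep_direction
    acc: dict[tuple[str, str], float] = {}
    for (iu, iv), w in graph._wmap.items():
        u, v = graph.ids[iu], graph.ids[iv]
        cu = membership.get(u, [])
        cv = membership.get(v, [])
        if not cu or not cv:
            continue
        share = (w if graph.weighted or graph.multiplicity_weights else 1.0) \
            / (len(cu) * len(cv))
        for a in cu:
            for b in cv:
                if a == b:
                    continue
                key = (a, b) if directed else (min(a, b), max(a, b))
                acc[key] = acc.get(key, 0.0) + share

    edges = []
    for (a, b), w in acc.items():
        wi = _round_half_away(w)
        if wi > 0:
            edges.append((a, b, float(wi)))
    supernet = Graph(edges, directed=directed, weighted=True,
                     vertices=sorted(expand), multiplicity_weights=True)
    return supernet, expand


def detect_hierarchy(graph: Graph, cfg: Config | None = None,
                     rng: np.random.Generator | None = None,
                     init: Cover | None = None,
                     carry_homeless: bool = False) -> Hierarchy:
    """Find covers level by level until no further grouping is significant.

    With ``carry_homeless`` the homeless vertices ride into the supernetwork
    as singleton supervertices so upper levels can absorb them; by default
    they are left out, because leftover fragments of trimmed clusters tend to
    agglomerate into spurious supernetwork clusters instead of joining their
    parent groups.
    """
    cfg = cfg or Config()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    hier = Hierarchy()
    current = graph
    expand: dict[str, set[str]] = {v: {v} for v in graph.ids}
    level_init = init
    max_levels = cfg.max_levels if cfg.max_levels is not None else graph.n

    while hier.depth < max_levels:
        level_cfg = cfg
        if hier.depth > 0:
            # supernetworks are small; more sweeps and trials buy membership
            # stability cheaply at the upper levels
            from dataclasses import replace
            level_cfg = replace(cfg, runs=max(cfg.runs, 10),
                                trials=max(cfg.trials, 20),
                                decompose_in_sweep=True)
        cover = Searcher(current, level_cfg, rng).find_cover(init=level_init)
        level_init = None
        expanded_clusters = []
        for c in cover.clusters:
            flat: set[str] = set()
            for sv in c:
                flat |= expand[sv]
            expanded_clusters.append(flat)
        expanded = Cover(expanded_clusters, vertices=set(graph.ids),
                         level=hier.depth, scores=list(cover.scores))
        if hier.levels and expanded == hier.levels[-1]:
            break
        if not cover.clusters:
            if not hier.levels:
                hier.levels.append(expanded)
            break
        hier.levels.append(expanded)
        if all(len(c) <= 1 for c in cover.clusters) or len(cover.clusters) <= 1:
            break
        supernet, sup_expand = build_supernetwork(cover, current,
                                                  keep_homeless=carry_homeless)
        hier.supernets.append(supernet)
        expand = {name: set().union(*(expand[v] for v in vs))
                  for name, vs in sup_expand.items()}
        if supernet.n <= 2 or supernet.E == 0:
            break
        logger.info("level %d: %d clusters -> supernetwork with %d vertices",
                    hier.depth - 1, len(cover.clusters), supernet.n)
        current = supernet
    return hierarchy_or_empty(hier, graph)


def hierarchy_or_empty(hier: Hierarchy, graph: Graph) -> Hierarchy:
    if not hier.levels:
        hier.levels.append(Cover([], vertices=set(graph.ids)))
    return hier
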