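"""Graph data model and plain-text readers/writers.

Edge lists are whitespace-separated ``src dst [weight]`` lines with ``#``
comments.  Covers are "tp"-style files: one cluster per line (vertex IDs
separated by whitespace), optionally preceded by ``#`` metadata lines; the
homeless vertices live in a sibling ``<name>.homeless`` file.

The :class:`Graph` container keeps the bookkeeping the significance machinery
needs: per-vertex degree (in/out split when directed), strength (sum of
incident weights), total edge count, and fast neighbor sets over a dense
integer indexing of the (opaque, string) vertex IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Graph", "Cover", "read_edgelist", "write_edgelist",
           "read_cover", "write_cover", "GraphParseError"]


class GraphParseError(ValueError):
    """Raised for malformed edge-list or cover files."""


class Graph:
    """An undirected or directed graph with optional positive edge weights.

    Self-loops are dropped on construction (the configuration-model null
    counts stubs between *distinct* endpoint sets) and duplicate edges are
    collapsed by summing their weights.  Undirected edges are stored
    canonically so ``a b`` and ``b a`` collapse.

    Parameters
    ----------
    edges :
        Iterable of ``(u, v)`` or ``(u, v, w)`` tuples; IDs are opaque
        (converted to ``str``).
    directed, weighted :
        Interpretation flags.  In unweighted mode any provided weights are
        ignored and each collapsed edge gets weight 1.
    multiplicity_weights :
        When true, integer edge weights are treated as edge *multiplicities*:
        the degree of a vertex is its weighted degree.  This is how
        supernetworks built from a cover are analyzed, where superedge
        weights count the (split) original edges between clusters.
    """

    def __init__(self, edges: Iterable[Sequence], *, directed: bool = False,
                 weighted: bool = False, vertices: Iterable | None = None,
                 multiplicity_weights: bool = False):
        self.directed = bool(directed)
        self.weighted = bool(weighted)
        self.multiplicity_weights = bool(multiplicity_weights)

        collapsed: dict[tuple[str, str], float] = {}
        dup = 0
        loops = 0
        ids: dict[str, None] = {}
        if vertices is not None:
            for v in vertices:
                ids.setdefault(str(v), None)
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = 1.0
            else:
                u, v, w = e
                w = float(w)
            u, v = str(u), str(v)
            ids.setdefault(u, None)
            ids.setdefault(v, None)
            if u == v:
                loops += 1
                continue
            if w <= 0:
                raise ValueError(f"non-positive weight {w} on edge {u} {v}")
            key = (u, v) if self.directed else (min(u, v), max(u, v))
            if key in collapsed:
                dup += 1
                collapsed[key] += w if self.weighted else 0.0
            else:
                collapsed[key] = w if self.weighted else 1.0
        if loops:
            logger.info("dropped %d self-loop(s)", loops)
        if dup:
            logger.info("collapsed %d duplicate edge(s)", dup)
        self.n_duplicates = dup
        self.n_self_loops = loops

        self.ids: list[str] = list(ids)
        self.index: dict[str, int] = {u: i for i, u in enumerate(self.ids)}
        n = len(self.ids)
        self.n = n

        self._wmap: dict[tuple[int, int], float] = {}
        if self.directed:
            self.successors: list[dict[int, float]] = [dict() for _ in range(n)]
            self.predecessors: list[dict[int, float]] = [dict() for _ in range(n)]
        self.adj: list[dict[int, float]] = [dict() for _ in range(n)]
        for (u, v), w in collapsed.items():
            iu, iv = self.index[u], self.index[v]
            self._wmap[(iu, iv)] = w
            self.adj[iu][iv] = w
            self.adj[iv][iu] = w
            if self.directed:
                self.successors[iu][iv] = w
                self.predecessors[iv][iu] = w

        self.E = len(collapsed)

        def stub(w: float) -> int:
            if self.multiplicity_weights:
                return int(round(w))
            return 1

        self.k = np.zeros(n, dtype=np.int64)
        self.s = np.zeros(n, dtype=float)
        if self.directed:
            self.k_out = np.zeros(n, dtype=np.int64)
            self.k_in = np.zeros(n, dtype=np.int64)
            for (iu, iv), w in self._wmap.items():
                self.k_out[iu] += stub(w)
                self.k_in[iv] += stub(w)
                self.s[iu] += w
                self.s[iv] += w
            self.k = self.k_out + self.k_in
        for i in range(n):
            if not self.directed:
                self.k[i] = sum(stub(w) for w in self.adj[i].values())
            self.s[i] = sum(self.adj[i].values())
        self.total_stubs = int(self.k.sum()) if not self.directed else int(self.k_in.sum())

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return self.n

    def weight(self, iu: int, iv: int) -> float:
        if self.directed:
            return self._wmap.get((iu, iv), 0.0)
        return self._wmap.get((min(iu, iv), max(iu, iv)), 0.0)

    def neighbors(self, i: int) -> dict[int, float]:
        """All neighbors of i (union of in/out when directed)."""
        return self.adj[i]

    def degree_between(self, i: int, members: set[int]) -> int:
        """Stub count between vertex i and a member set (undirected view)."""
        a = self.adj[i]
        if self.multiplicity_weights:
            return int(round(sum(w for j, w in a.items() if j in members)))
        return sum(1 for j in a if j in members)

    def internal_stubs(self, members: set[int]) -> int:
        """Twice the (multiplicity-weighted) number of internal edges."""
        tot = 0
        for i in members:
            a = self.adj[i]
            if self.multiplicity_weights:
                tot += int(round(sum(w for j, w in a.items() if j in members)))
            else:
                tot += sum(1 for j in a if j in members)
        return tot

    def subgraph(self, members: set[int]) -> tuple["Graph", list[int]]:
        """Induced subgraph plus the list mapping new index -> old index."""
        keep = sorted(members)
        old_ids = [self.ids[i] for i in keep]
        edges = []
        for (iu, iv), w in self._wmap.items():
            if iu in members and iv in members:
                edges.append((self.ids[iu], self.ids[iv], w))
        sub = Graph(edges, directed=self.directed,
                    weighted=self.weighted or self.multiplicity_weights,
                    vertices=old_ids,
                    multiplicity_weights=self.multiplicity_weights)
        return sub, [self.index[u] for u in sub.ids]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.ids)
        for (iu, iv), w in self._wmap.items():
            g.add_edge(self.ids[iu], self.ids[iv], weight=w)
        return g

    @classmethod
    def from_networkx(cls, g, *, weighted: bool | None = None,
                      multiplicity_weights: bool = False) -> "Graph":
        import networkx as nx

        directed = g.is_directed()
        if weighted is None:
            weighted = any("weight" in d for *_e, d in g.edges(data=True))
        edges = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
        return cls(edges, directed=directed, weighted=weighted,
                   vertices=g.nodes(), multiplicity_weights=multiplicity_weights)


@dataclass
class Cover:
    """A set of possibly overlapping clusters plus the homeless vertices.

    Clusters are stored as sets of vertex IDs (strings).  ``homeless`` is
    always the complement of the union of the clusters within ``vertices``.
    """

    clusters: list[set[str]]
    vertices: set[str]
    level: int = 0
    scores: list[float] = field(default_factory=list)

    def __post_init__(self):
        uniq: list[set[str]] = []
        seen: set[frozenset] = set()
        kept_scores = []
        for i, c in enumerate(self.clusters):
            f = frozenset(c)
            if f and f not in seen:
                seen.add(f)
                uniq.append(set(c))
                kept_scores.append(self.scores[i] if i < len(self.scores) else float("nan"))
        self.clusters = uniq
        self.scores = kept_scores

    @property
    def homeless(self) -> set[str]:
        cov: set[str] = set()
        for c in self.clusters:
            cov |= c
        return self.vertices - cov

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.clusters:
            for v in c:
                counts[v] = counts.get(v, 0) + 1
        return counts

    def __eq__(self, other):
        if not isinstance(other, Cover):
            return NotImplemented
        return (set(map(frozenset, self.clusters)) == set(map(frozenset, other.clusters))
                and self.vertices == other.vertices)


# -- file formats ----------------------------------------------------------

def read_edgelist(path, *, directed: bool = False, weighted: bool = False) -> Graph:
    """Read a whitespace-separated ``src dst [weight]`` file."""
    path = Path(path)
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if weighted:
                if len(tokens) != 3:
                    raise GraphParseError(
                        f"{path}:{lineno}: expected 'src dst weight', got {line!r}")
                try:
                    w = float(tokens[2])
                except ValueError:
                    raise GraphParseError(
                        f"{path}:{lineno}: weight {tokens[2]!r} is not a number") from None
                if w <= 0:
                    raise GraphParseError(
                        f"{path}:{lineno}: weight must be positive, got {w}")
                edges.append((tokens[0], tokens[1], w))
            else:
                if len(tokens) not in (2, 3):
                    raise GraphParseError(
                        f"{path}:{lineno}: expected 'src dst', got {line!r}")
                edges.append((tokens[0], tokens[1]))
    return Graph(edges, directed=directed, weighted=weighted)


def write_edgelist(graph: Graph, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# src dst" + (" weight" if graph.weighted or graph.multiplicity_weights else "") + "\n")
        for (iu, iv), w in sorted(graph._wmap.items()):
            u, v = graph.ids[iu], graph.ids[iv]
            if graph.weighted or graph.multiplicity_weights:
                fh.write(f"{u}\t{v}\t{w:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def write_cover(cover: Cover, path) -> None:
    """Write one cluster per line, with a ``# module`` header line each.

    Homeless vertices go to ``<path>.homeless``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for i, c in enumerate(cover.clusters):
            score = cover.scores[i] if i < len(cover.scores) else float("nan")
            fh.write(f"# module {i} size {len(c)} score {score:g}\n")
            fh.write(" ".join(sorted(c)) + "\n")
    with open(path.with_name(path.name + ".homeless"), "w") as fh:
        for v in sorted(cover.homeless):
            fh.write(v + "\n")


def read_cover(path, vertices: Iterable[str] | None = None) -> Cover:
    """Read a cover file written by :func:`write_cover` (or any tp-style file).

    If ``vertices`` is not given, the universe is the union of cluster members
    plus any IDs found in the sibling homeless file.
    """
    path = Path(path)
    clusters: list[set[str]] = []
    scores: list[float] = []
    pending_score = float("nan")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line.split()
                if "score" in tokens:
                    try:
                        pending_score = float(tokens[tokens.index("score") + 1])
                    except (IndexError, ValueError):
                        pending_score = float("nan")
                continue
            clusters.append(set(line.split()))
            scores.append(pending_score)
            pending_score = float("nan")
    universe: set[str] = set()
    for c in clusters:
        universe |= c
    homeless_path = path.with_name(path.name + ".homeless")
    if homeless_path.exists():
        with open(homeless_path) as fh:
            universe |= {line.strip() for line in fh if line.strip()}
    if vertices is not None:
        universe = set(map(str, vertices))
    return Cover(clusters, vertices=universe, scores=scores)
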