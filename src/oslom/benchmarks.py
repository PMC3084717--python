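"""Synthetic benchmark graphs with planted community structure, plus metrics.

The planted-partition family implemented here follows the statistical
structure of the standard heterogeneous benchmarks: power-law degree and
community-size distributions, a mixing parameter ``mu`` giving the fraction
of each vertex's neighbors outside its own community, a two-level
hierarchical variant (``mu1`` across macro-communities, ``mu2`` across
micro-communities within a macro), an overlapping variant where vertices
belong to several communities with their internal stubs split equally, and a
noise variant that attaches community-free vertices by preferential
attachment.  The wiring is a rounded per-vertex internal/external degree
split followed by stub matching with rewiring passes to remove self-loops
and duplicate edges; leftover offending edges (a vanishing fraction) are
dropped.

Evaluation metrics: the overlap-aware normalized mutual information between
covers, the Jaccard index between vertex sets, and the L1 distance between
edge-weight matrices normalized to unit total weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import Cover, Graph

__all__ = ["BenchmarkSpec", "gen_random", "gen_planted", "gen_lpartition",
           "gen_hierarchical", "gen_noisy", "nmi_covers", "jaccard",
           "matrix_distance"]


@dataclass
class BenchmarkSpec:
    """Parameters of one planted-community benchmark realization."""

    n: int = 1000
    avg_k: float = 20.0
    max_k: int = 50
    degree_exponent: float = 2.0       # gamma, P(k) ~ k^-gamma
    community_size_exponent: float = 1.0  # beta, P(s) ~ s^-beta
    s_min: int = 10
    s_max: int = 50
    mu: float = 0.3
    mu1: float = 0.1                   # hierarchical: across macro-communities
    mu2: float = 0.2                   # hierarchical: across micro, within macro
    overlap_fraction: float = 0.0
    memberships: int = 2
    n_noise: int = 0
    noise_min_degree: int = 2
    noise_exponent: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.mu1 + self.mu2 > 1.0:
            raise ValueError("mu1 + mu2 must not exceed 1")
        if self.s_min < 2:
            raise ValueError("communities need at least 2 vertices")
        if self.s_max * max(1, self.n // max(2, self.s_min)) < self.n:
            raise ValueError("community sizes cannot tile n vertices")


# ---------------------------------------------------------------------------
# degree / size sampling

def _powerlaw_ints(rng, exponent: float, lo: int, hi: int, size: int) -> np.ndarray:
    """Sample integers in [lo, hi] with P(x) ~ x^-exponent."""
    xs = np.arange(lo, hi + 1, dtype=float)
    w = xs ** (-exponent)
    w /= w.sum()
    return rng.choice(np.arange(lo, hi + 1), size=size, p=w)


def _degrees_with_mean(rng, n: int, exponent: float, avg_k: float,
                       max_k: int) -> np.ndarray:
    """Power-law degree sequence whose minimum is tuned to hit avg_k."""
    best = None
    for lo in range(1, max_k):
        xs = np.arange(lo, max_k + 1, dtype=float)
        w = xs ** (-exponent)
        mean = (xs * w).sum() / w.sum()
        if best is None or abs(mean - avg_k) < best[1]:
            best = (lo, abs(mean - avg_k))
        if mean >= avg_k:
            break
    lo = best[0]
    return _powerlaw_ints(rng, exponent, lo, max_k, n)


# ---------------------------------------------------------------------------
# stub matching with rewiring

def _match_stubs(rng, stubs: np.ndarray, forbidden_pairs=None,
                 labels=None, max_passes: int = 60) -> list[tuple[int, int]]:
    """Pair up stubs uniformly; rewire self/duplicate (and same-label) edges.

    ``stubs`` lists one entry per stub (vertex index).  When ``labels`` is
    given, edges between vertices of the same label are also treated as
    conflicts (used to keep external stubs external).  Conflicting edges that
    survive the rewiring passes are dropped.
    """
    stubs = np.array(stubs)
    if stubs.size % 2:
        raise ValueError("odd stub count")
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)

    def conflicts(pairs, seen):
        bad = []
        for idx, (u, v) in enumerate(pairs):
            key = (min(u, v), max(u, v))
            if u == v or key in seen or (labels is not None and labels[u] == labels[v]) \
                    or (forbidden_pairs is not None and key in forbidden_pairs):
                bad.append(idx)
            else:
                seen.add(key)
        return bad

    for _ in range(max_passes):
        seen: set[tuple[int, int]] = set()
        bad = conflicts(pairs, seen)
        if not bad:
            break
        # reshuffle the stubs of all bad edges together
        pool = pairs[bad].ravel()
        rng.shuffle(pool)
        pairs[bad] = pool.reshape(-1, 2)
    # final pass: drop what could not be fixed
    out = []
    seen = set()
    for u, v in pairs:
        key = (min(u, v), max(u, v))
        if u == v or key in seen or (labels is not None and labels[u] == labels[v]) \
                or (forbidden_pairs is not None and key in forbidden_pairs):
            continue
        seen.add(key)
        out.append((int(u), int(v)))
    return out


# ---------------------------------------------------------------------------
# generators

def gen_random(kind: str, n: int, avg_k: float | None = None,
               gamma: float = 2.5, max_k: int | None = None,
               seed: int = 0) -> Graph:
    """Random graph with no community structure.

    kind='er': Erdos-Renyi G(n, p) with p = avg_k / (n - 1).
    kind='powerlaw': configuration model with a truncated power-law degree
    sequence (self-loops and multi-edges removed by rewiring).
    """
    rng = np.random.default_rng(seed)
    if kind == "er":
        if avg_k is None:
            raise ValueError("er needs avg_k")
        p = avg_k / (n - 1)
        edges = []
        if p > 0:
            iu, iv = np.triu_indices(n, k=1)
            mask = rng.random(iu.size) < p
            edges = list(zip(iu[mask], iv[mask]))
        return Graph(edges, vertices=range(n))
    if kind == "powerlaw":
        if max_k is None:
            max_k = max(3, n // 10)
        if avg_k is not None:
            deg = _degrees_with_mean(rng, n, gamma, avg_k, max_k)
        else:
            deg = _powerlaw_ints(rng, gamma, 2, max_k, n)
        if deg.sum() % 2:
            deg[int(rng.integers(n))] += 1
        stubs = np.repeat(np.arange(n), deg)
        edges = _match_stubs(rng, stubs)
        return Graph(edges, vertices=range(n))
    raise ValueError(f"unknown kind {kind!r}")


def _draw_sizes(rng, spec: BenchmarkSpec) -> list[int]:
    sizes: list[int] = []
    for _ in range(10_000):
        s = int(_powerlaw_ints(rng, spec.community_size_exponent,
                               spec.s_min, spec.s_max, 1)[0])
        total = sum(sizes)
        if total + s >= spec.n:
            last = spec.n - total
            if last < spec.s_min and sizes:
                sizes[-1] += last
            else:
                sizes.append(last)
            return sizes
        sizes.append(s)
    raise RuntimeError("failed to tile n with community sizes")


def gen_planted(spec: BenchmarkSpec) -> tuple[Graph, Cover]:
    """Heterogeneous planted-partition graph with ground-truth cover.

    Each vertex gets round((1 - mu) * k) of its degree inside its own
    community(ies) and the rest outside.  With ``overlap_fraction > 0`` the
    first ``overlap_fraction * n`` vertices belong to ``memberships``
    communities, their internal stubs split equally.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _draw_sizes(rng, spec)
    n_comm = len(sizes)

    deg = _degrees_with_mean(rng, spec.n, spec.degree_exponent,
                             spec.avg_k, spec.max_k)
    kin = np.array([int(round((1.0 - spec.mu) * k)) for k in deg])

    # capacity-aware assignment: a vertex only joins a community that can
    # host its internal degree (size - 1 >= kin), largest demands first
    comm_members: list[list[int]] = [[] for _ in range(n_comm)]
    label = np.full(spec.n, -1)
    capacity = list(sizes)
    for v in sorted(range(spec.n), key=lambda v: -kin[v]):
        fits = [c for c in range(n_comm)
                if capacity[c] > 0 and sizes[c] - 1 >= kin[v]]
        if not fits:
            fits = [c for c in range(n_comm) if capacity[c] > 0]
        c = int(fits[int(rng.integers(len(fits)))])
        comm_members[c].append(v)
        label[v] = c
        capacity[c] -= 1

    membership: list[list[int]] = [[int(label[v])] for v in range(spec.n)]
    n_overlap = int(round(spec.overlap_fraction * spec.n))
    if n_overlap and n_comm > 1:
        overlappers = rng.choice(spec.n, size=n_overlap, replace=False)
        for v in overlappers:
            extra = [c for c in range(n_comm) if c != label[v]]
            picks = rng.choice(extra, size=min(spec.memberships - 1, len(extra)),
                               replace=False)
            for c in picks:
                membership[v].append(int(c))
                comm_members[c].append(int(v))

    edges: list[tuple[int, int]] = []

    # internal wiring, community by community; internal stubs split equally
    # across the memberships of overlapping vertices
    for ci, members in enumerate(comm_members):
        stubs = []
        for v in members:
            share = kin[v] // len(membership[v])
            share = min(share, len(members) - 1)
            stubs.extend([v] * share)
        if len(stubs) % 2:
            stubs.pop()
        edges.extend(_match_stubs(rng, np.array(stubs, dtype=int)))

    # matching deficits reduce the degree rather than spill into external
    # edges, so the requested mixing is preserved
    kext = np.maximum(deg - kin, 0)
    stubs = np.repeat(np.arange(spec.n), kext)
    if stubs.size % 2:
        stubs = stubs[:-1]
    # keep external stubs external: same-community pairs are conflicts
    # (only the primary label is enforced; overlap memberships are too
    # entangled to forbid cheaply and are a small correction)
    ext_edges = _match_stubs(rng, stubs, labels=label)
    existing = {(min(u, v), max(u, v)) for u, v in edges}
    for u, v in ext_edges:
        if (min(u, v), max(u, v)) not in existing:
            edges.append((u, v))
            existing.add((min(u, v), max(u, v)))

    graph = Graph(edges, vertices=range(spec.n))
    clusters = [set(map(str, members)) for members in comm_members]
    truth = Cover(clusters, vertices=set(map(str, range(spec.n))))
    return graph, truth


def gen_lpartition(n: int, ell: int, avg_k: float, mu: float,
                   seed: int = 0) -> tuple[Graph, Cover]:
    """Classic planted l-partition: equal groups, binomial degrees.

    Intra/inter link probabilities are set so the expected degree is avg_k
    with an expected external-neighbor fraction mu.
    """
    import networkx as nx

    if n % ell:
        raise ValueError("n must be divisible by ell")
    s = n // ell
    p_in = (1.0 - mu) * avg_k / (s - 1)
    p_out = mu * avg_k / (n - s) if ell > 1 else 0.0
    if p_in > 1 or p_out > 1:
        raise ValueError("infeasible (avg_k too large for group size)")
    g = nx.planted_partition_graph(ell, s, p_in, p_out,
                                   seed=int(seed) % (2**31))
    graph = Graph(list(g.edges()), vertices=range(n))
    clusters = [set(str(v) for v in range(ci * s, (ci + 1) * s))
                for ci in range(ell)]
    return graph, Cover(clusters, vertices=set(map(str, range(n))))


def gen_hierarchical(spec: BenchmarkSpec, n_macro: int = 4,
                     micro_per_macro: int = 4) -> tuple[Graph, Cover, Cover]:
    """Two-level benchmark: equal-size macro blocks of equal micro blocks.

    Per vertex, a fraction mu1 of neighbors falls outside its
    macro-community, mu2 inside the macro but outside its micro-community,
    and the rest inside the micro-community.
    """
    if spec.mu1 + spec.mu2 >= 1.0:
        raise ValueError("need mu1 + mu2 < 1")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_micro = n_macro * micro_per_macro
    if n % n_micro:
        raise ValueError("n must be divisible by the micro-community count")
    s_micro = n // n_micro
    macro = np.arange(n) // (n // n_macro)
    micro = np.arange(n) // s_micro

    deg = _degrees_with_mean(rng, n, spec.degree_exponent, spec.avg_k, spec.max_k)
    k1 = np.round(spec.mu1 * deg).astype(int)              # across macros
    k2 = np.round(spec.mu2 * deg).astype(int)              # across micros, in macro
    k0 = np.maximum(deg - k1 - k2, 0)                      # inside micro
    k0 = np.minimum(k0, s_micro - 1)

    edges: list[tuple[int, int]] = []
    for m in range(n_micro):
        members = np.nonzero(micro == m)[0]
        stubs = np.repeat(members, k0[members])
        if stubs.size % 2:
            stubs = stubs[:-1]
        edges.extend(_match_stubs(rng, stubs))
    for M in range(n_macro):
        members = np.nonzero(macro == M)[0]
        stubs = np.repeat(members, k2[members])
        if stubs.size % 2:
            stubs = stubs[:-1]
        edges.extend(_match_stubs(rng, stubs, labels=micro))
    stubs = np.repeat(np.arange(n), k1)
    if stubs.size % 2:
        stubs = stubs[:-1]
    ext = _match_stubs(rng, stubs, labels=macro)
    existing = {(min(u, v), max(u, v)) for u, v in edges}
    for u, v in ext:
        if (min(u, v), max(u, v)) not in existing:
            edges.append((u, v))
            existing.add((min(u, v), max(u, v)))

    graph = Graph(edges, vertices=range(n))
    verts = set(map(str, range(n)))
    fine = Cover([{str(v) for v in np.nonzero(micro == m)[0]}
                  for m in range(n_micro)], vertices=verts)
    coarse = Cover([{str(v) for v in np.nonzero(macro == M)[0]}
                    for M in range(n_macro)], vertices=verts)
    return graph, fine, coarse


def gen_noisy(graph: Graph, cover: Cover, n_noise: int,
              min_degree: int = 2, exponent: float = 2.5,
              max_degree: int | None = None,
              seed: int = 0) -> tuple[Graph, Cover, set[str]]:
    """Attach community-free noise vertices by preferential attachment.

    Each new vertex draws its initial degree from a truncated power law and
    picks distinct existing targets with probability proportional to their
    current degree.  Returns the enlarged graph, the (unchanged, re-based)
    ground-truth cover, and the noise vertex IDs.
    """
    rng = np.random.default_rng(seed)
    if max_degree is None:
        max_degree = max(min_degree, int(graph.k.mean() * 2))
    edges = [(graph.ids[iu], graph.ids[iv], w) for (iu, iv), w in graph._wmap.items()]
    ids = list(graph.ids)
    deg = {u: int(k) for u, k in zip(graph.ids, graph.k)}
    noise: set[str] = set()
    for t in range(n_noise):
        name = f"noise{t}"
        noise.add(name)
        d = int(_powerlaw_ints(rng, exponent, min_degree, max_degree, 1)[0])
        d = min(d, len(ids))
        pool = np.array(ids)
        weights = np.array([deg[u] for u in ids], dtype=float)
        weights = np.maximum(weights, 1e-9)
        targets = rng.choice(pool, size=d, replace=False,
                             p=weights / weights.sum())
        for u in targets:
            edges.append((name, str(u), 1.0))
            deg[str(u)] += 1
        deg[name] = d
        ids.append(name)
    big = Graph(edges, directed=graph.directed, weighted=graph.weighted,
                vertices=ids)
    truth = Cover([set(c) for c in cover.clusters], vertices=set(ids))
    return big, truth, noise


# ---------------------------------------------------------------------------
# evaluation metrics

def _h(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = -p[mask] * np.log(p[mask])
    return out


def nmi_covers(cover_a: Cover, cover_b: Cover) -> float:
    """Overlap-aware normalized mutual information between two covers.

    Each cluster is a binary membership variable; the conditional entropy of
    a cluster given another is accepted only when the joint agreement terms
    dominate (h11 + h00 >= h01 + h10), otherwise that pairing carries no
    information.  Homeless vertices are not turned into singleton clusters.
    Returns a value in [0, 1]; 1 iff the covers are identical.
    """
    universe = cover_a.vertices | cover_b.vertices
    if not (cover_a.vertices & cover_b.vertices):
        raise ValueError("covers live on disjoint vertex sets")
    if not cover_a.clusters and not cover_b.clusters:
        return 1.0
    if not cover_a.clusters or not cover_b.clusters:
        return 0.0
    idx = {v: i for i, v in enumerate(sorted(universe))}
    n = len(idx)

    def matrix(cover):
        m = np.zeros((len(cover.clusters), n), dtype=bool)
        for k, c in enumerate(cover.clusters):
            for v in c:
                m[k, idx[v]] = True
        return m

    A = matrix(cover_a)
    B = matrix(cover_b)

    def cond_norm(X, Y):
        nx_ = X.sum(axis=1).astype(float)
        ny = Y.sum(axis=1).astype(float)
        n11 = (X.astype(np.int32) @ Y.T.astype(np.int32)).astype(float)
        n10 = nx_[:, None] - n11
        n01 = ny[None, :] - n11
        n00 = n - n11 - n10 - n01
        p11, p10, p01, p00 = n11 / n, n10 / n, n01 / n, n00 / n
        h11, h10, h01, h00 = _h(p11), _h(p10), _h(p01), _h(p00)
        px1 = nx_ / n
        py1 = ny / n
        hx = _h(px1) + _h(1 - px1)
        hy = _h(py1) + _h(1 - py1)
        hxy = h11 + h10 + h01 + h00
        cond = hxy - hy[None, :]
        valid = (h11 + h00) >= (h01 + h10)
        cond = np.where(valid, cond, np.inf)
        best = cond.min(axis=1)
        best = np.where(np.isfinite(best), best, hx)
        with np.errstate(divide="ignore", invalid="ignore"):
            # a cluster with zero membership entropy (empty or the whole
            # universe) carries no information and counts as unexplained
            ratio = np.where(hx > 0, best / np.maximum(hx, 1e-300), 1.0)
        return float(np.clip(ratio, 0.0, 1.0).mean())

    return float(np.clip(1.0 - 0.5 * (cond_norm(A, B) + cond_norm(B, A)),
                         0.0, 1.0))


def jaccard(a: set, b: set) -> float:
    """|A & B| / |A | B| (1.0 when both sets are empty)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def matrix_distance(graph_a: Graph, graph_b: Graph) -> float:
    """L1 distance between edge-weight matrices normalized to unit total.

    Both graphs are mapped onto the union of their vertex sets; the result
    lies in [0, 2], with 0 iff the normalized weight patterns coincide.
    """
    ids = sorted(set(graph_a.ids) | set(graph_b.ids))
    if not (set(graph_a.ids) & set(graph_b.ids)):
        raise ValueError("graphs live on disjoint vertex sets")
    idx = {v: i for i, v in enumerate(ids)}

    def normalized(g: Graph) -> dict[tuple[int, int], float]:
        tot = sum(g._wmap.values())
        out = {}
        for (iu, iv), w in g._wmap.items():
            u, v = idx[g.ids[iu]], idx[g.ids[iv]]
            key = (u, v) if g.directed else (min(u, v), max(u, v))
            out[key] = w / tot
        return out

    wa = normalized(graph_a)
    wb = normalized(graph_b)
    keys = set(wa) | set(wb)
    d = sum(abs(wa.get(k, 0.0) - wb.get(k, 0.0)) for k in keys)
    if not graph_a.directed and not graph_b.directed:
        return float(d)
    return float(d)
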