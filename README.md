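# oslom

Statistically significant community detection in networks, by local
optimization of an order-statistics cluster score defined against the
configuration-model null.

Most community-detection algorithms return clusters on *any* input —
including pure random graphs, where edge concentrations are nothing but
noise. This package takes the opposite stance: a group of vertices is a
community only if a random graph with the same degree sequence would almost
never produce it. It handles undirected and directed graphs, edge weights,
overlapping clusters, hierarchical levels, vertices that belong to no
cluster at all (*homeless* vertices), and refinement of a cover produced by
another method (for very large graphs, or for tracking communities across
snapshots of a dynamic network). It is aimed at anyone mining modules from
relational data — protein interaction maps, food webs, social and
information networks.

## The score

For a cluster `C` and an external vertex `i` with degree `k_i`, the null
distribution of the number of edges `k_in` between `i` and `C` — with all
degrees and the internal degree of `C` fixed, and the remaining stubs
matched uniformly at random — is hypergeometric:

    P(k_in = t) = C(k_i, t) C(kG_out, kC_out − t) / C(k_i + kG_out, kC_out)

where `kC_out` and `kG_out` count the free stubs of the cluster and of the
rest of the graph. A randomized tail transform turns each observed `k_in`
into a score `r` that is exactly Uniform(0,1) under the null; candidates
are scored sequentially so the whole boundary score vector is iid. Sorting
the `r`'s, the q-th smallest is measured by its order-statistic probability
`Ω_q(r) = I_r(q, n−q+1)`, and the cluster score

    c = min_q Ω_q(r_(q)),    Φ(c) = null CDF of c (tabulated)

drives everything: vertices are added while their collective boundary
evidence beats the `P`-quantile of the null of `c`, internally
least-supported vertices are pruned, and the stochastic procedure is
repeated and voted over. Directed graphs contribute in/out score channels,
weighted graphs a weight channel (exponential null with harmonic-mean
scale), combined through the exact CDF of a product of uniforms.

See `docs/methods.md` for the full model, parameter table, and limitations.

## Worked example

Generate a benchmark graph with 512 vertices, mean degree 18 and mixing 0.2
(every vertex has 20 % of its neighbors outside its planted community), then
detect its communities:

```
$ oslom bench planted --n 512 --avg-k 18 --max-k 40 --s-min 16 --s-max 48 \
        --mu 0.2 --seed 42 --out demo
wrote demo/graph.tsv  (N=512, E=4412)

$ oslom run demo/graph.tsv --seed 1 --out demo/out
level 0: 16 cluster(s), 0 homeless
```

The run wrote `demo/out/tp` (one cluster per line, with `# module ...`
header lines), `demo/out/tp.homeless` (empty here: every vertex was
assigned), and `demo/out/manifest.json` (config, seed, input checksum —
enough to reproduce the run bit for bit). The 16 detected clusters are
exactly the 16 planted communities:

```python
>>> from oslom import read_cover, nmi_covers
>>> truth = read_cover("demo/truth.cover")
>>> found = read_cover("demo/out/tp", vertices=truth.vertices)
>>> nmi_covers(found, truth)
1.0
```

On a random graph the same command reports `0 cluster(s)` and every vertex
homeless — the absence of community structure is a first-class result.

The same machinery is available as a library (`find_cover`,
`detect_hierarchy`, `clean_cluster`, the generators in
`oslom.benchmarks`), and `oslom run --init-cover PATH` refines an existing
cover: feed it the output of a fast partitioner on a huge graph, or the
cover of the previous snapshot of a time-stamped network.

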