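"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np


def brute_force_maximal_cliques(nodes, edges):
    """Enumerate maximal cliques by checking every vertex subset.

    Bitmask adjacency: a subset S is a clique iff every member's
    neighbourhood covers S \\ {member}; it is maximal iff no outside vertex
    is adjacent to all of S.  Feasible up to ~16 nodes.
    """
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for a, b in edges:
        adj[idx[a]] |= 1 << idx[b]
        adj[idx[b]] |= 1 << idx[a]
    maximal = []
    for s in range(1, 1 << n):
        t = s
        is_clique = True
        while t:
            v = (t & -t).bit_length() - 1
            if (adj[v] & s) != (s & ~(1 << v)):
                is_clique = False
                break
            t &= t - 1
        if not is_clique:
            continue
        extendable = any(
            not (s >> v) & 1 and (adj[v] & s) == s for v in range(n)
        )
        if not extendable:
            maximal.append(s)
    out = []
    for s in maximal:
        out.append(tuple(sorted(nodes[v] for v in range(n) if (s >> v) & 1)))
    out.sort(key=lambda c: (-len(c), c))
    return out


def transitive_closure_components(nodes, edges):
    """Connected components via Boolean-matrix transitive closure."""
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    reach = np.eye(n, dtype=bool)
    for a, b in edges:
        reach[idx[a], idx[b]] = reach[idx[b], idx[a]] = True
    for _ in range(n):
        new = reach | (reach @ reach)
        if np.array_equal(new, reach):
            break
        reach = new
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        members = [nodes[j] for j in range(n) if reach[i, j]]
        seen.update(j for j in range(n) if reach[i, j])
        comps.append(tuple(sorted(members)))
    comps.sort(key=lambda c: (-len(c), c))
    return comps


def random_graph(rng, max_nodes=12, labels=None):
    """Seeded Erdős–Rényi-style graph as (nodes, edges) with string labels."""
    n = int(rng.integers(1, max_nodes + 1))
    if labels is None:
        nodes = [f"n{i:02d}" for i in range(n)]
    else:
        nodes = list(labels)[:n]
    p = float(rng.uniform(0.0, 1.0))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j]))
    return nodes, edges
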