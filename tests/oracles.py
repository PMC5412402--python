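"""Independent brute-force oracles used to validate the pipeline.

These are deliberately separate, simple implementations: the Nei-Gojobori
enumerator builds its own mutant neighborhoods from Biopython's translation
table, the BH oracle evaluates the step-up definition literally, and the
additive-tree generator produces random trees whose exact leaf-leaf
distances any consistent distance method must recover.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


from functools import lru_cache


@lru_cache(maxsize=None)
def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_brute_force(cds_a: str, cds_b: str):
    """(pN, pS, N, S, Nd, Sd) by literal enumeration of the NG86 definitions."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3].upper(), cds_b[i : i + 3].upper()
        if set(ca + cb) - set(BASES):
            continue
        if _translate(ca) == "*" or _translate(cb) == "*":
            continue
        # sites: per codon, fraction of single-base mutants keeping the aa
        for codon in (ca, cb):
            syn = 0
            for pos in range(3):
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1 :]
                    if _translate(mut) == _translate(codon):
                        syn += 1
            S += syn / 3.0 / 2.0
            N += (3.0 - syn / 3.0) / 2.0
        # differences: average over minimal pathways avoiding stops
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        if not diffs:
            continue
        ok_paths, stop_paths = [], []
        for order in itertools.permutations(diffs):
            cur, sd, nd, hit_stop = ca, 0.0, 0.0, False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if _translate(nxt) == _translate(cur):
                    sd += 1
                else:
                    nd += 1
                if _translate(nxt) == "*":
                    hit_stop = True
                cur = nxt
            (stop_paths if hit_stop else ok_paths).append((sd, nd))
        paths = ok_paths or stop_paths
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    return pN, pS, N, S, Nd, Sd


def jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def bh_step_up(p_values):
    """Literal BH step-up: q(i) = min_{j>=i} p(j)*m/j on the sorted scale."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary tree; returns (labels, distance matrix, bipartitions).

    Built by sequential leaf attachment with positive branch lengths; the
    returned matrix holds the exact path-length distances, and the
    bipartitions are the non-trivial splits of the generating topology.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # adjacency of a tree grown by attaching leaves to random edges
    next_node = [n_taxa]
    edges: dict[tuple[int, int], float] = {}

    def _add_edge(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w

    def _split_edge(u, v):
        mid = next_node[0]
        next_node[0] += 1
        w = edges.pop((u, v))
        edges.pop((v, u))
        a = rng.uniform(0.05, 1.0) * w
        _add_edge(u, mid, a)
        _add_edge(mid, v, w - a + rng.uniform(0.05, 0.5))
        return mid

    _add_edge(0, 1, rng.uniform(0.5, 2.0))
    for leaf in range(2, n_taxa):
        u, v = list(edges)[rng.integers(len(edges))]
        mid = _split_edge(u, v)
        _add_edge(leaf, mid, rng.uniform(0.1, 2.0))

    # all-pairs path lengths by BFS over the tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]

    # bipartitions: removing each internal edge splits the leaves
    all_leaves = frozenset(labels)
    splits = set()
    for (u, v) in list(edges):
        if u < n_taxa or v < n_taxa:
            continue
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, _ in adj[x]:
                if (x, y) == (u, v):
                    continue  # do not cross the removed edge
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(labels[i] for i in seen if i < n_taxa)
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(frozenset((side, all_leaves - side)))
    return labels, d, splits
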