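"""Distance-based phylogenetics: p-distance, neighbor joining, bootstrap.

The tree path mirrors the classic MEGA-style workflow for protein
alignments: pairwise p-distances with pairwise deletion of gapped columns,
Saitou & Nei neighbor joining, and nonparametric bootstrap supports from
column resampling.  Trees are scikit-bio ``TreeNode`` objects (unrooted,
represented with a trifurcating root); bootstrap supports are stored as
internal-node names, the convention Newick shares with most tree viewers.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

GAP_CHARS = "-."


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts."""

    labels: list[str]
    d: np.ndarray
    usable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        # p-distances are proportions; generic additive matrices may exceed 1


def _encode(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    arr = np.array([list(alignment[l].upper()) for l in labels])
    return labels, arr


def p_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """Proportion of differing sites per pair, gapped columns deleted pairwise.

    For each pair of rows, columns where either sequence carries a gap
    ("-" or ".") are dropped; the distance is mismatches over the remaining
    columns.  A pair with no comparable column is an error naming the pair.
    """
    labels, arr = _encode(alignment)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    nongap = ~np.isin(arr, list(GAP_CHARS))
    n = len(labels)
    d = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = nongap[i] & nongap[i + 1 :]
        mism = (arr[i] != arr[i + 1 :]) & both
        counts = both.sum(axis=1)
        for off, cnt in enumerate(counts):
            j = i + 1 + off
            if cnt == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = mism[off].sum() / cnt
            usable[i, j] = usable[j, i] = cnt
    return DistanceMatrix(labels, d, usable)


def nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou & Nei 1987, Studier-Keppler form).

    Ties in the Q criterion are broken by the lowest (row, column) index
    after sorting labels, so the topology does not depend on input order.
    Negative branch-length estimates are clamped to zero and the clamped
    deficit logged.  The returned tree is unrooted, encoded with a
    trifurcating root (or bifurcating for 3 taxa joined last).
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = np.argsort(np.array(dm.labels))
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    deficit = 0.0

    def _clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically first (i, j) among minima: stable tie-break
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = _clamp(li)
        nodes[j].length = _clamp(lj)
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    root = TreeNode()
    if len(nodes) == 3:
        l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for node, length in zip(nodes, (l0, l1, l2)):
            node.length = _clamp(length)
        root.extend(nodes)
    else:  # exactly 2 remaining cannot occur: loop stops at 3
        raise AssertionError("unreachable")
    if deficit > 0:
        logger.info("clamped negative branch lengths; total deficit %.6g", deficit)
    return root


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions as canonical two-sided frozensets."""
    all_leaves = frozenset(t.name for t in tree.tips())
    result: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue  # trivial split
        result[frozenset((side, all_leaves - side))] = node
    return result


def bootstrap(
    alignment: dict[str, str],
    n_replicates: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[TreeNode, int]:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate is run through the same p-distance + NJ path, and the support
    of an internal edge is the percentage of usable replicates containing
    the same bipartition, written onto the internal node's name as an
    integer.  Replicates in which some pair has no comparable column are
    dropped and counted.  Returns ``(tree, n_dropped)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(rng)
    labels, arr = _encode(alignment)
    tree = nj(p_distance(alignment))
    parts = bipartitions(tree)
    counts = {bp: 0 for bp in parts}
    n_cols = arr.shape[1]
    dropped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = {l: "".join(row) for l, row in zip(labels, arr[:, cols])}
        try:
            rep_tree = nj(p_distance(rep_aln))
        except ValueError:
            dropped += 1
            continue
        rep_parts = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1
    used = n_replicates - dropped
    if dropped:
        logger.warning("%d bootstrap replicates dropped (incomparable pairs)", dropped)
    if used == 0:
        raise ValueError("all bootstrap replicates dropped")
    for bp, node in parts.items():
        node.name = str(round(100.0 * counts[bp] / used))
    return tree, dropped


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick, branch lengths rounded to 6 decimals."""
    clone = tree.copy()
    for node in clone.traverse():
        if node.length is not None:
            node.length = round(node.length, 6)
    buf = io.StringIO()
    clone.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse Newick text; internal-node labels are bootstrap supports."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"malformed newick: {exc}") from exc
    n_tips = sum(1 for _ in tree.tips())
    if n_tips < 2:
        raise ValueError("tree must have at least 2 leaves")
    return tree
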