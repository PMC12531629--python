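"""Distance-based neighbor-joining trees and rooting.

Distances come from pairwise column comparisons of the alignment (simple
p-distance or the 20-state Poisson correction).  The NJ implementation is
canonical Saitou–Nei: Q-matrix minimisation with the standard branch-length
formulas, deterministic tie-breaking, and negative branch lengths clamped to
zero with the deficit moved to the sister branch.  Rooting is by outgroup
(root on the outgroup's pendant edge at its midpoint) or by midpoint of the
longest tip-to-tip path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import GAP, Alignment
from .tree import Tree, TreeNode, midpoint_root, reroot_on_edge


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, +inf allowed for saturated pairs

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match ids")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if not np.allclose(
            np.nan_to_num(self.d, posinf=1e18), np.nan_to_num(self.d.T, posinf=1e18)
        ):
            raise PhyloError("distance matrix must be symmetric")
        finite = self.d[np.isfinite(self.d)]
        if np.any(finite < 0):
            raise PhyloError("distances must be >= 0")


def distance_matrix(alignment: Alignment, correction: str = "p") -> DistanceMatrix:
    """Pairwise distances over columns where both rows hold residues.

    ``p`` is the mismatch fraction; ``poisson20`` applies the 20-state
    Poisson correction ``-(19/20) ln(1 - 20 p / 19)``, returning +inf for
    saturated pairs (p >= 0.95).  'X' counts as a gap.  A pair with no
    comparable column is an error naming the pair.
    """
    if correction not in ("p", "poisson20"):
        raise PhyloError(f"unknown correction {correction!r}")
    ids = alignment.ids
    rows = [alignment.get(i).residues for i in ids]
    arr = np.array([list(r) for r in rows])
    valid = (arr != GAP) & (arr != "X")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise PhyloError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            if correction == "p":
                d = p
            else:
                d = math.inf if p >= 0.95 else -(19.0 / 20.0) * math.log(
                    1.0 - 20.0 * p / 19.0
                )
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids, D)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical Saitou–Nei NJ; returns an unrooted tree (trifurcating root).

    Ties in the Q criterion break by the lexicographically smallest id pair
    (cluster ids are the smallest tip id each side).  Negative branch
    lengths are clamped to zero with the deficit added to the sister, so
    the joined pair's path length is preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise PhyloError("neighbor joining requires finite distances")

    nodes: list[TreeNode] = [TreeNode(name) for name in dm.ids]
    keys: list[str] = list(dm.ids)  # smallest tip id in each cluster
    D = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        N = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best: tuple[float, str, str, int, int] | None = None
        for a in range(N):
            for b in range(a + 1, N):
                q = (N - 2) * sub[a, b] - r[a] - r[b]
                ka, kb = sorted((keys[idx[a]], keys[idx[b]]))
                cand = (q, ka, kb, a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        assert best is not None
        _, _, _, a, b = best
        i, j = idx[a], idx[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (N - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = TreeNode("")
        nodes[i].length = li
        nodes[j].length = lj
        u.add(nodes[i])
        u.add(nodes[j])
        new = len(nodes)
        nodes.append(u)
        keys.append(min(keys[i], keys[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[new, k] = D[k, new] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new]

    # terminal 3-star: three-point formulas
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    lens = [
        0.5 * (dij + dik - djk),
        0.5 * (dij + djk - dik),
        0.5 * (dik + djk - dij),
    ]
    center = TreeNode("")
    for node, ln in zip((nodes[i], nodes[j], nodes[k]), lens):
        node.length = max(ln, 0.0)
        center.add(node)
    return Tree(center, rooted=False)


def root_tree(
    tree: Tree, outgroup: str | None = None, midpoint: bool = False
) -> Tree:
    """Root by outgroup (root on its pendant edge midpoint) or by midpoint."""
    if (outgroup is None) == (not midpoint):
        raise PhyloError("specify exactly one of outgroup or midpoint")
    if outgroup is not None:
        tip_names = set(tree.tip_names())
        if outgroup not in tip_names:
            raise PhyloError(f"unknown outgroup {outgroup!r}")
        tip = tree.find(outgroup)
        return reroot_on_edge(tree, outgroup, tip.length / 2.0)
    return midpoint_root(tree)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Path-length distances between all tips of a tree."""
    names, D = tree.tip_distance_matrix()
    return DistanceMatrix(names, np.array(D))
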