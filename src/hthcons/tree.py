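"""Phylogenetic tree container with the traversals the pipeline needs.

The tree is a plain rooted node structure (an unrooted tree is represented
with a trifurcating root and ``rooted=False``).  Newick text is parsed with
dendropy and converted; writing emits Newick directly so output bytes are
deterministic.  Unnamed internal nodes are auto-named ``Node1..NodeK`` in
post-order, which is the naming that ancestral-state tables key on.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import dendropy


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


class TreeNode:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = float(length)  # branch to parent, subst/site
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.support: float | None = None  # bootstrap-style label, unused

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal/{len(self.children)}"
        return f"<TreeNode {self.name!r} {kind} len={self.length:g}>"


class Tree:
    """Rooted (or root-represented unrooted) phylogeny with named nodes."""

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._autoname_internals()
        self._check()

    # -- construction & invariants ------------------------------------

    def _autoname_internals(self) -> None:
        used = {n.name for n in self.postorder() if n.name}
        counter = itertools.count(1)
        for node in self.postorder():
            if not node.is_tip and not node.name:
                name = f"Node{next(counter)}"
                while name in used:
                    name = f"Node{next(counter)}"
                used.add(name)
                node.name = name

    def _check(self) -> None:
        names: set[str] = set()
        n_tips = 0
        for node in self.postorder():
            if node.length < 0 or node.length != node.length:
                raise TreeError(
                    f"node {node.name!r}: branch length must be finite and "
                    f">= 0, got {node.length}"
                )
            if node.name in names:
                raise TreeError(f"duplicate node name {node.name!r}")
            names.add(node.name)
            if node.is_tip:
                if not node.name:
                    raise TreeError("tips must be named")
                n_tips += 1
        if n_tips < 2:
            raise TreeError(f"tree must have >= 2 tips, got {n_tips}")

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def internals(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def find(self, name: str) -> TreeNode:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def tips_below(self, node: TreeNode) -> list[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.name)
            stack.extend(n.children)
        return out

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def depths(self) -> dict[str, float]:
        """Root-to-node path length for every node, keyed by name."""
        out: dict[str, float] = {}
        for node in self.preorder():
            parent_depth = out[node.parent.name] if node.parent else 0.0
            d = parent_depth + (node.length if node.parent else 0.0)
            out[node.name] = d
        return out

    def tip_distance_matrix(self) -> tuple[list[str], "list[list[float]]"]:
        """All pairwise tip-to-tip path lengths (small-tree utility)."""
        tips = self.tips()
        names = [t.name for t in tips]
        # ancestor chains with cumulative distances
        chains: list[dict[int, float]] = []
        for tip in tips:
            chain: dict[int, float] = {}
            node: TreeNode | None = tip
            d = 0.0
            while node is not None:
                chain[id(node)] = d
                d += node.length
                node = node.parent
            chains.append(chain)
        n = len(tips)
        D = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                # walk up from tip j until we hit tip i's chain
                node: TreeNode | None = tips[j]
                d = 0.0
                while node is not None and id(node) not in chains[i]:
                    d += node.length
                    node = node.parent
                assert node is not None
                dij = d + chains[i][id(node)]
                D[i][j] = D[j][i] = dij
        return names, D

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.name, node.length)
            c.support = node.support
            for child in node.children:
                c.add(clone(child))
            return c

        return Tree(clone(self.root), rooted=self.rooted)

    # -- Newick --------------------------------------------------------

    def newick(self, internal_names: bool = True) -> str:
        def fmt_len(x: float) -> str:
            return f"{x:.10g}"

        def emit(node: TreeNode) -> str:
            if node.is_tip:
                label = node.name
            else:
                inner = ",".join(emit(c) for c in node.children)
                label = f"({inner})" + (node.name if internal_names else "")
            if node.parent is not None:
                label += f":{fmt_len(node.length)}"
            return label

        return emit(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree tips={len(self.tips())} rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Newick parsing (dendropy-backed)
# ---------------------------------------------------------------------------


def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeError(
                    f"Newick parse error: unbalanced ')' at character {offset}"
                )
    if depth != 0:
        raise TreeError(
            "Newick parse error: unbalanced '(' "
            f"({depth} unclosed) at character {len(text)}"
        )


def parse_newick(text: str) -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Missing branch lengths default to 0.0.  Numeric labels in internal-node
    position are treated as support values (stored, unused); quoted labels
    are not supported.
    """
    text = text.strip()
    if not text:
        raise TreeError("empty Newick string")
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    def convert(dnode: dendropy.Node) -> TreeNode:
        label = ""
        support: float | None = None
        if dnode.taxon is not None:
            label = dnode.taxon.label or ""
        elif dnode.label:
            # internal-node label position: numeric => bootstrap support
            try:
                support = float(dnode.label)
            except ValueError:
                label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = TreeNode(label, length)
        node.support = support
        for dchild in dnode.child_nodes():
            node.add(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    rooted = len(root.children) == 2
    return Tree(root, rooted=rooted)


# ---------------------------------------------------------------------------
# Rerooting machinery (used by phylo.root_tree)
# ---------------------------------------------------------------------------


def reroot_on_edge(tree: Tree, child_name: str, dist_from_child: float) -> Tree:
    """Place a new root on the edge above ``child_name``.

    The edge from ``child_name`` to its parent is split ``dist_from_child``
    above the child; everything on the parent side is inverted.  A former
    root left with a single child is spliced out (branch lengths merged), so
    the total branch length is conserved.
    """
    tree = tree.copy()
    child = tree.find(child_name)
    if child.parent is None:
        raise TreeError("cannot reroot on the root node itself")
    if not 0.0 <= dist_from_child <= child.length:
        raise TreeError(
            f"split point {dist_from_child} outside edge of length "
            f"{child.length}"
        )

    new_root = TreeNode("")
    parent = child.parent
    parent.children.remove(child)
    upper = child.length - dist_from_child
    child.length = dist_from_child
    new_root.add(child)

    # invert the path parent -> old root
    prev = new_root
    carry = upper
    node: TreeNode | None = parent
    while node is not None:
        nxt = node.parent
        nxt_len = node.length
        if nxt is not None:
            nxt.children.remove(node)
        node.parent = None
        prev.add(node)
        node.length = carry
        carry = nxt_len
        prev = node
        node = nxt

    # splice out a former root left with one child
    walk = new_root
    while walk is not None:
        if walk.children and len(walk.children) == 1 and walk.parent is not None:
            only = walk.children[0]
            gp = walk.parent
            gp.children[gp.children.index(walk)] = only
            only.parent = gp
            only.length += walk.length
        walk = walk.children[-1] if walk.children else None

    new_root.name = ""
    out = Tree(new_root, rooted=True)
    return out


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    names, D = tree.tip_distance_matrix()
    n = len(names)
    best = (0.0, 0, 0)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i][j] > best[0]:
                best = (D[i][j], i, j)
    total, i, j = best
    if total == 0.0:
        # degenerate star: root on the first tip's edge at its base
        return reroot_on_edge(tree, names[0], 0.0)
    half = total / 2.0
    u = tree.find(names[i])
    v = tree.find(names[j])
    # node path u .. lca .. v
    anc_u: list[TreeNode] = []
    node: TreeNode | None = u
    while node is not None:
        anc_u.append(node)
        node = node.parent
    anc_ids = {id(a): k for k, a in enumerate(anc_u)}
    path_v: list[TreeNode] = []
    node = v
    while id(node) not in anc_ids:
        path_v.append(node)
        node = node.parent  # type: ignore[assignment]
    lca_idx = anc_ids[id(node)]
    path = anc_u[: lca_idx + 1] + list(reversed(path_v))
    # walk from u accumulating; each step is an edge between path[k], path[k+1]
    acc = 0.0
    for k in range(len(path) - 1):
        a, b = path[k], path[k + 1]
        if a.parent is b:
            edge_child, edge_len, from_child_side = a, a.length, True
        else:
            edge_child, edge_len, from_child_side = b, b.length, False
        if acc + edge_len >= half - 1e-12:
            into = half - acc  # distance into the edge from the a-end
            if from_child_side:
                dist_from_child = into
            else:
                dist_from_child = edge_len - into
            dist_from_child = min(max(dist_from_child, 0.0), edge_len)
            return reroot_on_edge(tree, edge_child.name, dist_from_child)
        acc += edge_len
    raise TreeError("midpoint not found on path (numerical inconsistency)")
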