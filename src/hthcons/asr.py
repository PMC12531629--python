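"""Likelihood computation and marginal ancestral sequence reconstruction.

Column likelihoods come from Felsenstein's pruning recursion (post-order
conditional likelihoods, gaps and 'X' as missing data).  Marginal posteriors
at internal nodes use the standard two-pass algorithm: the downward
conditional likelihood at a node is combined with the "upward" partial
likelihood carried from the rest of the tree, then normalised per column.
"""

from __future__ import annotations

import numpy as np

from .models import SubstitutionModel
from .records import AMINO_ACIDS, GAP, Alignment, SequenceRecord
from .tree import Tree

N_STATES = 20


class AsrError(ValueError):
    pass


class AncestralStates:
    """Per (internal node, column) posterior residue distributions.

    Attributes
    ----------
    node_names:
        Internal node names, tree post-order.
    n_cols:
        Number of alignment columns.
    posteriors:
        Mapping node name -> (n_cols, 20) array, rows summing to 1 except
        at gap-flagged columns (kept as a uniform placeholder).
    gap_flags:
        Mapping node name -> boolean (n_cols,) array; True where every tip
        below the node is gapped, i.e. the ancestor is read out as a gap.
    """

    def __init__(
        self,
        node_names: list[str],
        n_cols: int,
        posteriors: dict[str, np.ndarray],
        gap_flags: dict[str, np.ndarray] | None = None,
    ):
        self.node_names = list(node_names)
        self.n_cols = int(n_cols)
        self.posteriors = {}
        self.gap_flags = {}
        for name in self.node_names:
            P = np.asarray(posteriors[name], dtype=float)
            if P.shape != (self.n_cols, N_STATES):
                raise AsrError(
                    f"node {name!r}: posterior shape {P.shape}, expected "
                    f"({self.n_cols}, {N_STATES})"
                )
            s = P.sum(axis=1, keepdims=True)
            if np.any(np.abs(s - 1.0) > 1e-9):
                P = P / s
            self.posteriors[name] = P
            if gap_flags and name in gap_flags:
                g = np.asarray(gap_flags[name], dtype=bool)
            else:
                g = np.zeros(self.n_cols, dtype=bool)
            self.gap_flags[name] = g

    #: posteriors within this distance of the maximum count as tied, so the
    #: alphabetical tie-break survives serialisation round trips
    MAP_TIE_TOL = 1e-6

    def map_residue(self, node: str, col: int) -> str:
        """MAP residue at 1-based column ``col``.

        Ties — including near-ties within ``MAP_TIE_TOL`` of the maximum —
        resolve to the alphabetically first residue, keeping the call
        deterministic and stable under state-file round trips.
        """
        if node not in self.posteriors:
            raise KeyError(f"no ancestral states for node {node!r}")
        if self.gap_flags[node][col - 1]:
            return GAP
        row = self.posteriors[node][col - 1]
        return AMINO_ACIDS[int(np.argmax(row >= row.max() - self.MAP_TIE_TOL))]

    def map_sequence(self, node: str) -> str:
        return "".join(self.map_residue(node, c) for c in range(1, self.n_cols + 1))


def _tip_conditionals(alignment: Alignment, tip_names: list[str]) -> dict[str, np.ndarray]:
    """(n_cols, 20) conditional-likelihood arrays per tip; gaps/X -> all ones."""
    out: dict[str, np.ndarray] = {}
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for name in tip_names:
        row = alignment.get(name).residues
        L = np.zeros((alignment.n_cols, N_STATES))
        for c, sym in enumerate(row):
            if sym in idx:
                L[c, idx[sym]] = 1.0
            else:  # '-' or 'X': missing data
                L[c, :] = 1.0
        out[name] = L
    return out


def _check_tips(tree: Tree, alignment: Alignment) -> list[str]:
    tip_names = tree.tip_names()
    missing = sorted(set(tip_names) - set(alignment.ids))
    extra = sorted(set(alignment.ids) - set(tip_names))
    if missing or extra:
        raise AsrError(
            "tree tips and alignment ids differ; "
            f"missing from alignment: {missing}; not in tree: {extra}"
        )
    return tip_names


def _downward_pass(
    tree: Tree,
    alignment: Alignment,
    model: SubstitutionModel,
) -> tuple[dict[str, np.ndarray], dict[str, float], dict[str, np.ndarray]]:
    """Post-order conditionals, per-node log-scale totals, child contributions.

    Returns (L, logscale, G) where for node v, L[v] is the (n_cols, 20)
    conditional likelihood of data below v given the state at v (rescaled
    per column; accumulated log scale in logscale[v] summed over columns is
    folded into the root total), and G["parent->child"] is the
    branch-propagated child term P(t_c) @ L_c used again by the upward pass.
    """
    tip_names = _check_tips(tree, alignment)
    L = _tip_conditionals(alignment, tip_names)
    logscale: dict[str, np.ndarray] = {
        name: np.zeros(alignment.n_cols) for name in tip_names
    }
    G: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            continue
        prod = np.ones((alignment.n_cols, N_STATES))
        scale = np.zeros(alignment.n_cols)
        for child in node.children:
            P = model.transition(child.length)
            contrib = L[child.name] @ P.T  # [col, a] = sum_b P[a,b] L_c[col,b]
            G[f"{node.name}->{child.name}"] = contrib
            prod = prod * contrib
            scale = scale + logscale[child.name]
        # rescale per column to avoid underflow
        m = prod.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        prod = prod / safe[:, None]
        with np.errstate(divide="ignore"):
            scale = scale + np.where(m > 0, np.log(safe), -np.inf)
        L[node.name] = prod
        logscale[node.name] = scale
    return L, logscale, G


def pruning_loglik(tree: Tree, alignment: Alignment, model: SubstitutionModel) -> float:
    """Total log-likelihood of the alignment on a fixed tree.

    Gap and 'X' symbols are missing data.  An impossible configuration
    (zero likelihood, e.g. conflicting tips joined by zero-length branches)
    yields ``-inf``.
    """
    L, logscale, _ = _downward_pass(tree, alignment, model)
    root = tree.root.name
    lik = L[root] @ model.pi
    with np.errstate(divide="ignore"):
        col_ll = np.log(lik) + logscale[root]
    return float(col_ll.sum())


def marginal_asr(
    tree: Tree, alignment: Alignment, model: SubstitutionModel
) -> AncestralStates:
    """Marginal ML posterior residue distributions at every internal node."""
    L, _, G = _downward_pass(tree, alignment, model)
    n_cols = alignment.n_cols

    # upward pass: F[v][col, a] = (partial) likelihood of everything outside
    # the subtree of v given state a at v, times the root prior
    F: dict[str, np.ndarray] = {tree.root.name: np.tile(model.pi, (n_cols, 1))}
    for node in tree.preorder():
        if node.is_tip:
            continue
        Fv = F[node.name]
        for child in node.children:
            if child.is_tip:
                continue
            other = Fv.copy()
            for sib in node.children:
                if sib is child:
                    continue
                other *= G[f"{node.name}->{sib.name}"]
            P = model.transition(child.length)
            Fc = other @ P  # [col, b] = sum_a other[col, a] P[a, b]
            m = Fc.max(axis=1)
            Fc /= np.where(m > 0, m, 1.0)[:, None]
            F[child.name] = Fc

    # gap flags: every tip below the node gapped at the column
    tip_gap = {
        rec.id: np.frombuffer(rec.residues.encode(), dtype="S1") == b"-"
        for rec in alignment
    }
    gap_below: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            gap_below[node.name] = tip_gap[node.name]
        else:
            g = np.ones(n_cols, dtype=bool)
            for child in node.children:
                g &= gap_below[child.name]
            gap_below[node.name] = g

    node_names = [n.name for n in tree.postorder() if not n.is_tip]
    posteriors: dict[str, np.ndarray] = {}
    gap_flags: dict[str, np.ndarray] = {}
    for name in node_names:
        post = F[name] * L[name]
        s = post.sum(axis=1, keepdims=True)
        bad = (s <= 0) | ~np.isfinite(s)
        if np.any(bad):
            # zero-likelihood column: fall back to the stationary prior
            post = np.where(bad, model.pi[None, :], post / np.where(bad, 1.0, s))
        else:
            post = post / s
        posteriors[name] = post
        gap_flags[name] = gap_below[name]
    return AncestralStates(node_names, n_cols, posteriors, gap_flags)


def map_node_sequence(states: AncestralStates, node: str) -> SequenceRecord:
    """MAP ancestral sequence at ``node`` (gap-flagged columns emit '-')."""
    if node not in states.posteriors:
        raise AsrError(f"unknown node {node!r}")
    return SequenceRecord(id=node, residues=states.map_sequence(node))
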