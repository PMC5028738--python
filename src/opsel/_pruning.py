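"""Felsenstein pruning on indexed trees, shared by the codon and amino-acid engines.

All computations are vectorized over site patterns.  ``site_log_likelihoods``
uses per-node rescaling so long alignments on deep trees cannot underflow;
``node_marginals`` implements the standard inside-outside (up-down) pass
used for marginal ancestral-state posteriors.
"""

from __future__ import annotations

import numpy as np

from opsel.seqio import LabeledTree


class TreeIndex:
    """Array-based view of a LabeledTree for fast likelihood passes."""

    def __init__(self, tree: LabeledTree):
        self.tree = tree
        n = len(tree.nodes)
        self.n_nodes = n
        self.parent = np.array(
            [-1 if nd.parent is None else nd.parent for nd in tree.nodes], dtype=int
        )
        self.lengths = np.array([nd.length for nd in tree.nodes], dtype=float)
        self.foreground = np.array([nd.foreground for nd in tree.nodes], dtype=bool)
        self.children = [list(nd.children) for nd in tree.nodes]
        self.postorder = [nd.index for nd in tree.postorder()]
        self.preorder = self.postorder[::-1]
        self.is_leaf = np.array([not c for c in self.children], dtype=bool)
        self.leaf_order = [i for i in range(n) if self.is_leaf[i]]
        self.leaf_name = {i: tree.nodes[i].name for i in self.leaf_order}
        self.root = tree.root.index

    def leaf_rows(self, taxa: list[str]) -> dict[int, int]:
        """Map leaf node index -> alignment row index for the given taxon order."""
        row_of = {t: i for i, t in enumerate(taxa)}
        try:
            return {i: row_of[self.leaf_name[i]] for i in self.leaf_order}
        except KeyError as e:
            raise ValueError(f"taxon {e.args[0]!r} missing from alignment") from None


def _upward_partials(
    tips: np.ndarray,
    idx: TreeIndex,
    P: np.ndarray,
    leaf_rows: dict[int, int],
    rescale: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Post-order partial likelihoods.

    tips: (n_taxa, n_patterns, S); P: (n_nodes, S, S), P[v] is the transition
    matrix along the branch above node v (unused for the root).
    Returns (partials (n_nodes, n_patterns, S), log_scale (n_patterns,)).
    """
    n_pat, S = tips.shape[1], tips.shape[2]
    partial = np.empty((idx.n_nodes, n_pat, S))
    log_scale = np.zeros(n_pat)
    for v in idx.postorder:
        if idx.is_leaf[v]:
            partial[v] = tips[leaf_rows[v]]
            continue
        acc = np.ones((n_pat, S))
        for c in idx.children[v]:
            acc *= partial[c] @ P[c].T
        if rescale:
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            acc = acc / m[:, None]
            log_scale += np.log(m)
        partial[v] = acc
    return partial, log_scale


def site_log_likelihoods(
    tips: np.ndarray,
    idx: TreeIndex,
    P: np.ndarray,
    pi: np.ndarray,
    leaf_rows: dict[int, int],
) -> np.ndarray:
    """Per-pattern log-likelihood under a single substitution process."""
    partial, log_scale = _upward_partials(tips, idx, P, leaf_rows, rescale=True)
    lik = partial[idx.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + log_scale


def node_marginals(
    tips: np.ndarray,
    idx: TreeIndex,
    P: np.ndarray,
    pi: np.ndarray,
    leaf_rows: dict[int, int],
) -> dict[int, np.ndarray]:
    """Marginal posterior state distributions at every internal node.

    Returns {node index: (n_patterns, S) posterior}, each row summing to 1.
    The result is invariant to the rooting of the (reversible) process.
    """
    n_pat, S = tips.shape[1], tips.shape[2]
    partial, _ = _upward_partials(tips, idx, P, leaf_rows, rescale=True)
    # Outside pass: outside[v][s] is proportional to the likelihood of all data
    # outside v's subtree given state s at v.
    outside = np.empty((idx.n_nodes, n_pat, S))
    outside[idx.root] = pi[None, :]
    for v in idx.preorder:
        if idx.is_leaf[v] and v != idx.root:
            continue
        # contribution toward each child: outside[v] * product of other children
        below = {c: partial[c] @ P[c].T for c in idx.children[v]}
        for c in idx.children[v]:
            acc = outside[v].copy()
            for s, val in below.items():
                if s != c:
                    acc *= val
            out = acc @ P[c]
            m = out.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            outside[c] = out / m[:, None]
    posts: dict[int, np.ndarray] = {}
    for v in range(idx.n_nodes):
        if idx.is_leaf[v]:
            continue
        w = partial[v] * outside[v]
        tot = w.sum(axis=1, keepdims=True)
        posts[v] = w / np.where(tot > 0, tot, 1.0)
    return posts
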