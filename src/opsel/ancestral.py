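"""Marginal ancestral amino-acid reconstruction and substitution-event calling.

The reconstruction is the empirical-Bayes marginal one: for each internal
node and site, the posterior over the 20 amino acids is proportional to
the product of the partial likelihoods above and below the node under a
fixed empirical model (JTT or Poisson), and the state with the highest
posterior is the best reconstruction.  Substitutions are then read off
branches where best states differ, and two focal branch sets can be
compared for parallel (same ancestral and derived state) or convergent
(same derived state only) changes — the pattern that identifies shared
spectral-tuning substitutions such as S164A arising independently in owls
and falcons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from opsel._genetic_code import AA_INDEX, AMINO_ACIDS, N_AA, compatible_aa_states
from opsel._pruning import TreeIndex, node_marginals, site_log_likelihoods
from opsel.aa_models import aa_rate_matrix, aa_transition_matrices
from opsel.seqio import AminoAcidAlignment, LabeledTree, NumberingMap


def node_label(tree: LabeledTree, index: int) -> str:
    n = tree.nodes[index]
    return n.name if n.name else f"N{index}"


def compress_aa_patterns(aln: AminoAcidAlignment):
    """Unique column patterns: (tips (n_taxa, n_pat, 20), weights, inverse)."""
    cols = list(zip(*aln.sequences))
    seen: dict[tuple, int] = {}
    inverse = np.empty(len(cols), dtype=int)
    uniques: list[tuple] = []
    for h, col in enumerate(cols):
        if col not in seen:
            seen[col] = len(uniques)
            uniques.append(col)
        inverse[h] = seen[col]
    weights = np.bincount(inverse, minlength=len(uniques)).astype(float)
    cache: dict[str, np.ndarray] = {}
    tips = np.empty((len(aln.taxa), len(uniques), N_AA))
    for p, col in enumerate(uniques):
        for i, aa in enumerate(col):
            if aa not in cache:
                cache[aa] = compatible_aa_states(aa)
            tips[i, p] = cache[aa]
    return tips, weights, inverse


def estimate_aa_branch_lengths(
    alignment: AminoAcidAlignment,
    tree: LabeledTree,
    model: str = "JTT",
    *,
    optimizer_tol: float = 1e-8,
    max_iter: int = 500,
) -> LabeledTree:
    """ML branch lengths on the fixed topology under the empirical model."""
    tree.validate_against(alignment)
    Q, pi = aa_rate_matrix(model)
    idx = TreeIndex(tree)
    leaf_rows = idx.leaf_rows(alignment.taxa)
    tips, weights, _ = compress_aa_patterns(alignment)
    edges = [v for v in range(idx.n_nodes) if v != idx.root]

    def neg_lnl(x: np.ndarray) -> float:
        P = np.empty((idx.n_nodes, N_AA, N_AA))
        P[edges] = aa_transition_matrices(Q, pi, np.exp(x))
        ll = site_log_likelihoods(tips, idx, P, pi, leaf_rows)
        val = float(np.dot(ll, weights))
        return 1e10 if not np.isfinite(val) else -val

    x0 = np.log(np.maximum(idx.lengths[edges], 1e-4))
    res = minimize(
        neg_lnl, x0, method="L-BFGS-B",
        bounds=[(np.log(1e-8), np.log(20.0))] * len(edges),
        options=dict(ftol=optimizer_tol, maxiter=max_iter, eps=1e-6),
    )
    lengths = idx.lengths.copy()
    lengths[edges] = np.exp(res.x)
    return tree.with_lengths(lengths)


@dataclass
class AncestralReconstruction:
    """Marginal posteriors and best states at every internal node.

    ``posteriors[v]`` is (n_sites, 20); ``best_state[v]`` the maximum-
    posterior sequence; ``best_prob[v]`` its per-site posterior;
    ``tied[v]`` marks sites where the maximum was not unique (broken
    toward the alphabetically first state).
    """

    tree: LabeledTree
    model: str
    posteriors: dict[int, np.ndarray]
    best_state: dict[int, str]
    best_prob: dict[int, np.ndarray]
    tied: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def internal_nodes(self) -> list[int]:
        return sorted(self.posteriors)

    def to_fasta(self, path) -> None:
        """Best-state sequences of all internal nodes as FASTA."""
        with open(path, "w") as fh:
            for v in self.internal_nodes:
                fh.write(f">{node_label(self.tree, v)}\n{self.best_state[v]}\n")


def reconstruct_marginal(
    alignment: AminoAcidAlignment,
    tree: LabeledTree,
    model: str = "JTT",
    *,
    estimate_branch_lengths: bool = True,
) -> AncestralReconstruction:
    """Empirical-Bayes marginal reconstruction under JTT or Poisson.

    Branch lengths are re-estimated by ML under the same model by default
    (posteriors require calibrated lengths); pass False to use the tree's
    lengths as given.  Ties in the maximum posterior are broken toward the
    alphabetically first amino acid and flagged.
    """
    tree.validate_against(alignment)
    if estimate_branch_lengths:
        tree = estimate_aa_branch_lengths(alignment, tree, model)
    Q, pi = aa_rate_matrix(model)
    idx = TreeIndex(tree)
    leaf_rows = idx.leaf_rows(alignment.taxa)
    tips, _, inverse = compress_aa_patterns(alignment)
    edges = [v for v in range(idx.n_nodes) if v != idx.root]
    P = np.empty((idx.n_nodes, N_AA, N_AA))
    P[edges] = aa_transition_matrices(Q, pi, idx.lengths[edges])
    marg = node_marginals(tips, idx, P, pi, leaf_rows)

    posteriors: dict[int, np.ndarray] = {}
    best_state: dict[int, str] = {}
    best_prob: dict[int, np.ndarray] = {}
    tied: dict[int, np.ndarray] = {}
    for v, post_pat in marg.items():
        post = post_pat[inverse]
        posteriors[v] = post
        # argmax returns the first (alphabetically lowest) state on ties
        best_idx = post.argmax(axis=1)
        best_p = post[np.arange(post.shape[0]), best_idx]
        n_max = (np.abs(post - best_p[:, None]) < 1e-12).sum(axis=1)
        best_state[v] = "".join(AMINO_ACIDS[i] for i in best_idx)
        best_prob[v] = best_p
        tied[v] = n_max > 1
    return AncestralReconstruction(
        tree=tree, model=model, posteriors=posteriors,
        best_state=best_state, best_prob=best_prob, tied=tied,
    )


@dataclass
class SubstitutionEvent:
    """One inferred amino-acid change along a branch."""

    branch: str
    site: int  # 1-based alignment coordinate
    ancestral: str
    derived: str
    support: float
    reference_site: int | None = None

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived states must differ")

    def label(self) -> str:
        """Conventional substitution name, e.g. 'S164A' (reference numbering when mapped)."""
        site = self.reference_site if self.reference_site is not None else self.site
        return f"{self.ancestral}{site}{self.derived}"


def branch_substitutions(
    asr: AncestralReconstruction,
    alignment: AminoAcidAlignment,
    tree: LabeledTree | None = None,
    *,
    numbering: NumberingMap | None = None,
    branches: "list[str] | None" = None,
) -> list[SubstitutionEvent]:
    """Call substitutions on every branch from best-state sequences.

    An event is emitted wherever the best states on the two ends of a
    branch differ; its support is the smaller of the two node posteriors
    (observed leaf states count as certainty 1).  Gapped or ambiguous leaf
    residues yield no event.  ``branches`` restricts output to the named
    branches (labels are "parent->child").
    """
    tree = asr.tree if tree is None else tree
    row_of = {t: i for i, t in enumerate(alignment.taxa)}
    events: list[SubstitutionEvent] = []
    for node in tree.nodes:
        if node.parent is None:
            continue
        branch = f"{node_label(tree, node.parent)}->{node_label(tree, node.index)}"
        if branches is not None and branch not in branches:
            continue
        parent_seq = asr.best_state[node.parent]
        parent_p = asr.best_prob[node.parent]
        if node.children:
            child_seq = asr.best_state[node.index]
            child_p = asr.best_prob[node.index]
        else:
            child_seq = alignment.sequences[row_of[node.name]]
            child_p = np.ones(len(child_seq))
        for h, (a, d) in enumerate(zip(parent_seq, child_seq)):
            if a == d or d not in AA_INDEX or a not in AA_INDEX:
                continue
            events.append(
                SubstitutionEvent(
                    branch=branch,
                    site=h + 1,
                    ancestral=a,
                    derived=d,
                    support=float(min(parent_p[h], child_p[h])),
                    reference_site=numbering.to_reference(h + 1) if numbering else None,
                )
            )
    return events


def events_to_frame(events: list[SubstitutionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "branch": e.branch,
                "site": e.site,
                "reference_site": e.reference_site,
                "from": e.ancestral,
                "to": e.derived,
                "support": e.support,
            }
            for e in events
        ]
    )


def detect_parallel(
    events_a: list[SubstitutionEvent],
    events_b: list[SubstitutionEvent],
    *,
    use_reference_numbering: bool = False,
) -> pd.DataFrame:
    """Sites with the same derived state in two branch sets.

    A shared site is 'parallel' when the ancestral states also match and
    'convergent' otherwise.  With ``use_reference_numbering`` the
    comparison is made in reference coordinates (events must carry them).
    """

    def key(e: SubstitutionEvent) -> int:
        if use_reference_numbering:
            if e.reference_site is None:
                raise ValueError(
                    f"event at site {e.site} lacks a reference coordinate; "
                    "supply a NumberingMap when calling branch_substitutions"
                )
            return e.reference_site
        return e.site

    by_site_a: dict[int, SubstitutionEvent] = {key(e): e for e in events_a}
    rows = []
    for e_b in events_b:
        s = key(e_b)
        e_a = by_site_a.get(s)
        if e_a is None or e_a.derived != e_b.derived:
            continue
        rows.append(
            {
                "site": s,
                "derived": e_b.derived,
                "ancestral_a": e_a.ancestral,
                "ancestral_b": e_b.ancestral,
                "type": "parallel" if e_a.ancestral == e_b.ancestral else "convergent",
                "support_a": e_a.support,
                "support_b": e_b.support,
            }
        )
    return pd.DataFrame(rows, columns=[
        "site", "derived", "ancestral_a", "ancestral_b", "type", "support_a", "support_b",
    ])
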