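"""Alignment and tree I/O, plus mapping of site numbering onto bovine rhodopsin.

Alignments are read and written as FASTA (via Biopython); trees are newick
with the ``#1`` suffix convention marking foreground branches, the de facto
standard for branch/branch-site codon models.  ``map_to_reference`` projects
alignment columns onto bovine RH1 (NP_001014890) numbering so that
substitutions can be named the way the spectral-tuning literature names
them (S164A, T269A, ...).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from opsel._genetic_code import (
    AMINO_ACIDS,
    STOP_CODONS,
    compatible_aa_states,
    compatible_codon_states,
)
from opsel._reference_data import BOVINE_RH1, BOVINE_RH1_ACCESSION

#: Branch length substituted for edges a newick file leaves unspecified.
DEFAULT_BRANCH_LENGTH = 0.1

GAP_CODON = "---"


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


class TreeError(ValueError):
    """Raised for malformed trees or tree/alignment mismatches."""


@dataclass
class CodonAlignment:
    """A gapped codon alignment: the observed data at the tips of the tree.

    ``sequences[i]`` is the nucleotide string for ``taxa[i]``; its length is
    3 x ``n_sites``.  Rows may contain gap codons (``---``) and IUPAC
    ambiguity codes; internal stop codons are rejected.
    """

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in length")
        if not self.taxa:
            raise AlignmentError("empty alignment")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon name(s): {', '.join(dup)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError("ragged alignment: rows have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(f"alignment length {length} is not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for taxon, seq in zip(self.taxa, self.sequences):
            for site in range(length // 3):
                codon = seq[3 * site : 3 * site + 3]
                if codon in STOP_CODONS:
                    raise AlignmentError(
                        f"internal stop codon {codon} in taxon {taxon!r} at codon site {site + 1}"
                    )

    @property
    def n_sites(self) -> int:
        """Number of codon columns."""
        return len(self.sequences[0]) // 3

    def codon(self, taxon_index: int, site: int) -> str:
        """Codon string for a (row, 0-based codon column) pair."""
        s = self.sequences[taxon_index]
        return s[3 * site : 3 * site + 3]

    def tip_partials(self) -> np.ndarray:
        """(n_taxa, n_sites, 61) indicator partial-likelihood tensor.

        Gap and ambiguous codons contribute the union of compatible sense
        codons (partial likelihood 1 over compatible states).
        """
        out = np.empty((len(self.taxa), self.n_sites, 61))
        cache: dict[str, np.ndarray] = {}
        for i in range(len(self.taxa)):
            for h in range(self.n_sites):
                c = self.codon(i, h)
                if c not in cache:
                    cache[c] = compatible_codon_states(c)
                out[i, h] = cache[c]
        return out


@dataclass
class AminoAcidAlignment:
    """A gapped amino-acid alignment over the 20 standard residues."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in length")
        if not self.taxa:
            raise AlignmentError("empty alignment")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        if len({len(s) for s in self.sequences}) != 1:
            raise AlignmentError("ragged alignment: rows have unequal lengths")
        self.sequences = [s.upper() for s in self.sequences]
        for taxon, seq in zip(self.taxa, self.sequences):
            for k, aa in enumerate(seq):
                if aa not in AMINO_ACIDS and aa not in "-XBZ?.":
                    raise AlignmentError(f"unknown residue {aa!r} in {taxon!r} at site {k + 1}")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def tip_partials(self) -> np.ndarray:
        """(n_taxa, n_sites, 20) indicator partial-likelihood tensor."""
        out = np.empty((len(self.taxa), self.n_sites, 20))
        cache: dict[str, np.ndarray] = {}
        for i, seq in enumerate(self.sequences):
            for h, aa in enumerate(seq):
                if aa not in cache:
                    cache[aa] = compatible_aa_states(aa)
                out[i, h] = cache[aa]
        return out


def translate_codon_alignment(aln: CodonAlignment) -> AminoAcidAlignment:
    """Translate a codon alignment column-wise; gaps and ambiguity become '-'/'X'."""
    rows = []
    for seq in aln.sequences:
        aas = []
        for h in range(len(seq) // 3):
            codon = seq[3 * h : 3 * h + 3]
            if codon == GAP_CODON:
                aas.append("-")
            elif set(codon) <= set("ACGT"):
                aas.append(str(Seq(codon).translate()))
            else:
                aas.append("X")
        rows.append("".join(aas))
    return AminoAcidAlignment(list(aln.taxa), rows)


# ---------------------------------------------------------------------------
# FASTA I/O


def _read_fasta(path) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return [r.id for r in records], [str(r.seq) for r in records]


def read_codon_alignment(path) -> CodonAlignment:
    """Read and validate a codon alignment from a FASTA file."""
    taxa, seqs = _read_fasta(path)
    return CodonAlignment(taxa, seqs)


def read_aa_alignment(path) -> AminoAcidAlignment:
    """Read and validate an amino-acid alignment from a FASTA file."""
    taxa, seqs = _read_fasta(path)
    return AminoAcidAlignment(taxa, seqs)


def write_alignment(aln: CodonAlignment | AminoAcidAlignment, path) -> None:
    """Write an alignment as FASTA."""
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Labeled trees


@dataclass
class TreeNode:
    """One node of a LabeledTree; the edge above it carries length/label."""

    index: int
    name: str | None
    parent: int | None
    length: float
    foreground: bool
    children: list[int] = field(default_factory=list)


@dataclass
class LabeledTree:
    """A phylogeny with per-branch foreground marks.

    Node 0 is the (possibly trifurcating) root used to anchor likelihood
    computations; under the reversible models in this package the choice is
    immaterial.  The branch above a node marked ``#1`` in the newick source
    is foreground; every other branch is background.
    """

    nodes: list[TreeNode]

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if not n.children]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def foreground_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.foreground and n.parent is not None]

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(i: int) -> None:
            for c in self.nodes[i].children:
                rec(c)
            out.append(self.nodes[i])

        rec(0)
        return out

    def branch_partition(self, node: TreeNode) -> str:
        """'foreground' or 'background' for the branch above ``node``."""
        return "foreground" if node.foreground else "background"

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent is not None)

    def with_lengths(self, lengths: dict[int, float] | np.ndarray) -> "LabeledTree":
        """Copy of the tree with branch lengths replaced (keyed by node index)."""
        nodes = [
            TreeNode(n.index, n.name, n.parent,
                     float(lengths[n.index]) if n.parent is not None else 0.0,
                     n.foreground, list(n.children))
            for n in self.nodes
        ]
        return LabeledTree(nodes)

    def validate_against(self, aln: CodonAlignment | AminoAcidAlignment) -> None:
        tree_leaves = set(self.leaf_names)
        aln_taxa = set(aln.taxa)
        if tree_leaves != aln_taxa:
            only_tree = sorted(tree_leaves - aln_taxa)
            only_aln = sorted(aln_taxa - tree_leaves)
            raise TreeError(
                "tree/alignment taxon mismatch"
                + (f"; only in tree: {only_tree}" if only_tree else "")
                + (f"; only in alignment: {only_aln}" if only_aln else "")
            )

    def require_foreground(self) -> None:
        if not self.foreground_nodes:
            raise TreeError("no foreground branch: mark branches with the #1 suffix")

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            n = self.nodes[i]
            if n.children:
                inner = ",".join(rec(c) for c in n.children)
                label = f"({inner})"
            else:
                label = n.name or ""
            mark = "#1" if n.foreground and n.parent is not None else ""
            if n.parent is None:
                return label
            return f"{label}{mark}:{n.length:g}"

        return rec(0) + ";"


_MARK_RE = re.compile(r"\s*#\s*1$")


def _from_dendropy(dtree: dendropy.Tree) -> LabeledTree:
    nodes: list[TreeNode] = []
    index_of: dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        name = None
        marked = False
        raw = None
        if dnode.taxon is not None:
            raw = dnode.taxon.label
        elif dnode.label is not None:
            raw = dnode.label
        if raw is not None:
            raw = raw.strip()
            if _MARK_RE.search(raw):
                marked = True
                raw = _MARK_RE.sub("", raw).strip()
            name = raw or None
        parent = index_of[id(dnode.parent_node)] if dnode.parent_node is not None else None
        length = dnode.edge.length
        if parent is not None and length is None:
            length = DEFAULT_BRANCH_LENGTH
        if parent is not None and length < 0:
            raise TreeError(f"negative branch length {length} above node {name!r}")
        idx = len(nodes)
        index_of[id(dnode)] = idx
        nodes.append(TreeNode(idx, name, parent, float(length or 0.0), marked))
        if parent is not None:
            nodes[parent].children.append(idx)
    tree = LabeledTree(nodes)
    leaf_names = [n.name for n in tree.leaves]
    if any(n is None for n in leaf_names):
        raise TreeError("tree has unnamed leaves")
    if len(set(leaf_names)) != len(leaf_names):
        raise TreeError("duplicate leaf names in tree")
    return tree


def read_labeled_tree(path=None, *, data: str | None = None) -> LabeledTree:
    """Read a newick tree; branches subtending ``#1``-marked nodes are foreground.

    Missing branch lengths default to ``DEFAULT_BRANCH_LENGTH``.
    """
    if (path is None) == (data is None):
        raise ValueError("provide exactly one of path or data")
    if path is not None:
        with open(path) as fh:
            data = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:  # dendropy raises various error classes
        raise TreeError(f"unparseable newick: {e}") from e
    return _from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Reference numbering


@dataclass
class NumberingMap:
    """Monotone, injective map from query site numbering to reference numbering.

    Both coordinates are 1-based.  Query sites aligned to a gap in the
    reference are unmapped (``None``).
    """

    pairs: list[tuple[int, int]]
    query_length: int

    def __post_init__(self) -> None:
        prev_q = prev_r = 0
        for q, r in self.pairs:
            if q <= prev_q or r <= prev_r:
                raise ValueError("numbering map must be strictly increasing in both coordinates")
            prev_q, prev_r = q, r

    def to_reference(self, query_site: int) -> int | None:
        """Reference site for a 1-based query site, or None when unmapped."""
        for q, r in self.pairs:
            if q == query_site:
                return r
        return None

    def unmapped_query_sites(self) -> list[int]:
        mapped = {q for q, _ in self.pairs}
        return [q for q in range(1, self.query_length + 1) if q not in mapped]


#: Fixed pairwise-alignment parameters making reference numbering reproducible.
ALIGNER_MATRIX = "BLOSUM62"
ALIGNER_OPEN = -11.0
ALIGNER_EXTEND = -1.0


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ALIGNER_MATRIX)
    aligner.open_gap_score = ALIGNER_OPEN
    aligner.extend_gap_score = ALIGNER_EXTEND
    return aligner


def map_to_reference(query: str, reference: str = BOVINE_RH1) -> NumberingMap:
    """Map 1-based sites of ``query`` onto ``reference`` numbering.

    Uses a global pairwise protein alignment with fixed parameters
    (BLOSUM62, gap open -11, extend -1); defaults to the packaged bovine
    rhodopsin reference (NP_001014890).
    """
    query = query.replace("-", "").upper()
    reference = reference.replace("-", "").upper()
    if not query or not reference:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    alignment = aligner.align(query, reference)[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (rs, re_) in zip(*alignment.aligned):
        for k in range(qe - qs):
            pairs.append((int(qs) + k + 1, int(rs) + k + 1))
    return NumberingMap(pairs, query_length=len(query))


def bovine_rh1_reference() -> tuple[str, str]:
    """(accession, sequence) of the packaged bovine rhodopsin reference."""
    return BOVINE_RH1_ACCESSION, BOVINE_RH1
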