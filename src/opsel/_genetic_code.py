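"""Standard nuclear genetic code: sense codons, synonymy and transition classification.

The 61 sense codons are indexed alphabetically over (A, C, G, T) triplets
with the three stop codons (TAA, TAG, TGA) removed.  All codon-model
matrices in the package use this fixed state order.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {'TAA', 'TAG', 'TGA'}

CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
N_CODONS = len(CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

CODON_AA: tuple[str, ...] = tuple(standard_dna_table.forward_table[c] for c in CODONS)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter codes
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _classify() -> np.ndarray:
    """61x61 codon-pair classification.

    0: not a single-nucleotide difference (or diagonal)
    1: synonymous transversion
    2: synonymous transition
    3: nonsynonymous transversion
    4: nonsynonymous transition
    """
    kind = np.zeros((N_CODONS, N_CODONS), dtype=np.int8)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ts = is_transition(*diffs[0])
            syn = CODON_AA[i] == CODON_AA[j]
            kind[i, j] = (1 if syn else 3) + (1 if ts else 0)
    return kind


#: Pair classification matrix used to assemble codon rate matrices.
PAIR_KIND: np.ndarray = _classify()
PAIR_KIND.setflags(write=False)

# IUPAC nucleotide ambiguity codes -> compatible bases
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "-": "ACGT",
    "?": "ACGT",
}


def compatible_codon_states(codon: str) -> np.ndarray:
    """Indicator vector over the 61 sense codons compatible with ``codon``.

    A fully determined sense codon yields a one-hot vector.  Gap codons
    (``---``) and codons containing IUPAC ambiguity codes yield the union of
    compatible sense codons (all ones for a full gap), the standard
    missing-data treatment in phylogenetic likelihoods.
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    out = np.zeros(N_CODONS)
    try:
        sets = [_IUPAC[c] for c in codon]
    except KeyError as e:
        raise ValueError(f"unknown nucleotide code {e.args[0]!r} in codon {codon!r}") from None
    for a in sets[0]:
        for b in sets[1]:
            for c in sets[2]:
                idx = CODON_INDEX.get(a + b + c)
                if idx is not None:
                    out[idx] = 1.0
    if not out.any():
        raise ValueError(f"codon {codon!r} is compatible only with stop codons")
    return out


def compatible_aa_states(aa: str) -> np.ndarray:
    """Indicator vector over the 20 amino acids compatible with ``aa``."""
    aa = aa.upper()
    out = np.zeros(N_AA)
    if aa in AA_INDEX:
        out[AA_INDEX[aa]] = 1.0
    elif aa in ("-", "X", "?", "."):
        out[:] = 1.0
    elif aa == "B":  # Asn/Asp
        out[AA_INDEX["N"]] = out[AA_INDEX["D"]] = 1.0
    elif aa == "Z":  # Gln/Glu
        out[AA_INDEX["Q"]] = out[AA_INDEX["E"]] = 1.0
    else:
        raise ValueError(f"unknown amino-acid code {aa!r}")
    return out
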