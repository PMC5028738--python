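"""The codon substitution process: frequencies, rate matrix, transition probabilities.

The model is the standard reversible 61-state Markov process in which a
single-nucleotide codon change i->j has rate

    q_ij = pi_j x { 1 (synonymous transversion), kappa (synonymous transition),
                    omega (nonsynonymous transversion), kappa*omega
                    (nonsynonymous transition) },

zero for multi-nucleotide changes, with the diagonal closing each row.  The
generator is rescaled so that one unit of branch length equals one expected
codon substitution at stationarity.  omega (dN/dS) is the object of
inference throughout the package: omega > 1 indicates positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from opsel._genetic_code import CODON_INDEX, N_CODONS, PAIR_KIND
from opsel.seqio import CodonAlignment

#: Conventional boundary cap on omega; fits at the boundary are reported at it.
OMEGA_MAX = 999.0

_MIN_PI = 1e-12


@dataclass
class CodonModelParams:
    """Parameters of the single-omega codon model."""

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not (0 <= self.omega <= OMEGA_MAX):
            raise ValueError(f"omega must be in [0, {OMEGA_MAX}], got {self.omega}")
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have {N_CODONS} entries")
        if (self.pi < 0).any():
            raise ValueError("pi entries must be >= 0")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")


@dataclass
class RateMatrix:
    """A scaled codon generator with cached spectral decomposition.

    ``Q`` rows sum to zero; the scaling constant is chosen so that
    -sum_i pi_i Q_ii = 1 (one expected substitution per unit time).
    States with pi = 0 are retained with zero incoming rate, keeping the
    61x61 dimensions stable across genes.
    """

    Q: np.ndarray
    pi: np.ndarray
    scale: float
    _decomp: tuple | None = field(default=None, repr=False, compare=False)

    def _eigendecompose(self) -> tuple:
        # Symmetrize the reversible generator: B = D^{1/2} Q D^{-1/2} is
        # symmetric when pi_i q_ij = pi_j q_ji, allowing a stable eigh.
        # Falls back to scipy expm per call for near-degenerate pi.
        if self._decomp is None:
            if self.pi.min() < _MIN_PI:
                self._decomp = ("expm",)
            else:
                sq = np.sqrt(self.pi)
                B = self.Q * (sq[:, None] / sq[None, :])
                B = 0.5 * (B + B.T)
                w, U = np.linalg.eigh(B)
                # P(t) = D^{-1/2} U exp(wt) U^T D^{1/2}
                A = U / sq[:, None]  # D^{-1/2} U, shape (S, S)
                Binv = U.T * sq[None, :]  # U^T D^{1/2}
                self._decomp = ("eig", w, A, Binv)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        d = self._eigendecompose()
        if d[0] == "expm":
            P = scipy.linalg.expm(self.Q * t)
        else:
            _, w, A, Binv = d
            P = (A * np.exp(w * t)[None, :]) @ Binv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for an array of branch lengths, shape (len(ts), S, S)."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValueError("branch lengths must be >= 0")
        d = self._eigendecompose()
        if d[0] == "expm":
            P = np.stack([scipy.linalg.expm(self.Q * t) for t in ts])
        else:
            _, w, A, Binv = d
            E = np.exp(np.outer(ts, w))  # (n, S)
            P = np.einsum("ik,nk,kj->nij", A, E, Binv, optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Nucleotide frequencies are tallied separately at the three codon
    positions over all ungapped, unambiguous bases; each sense codon's
    frequency is the product over its positions, renormalized after
    excluding stops.
    """
    counts = np.zeros((3, 4))
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    any_codon = False
    for seq in alignment.sequences:
        for h in range(len(seq) // 3):
            codon = seq[3 * h : 3 * h + 3]
            if set(codon) <= set("ACGT"):
                any_codon = True
            for p, nt in enumerate(codon):
                if nt in order:
                    counts[p, order[nt]] += 1
    if not any_codon or (counts.sum(axis=1) == 0).any():
        raise ValueError("alignment has no ungapped codons to estimate frequencies from")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(N_CODONS)
    for codon, idx in CODON_INDEX.items():
        pi[idx] = freqs[0, order[codon[0]]] * freqs[1, order[codon[1]]] * freqs[2, order[codon[2]]]
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate nucleotide frequencies")
    return pi / total


def equal_frequencies() -> np.ndarray:
    """Uniform frequencies over the 61 sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


def empirical_codon_frequencies(alignment: CodonAlignment, pseudocount: float = 0.0) -> np.ndarray:
    """Observed sense-codon frequencies (F61), optionally with a pseudocount."""
    counts = np.full(N_CODONS, pseudocount, dtype=float)
    for seq in alignment.sequences:
        for h in range(len(seq) // 3):
            idx = CODON_INDEX.get(seq[3 * h : 3 * h + 3])
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("alignment has no ungapped codons")
    return counts / counts.sum()


def unscaled_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """The generator before rescaling; used internally for mixture scaling."""
    mult = np.array([0.0, 1.0, kappa, omega, kappa * omega])
    Q = mult[PAIR_KIND] * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def expected_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per unit time at stationarity: -sum_i pi_i Q_ii."""
    return float(-(pi * np.diag(Q)).sum())


def build_rate_matrix(params: CodonModelParams, scale: bool = True) -> RateMatrix:
    """Assemble the codon rate matrix for a parameter set.

    With ``scale=True`` (default) the generator is normalized so a branch of
    length t accumulates t expected substitutions per codon.
    """
    Q = unscaled_rate_matrix(params.kappa, params.omega, params.pi)
    mu = expected_rate(Q, params.pi)
    if scale:
        if mu <= 0:
            raise ValueError("degenerate rate matrix: zero expected rate")
        Q = Q / mu
    return RateMatrix(Q=Q, pi=params.pi, scale=mu)


def transition_probabilities(Q: RateMatrix, t: float) -> np.ndarray:
    """Transition probability matrix exp(Qt) for branch length t >= 0."""
    return Q.transition_matrix(t)
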