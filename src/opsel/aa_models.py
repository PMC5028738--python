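"""Empirical amino-acid substitution models for ancestral reconstruction.

Two models are provided, matching the standard choices for ancestral
amino-acid inference:

* ``JTT`` — the Jones-Taylor-Thornton (1992) empirical exchangeability
  matrix with its stationary frequencies, transcribed from the published
  matrix (the values below are the familiar integer exchangeability counts
  in the conventional A R N D C Q E G H I L K M F P S T W Y V order).
* ``Poisson`` — equal exchange rates and equal frequencies: every amino
  acid changes into any other at the same rate.

Both generators are scaled so one unit of branch length equals one
expected substitution per site at stationarity.
"""

from __future__ import annotations

import numpy as np

from opsel._genetic_code import AMINO_ACIDS, N_AA

_PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower triangle (row-major) of the JTT exchangeability matrix, PAML order.
_JTT_LOWER = [
    58,
    54, 45,
    81, 16, 528,
    56, 113, 34, 10,
    57, 310, 86, 49, 9,
    105, 29, 58, 767, 5, 323,
    179, 137, 81, 130, 59, 26, 119,
    27, 328, 391, 112, 69, 597, 26, 23,
    36, 22, 47, 11, 17, 9, 12, 6, 16,
    30, 38, 12, 7, 23, 72, 9, 6, 56, 229,
    35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14,
    54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65,
    15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43,
    194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17,
    378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285,
    475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477,
    9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12,
    11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71,
    298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16,
]

# JTT stationary frequencies, PAML order.
_JTT_FREQS = [
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
]


def _reorder(matrix: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute from PAML order into the package's alphabetical order."""
    perm = [_PAML_ORDER.index(a) for a in AMINO_ACIDS]
    return matrix[np.ix_(perm, perm)], freqs[perm]


def _jtt_raw() -> tuple[np.ndarray, np.ndarray]:
    S = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            S[i, j] = S[j, i] = _JTT_LOWER[k]
            k += 1
    freqs = np.array(_JTT_FREQS)
    freqs = freqs / freqs.sum()
    return _reorder(S, freqs)


def aa_rate_matrix(model: str) -> tuple[np.ndarray, np.ndarray]:
    """(Q, pi) for 'JTT' or 'Poisson', scaled to one expected substitution/unit time.

    States follow the package's alphabetical amino-acid order.
    """
    model_l = model.upper()
    if model_l == "JTT":
        S, pi = _jtt_raw()
    elif model_l == "POISSON":
        S = np.ones((N_AA, N_AA))
        np.fill_diagonal(S, 0.0)
        pi = np.full(N_AA, 1.0 / N_AA)
    else:
        raise ValueError(f"unknown amino-acid model {model!r} (use JTT or Poisson)")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = float(-(pi * np.diag(Q)).sum())
    return Q / mu, pi


def aa_transition_matrices(Q: np.ndarray, pi: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Batched P(t) via the symmetrized eigendecomposition (pi is strictly positive)."""
    sq = np.sqrt(pi)
    B = Q * (sq[:, None] / sq[None, :])
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    A = U / sq[:, None]
    Binv = U.T * sq[None, :]
    E = np.exp(np.outer(np.asarray(ts, dtype=float), w))
    P = np.einsum("ik,nk,kj->nij", A, E, Binv, optimize=True)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P
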