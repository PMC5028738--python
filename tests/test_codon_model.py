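"""Codon frequencies, rate-matrix construction, and transition probabilities."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from opsel._genetic_code import CODONS, CODON_INDEX, N_CODONS
from opsel.codon_model import (
    CodonModelParams,
    build_rate_matrix,
    equal_frequencies,
    f3x4_frequencies,
    transition_probabilities,
)
from opsel.seqio import CodonAlignment


def random_params(rng) -> CodonModelParams:
    pi = rng.dirichlet(np.full(N_CODONS, 5.0))
    return CodonModelParams(
        kappa=float(rng.uniform(0.5, 5)), omega=float(rng.uniform(0.05, 3)), pi=pi
    )


class TestF3x4:
    def test_uniform_nucleotides_give_uniform_codons(self):
        # one taxon per base at every position -> uniform position frequencies
        aln = CodonAlignment(
            ["t1", "t2", "t3", "t4"], ["AAA", "CCC", "GGG", "TTT"]
        )
        pi = f3x4_frequencies(aln)
        assert np.allclose(pi, 1 / 61)

    def test_single_codon_alignment_is_degenerate(self):
        aln = CodonAlignment(["t1", "t2"], ["AAAAAA", "AAAAAA"])
        pi = f3x4_frequencies(aln)
        assert pi[CODON_INDEX["AAA"]] == pytest.approx(1.0)
        assert pi.sum() == pytest.approx(1.0)

    def test_sums_to_one(self, simulated_one_ratio):
        pi = f3x4_frequencies(simulated_one_ratio.alignment)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi >= 0).all()

    def test_all_gaps_rejected(self):
        aln = CodonAlignment(["t1"], ["---"])
        with pytest.raises(ValueError, match="ungapped"):
            f3x4_frequencies(aln)


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous_rates(self):
        R = build_rate_matrix(CodonModelParams(2.0, 0.0, equal_frequencies()))
        for i, ci in enumerate(CODONS):
            for j, cj in enumerate(CODONS):
                if i != j and Seq(ci).translate() != Seq(cj).translate():
                    assert R.Q[i, j] == 0.0

    def test_neutral_symmetric_case_has_equal_single_step_rates(self):
        R = build_rate_matrix(CodonModelParams(1.0, 1.0, equal_frequencies()))
        off = R.Q[R.Q > 0]
        assert np.allclose(off, off[0])

    def test_rates_match_independent_classification(self):
        # brute-force every pair with Biopython's translation table
        kappa, omega = 2.0, 0.5
        pi = equal_frequencies()
        R = build_rate_matrix(CodonModelParams(kappa, omega, pi), scale=False)
        transitions = {frozenset("AG"), frozenset("CT")}
        for i, ci in enumerate(CODONS):
            for j, cj in enumerate(CODONS):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    expected = 0.0
                else:
                    syn = Seq(ci).translate() == Seq(cj).translate()
                    ts = frozenset(diffs[0]) in transitions
                    expected = pi[j]
                    if ts:
                        expected *= kappa
                    if not syn:
                        expected *= omega
                assert R.Q[i, j] == pytest.approx(expected)
        # AAA->AAG is Lys->Lys: a synonymous transition
        assert R.Q[CODON_INDEX["AAA"], CODON_INDEX["AAG"]] == pytest.approx(
            kappa * pi[CODON_INDEX["AAG"]]
        )

    def test_scaled_to_one_expected_substitution(self):
        rng = np.random.default_rng(0)
        R = build_rate_matrix(random_params(rng))
        assert -(R.pi * np.diag(R.Q)).sum() == pytest.approx(1.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        R = build_rate_matrix(random_params(rng))
        assert np.allclose(R.Q.sum(axis=1), 0.0, atol=1e-12)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        R = build_rate_matrix(CodonModelParams(2.0, 0.3, equal_frequencies()))
        assert np.allclose(transition_probabilities(R, 0.0), np.eye(61), atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_rows_are_stochastic(self, t):
        rng = np.random.default_rng(2)
        R = build_rate_matrix(random_params(rng))
        P = transition_probabilities(R, t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= 0).all()

    def test_long_time_reaches_stationarity(self):
        rng = np.random.default_rng(3)
        R = build_rate_matrix(random_params(rng))
        P = transition_probabilities(R, 50.0)
        assert np.abs(P - R.pi[None, :]).max() < 1e-6

    def test_negative_time_rejected(self):
        R = build_rate_matrix(CodonModelParams(2.0, 0.3, equal_frequencies()))
        with pytest.raises(ValueError):
            transition_probabilities(R, -0.1)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_time_reversibility(self, seed):
        rng = np.random.default_rng(seed)
        R = build_rate_matrix(random_params(rng))
        P = transition_probabilities(R, 0.3)
        flux = R.pi[:, None] * P
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(4)
        R = build_rate_matrix(random_params(rng))
        P1, P2, P3 = (transition_probabilities(R, t) for t in (0.2, 0.5, 0.7))
        assert np.abs(P1 @ P2 - P3).max() < 1e-8


class TestParamValidation:
    @pytest.mark.parametrize(
        "kappa,omega",
        [(0.0, 0.5), (-1.0, 0.5), (2.0, -0.1), (2.0, 1000.0)],
    )
    def test_invalid_params_rejected(self, kappa, omega):
        with pytest.raises(ValueError):
            CodonModelParams(kappa, omega, equal_frequencies())

    def test_pi_must_be_normalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CodonModelParams(2.0, 0.5, np.full(61, 0.5))
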