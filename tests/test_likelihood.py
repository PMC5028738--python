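"""Mixture likelihood vs independent oracles; ML fitting behaviour."""

import numpy as np
import pytest

from opsel._genetic_code import CODON_INDEX
from opsel.codon_model import CodonModelParams, build_rate_matrix, equal_frequencies
from opsel.likelihood import (
    ModelError,
    SiteClassMixture,
    constrain,
    fit,
    log_likelihood,
)
from opsel.seqio import CodonAlignment, read_labeled_tree

from conftest import branch_site, one_ratio


def enumeration_log_likelihood(aln, kappa, omega, pi, lengths):
    """Exhaustive sum over internal states of ((A,B)u,(C,D)v)r, oracle for pruning.

    lengths: (tA, tB, tu, tC, tD, tv)."""
    R = build_rate_matrix(CodonModelParams(kappa, omega, pi))
    PA, PB, PU, PC, PD, PV = (R.transition_matrix(t) for t in lengths)
    total = 0.0
    for h in range(aln.n_sites):
        iA, iB, iC, iD = (CODON_INDEX[aln.codon(k, h)] for k in range(4))
        # site likelihood = sum_{r,u,v} pi_r P_ru P_u->A P_u->B P_rv P_v->C P_v->D
        like = np.einsum(
            "r,ru,u,u,rv,v,v->",
            pi, PU, PA[:, iA], PB[:, iB], PV, PC[:, iC], PD[:, iD],
        )
        total += np.log(like)
    return float(total)


class TestLogLikelihood:
    def test_two_taxon_closed_form(self):
        tree = read_labeled_tree(data="(A:0.2,B:0.3);")
        aln = CodonAlignment(["A", "B"], ["ATGGCT", "ATGTCT"])
        pi = equal_frequencies()
        ll = log_likelihood(aln, tree, one_ratio(0.4), kappa=2.0, pi=pi)
        R = build_rate_matrix(CodonModelParams(2.0, 0.4, pi))
        P = R.transition_matrix(0.5)  # single path of total length 0.5
        expected = sum(
            np.log(pi[CODON_INDEX[aln.codon(0, h)]]
                   * P[CODON_INDEX[aln.codon(0, h)], CODON_INDEX[aln.codon(1, h)]])
            for h in range(2)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_four_taxon_matches_enumeration(self, quartet_tree):
        aln = CodonAlignment(
            ["A", "B", "C", "D"], ["ATGGCTAAA", "ATGTCTAAA", "ATGGCAAAG", "ATGGCTAAG"]
        )
        pi = equal_frequencies()
        ll = log_likelihood(aln, quartet_tree, one_ratio(0.4), kappa=2.0, pi=pi)
        oracle = enumeration_log_likelihood(
            aln, 2.0, 0.4, pi, (0.1, 0.15, 0.05, 0.2, 0.1, 0.08)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_zero_lengths_identical_sequences(self):
        tree = read_labeled_tree(data="(A:0.0,B:0.0,C:0.0);")
        aln = CodonAlignment(["A", "B", "C"], ["ATGGCT"] * 3)
        pi = equal_frequencies()
        ll = log_likelihood(aln, tree, one_ratio(0.5), kappa=2.0, pi=pi)
        expected = sum(np.log(pi[CODON_INDEX[aln.codon(0, h)]]) for h in range(2))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_mixture_collapse_to_one_ratio(self, small_tree, simulated_branch_site):
        aln = simulated_branch_site.alignment
        pi = equal_frequencies()
        collapsed = SiteClassMixture(
            "M2a_rel",
            [0.3, 0.3, 0.4],
            [
                # degenerate mixture: every class shares omega = 1
                {"background": 1.0, "foreground": 1.0},
                {"background": 1.0, "foreground": 1.0},
                {"background": 1.0, "foreground": 1.0},
            ],
        )
        ll_mix = log_likelihood(aln, small_tree, collapsed, kappa=2.0, pi=pi)
        ll_one = log_likelihood(aln, small_tree, one_ratio(1.0), kappa=2.0, pi=pi)
        assert ll_mix == pytest.approx(ll_one, abs=1e-8)

    def test_taxon_mismatch_rejected(self, small_tree):
        aln = CodonAlignment(["x", "y"], ["ATG", "ATG"])
        with pytest.raises(Exception, match="mismatch"):
            log_likelihood(aln, small_tree, one_ratio(0.5),
                           kappa=2.0, pi=equal_frequencies())


class TestMixtureValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ModelError, match="sum to 1"):
            SiteClassMixture("M1a", [0.5, 0.2], [
                {"background": 0.1, "foreground": 0.1},
                {"background": 1.0, "foreground": 1.0},
            ])

    def test_branch_site_ratio_constraint_enforced(self):
        with pytest.raises(ModelError, match="p2a/p2b"):
            SiteClassMixture(
                "branch-site-A",
                [0.6, 0.2, 0.05, 0.15],
                [
                    {"background": 0.1, "foreground": 0.1},
                    {"background": 1.0, "foreground": 1.0},
                    {"background": 0.1, "foreground": 3.0},
                    {"background": 1.0, "foreground": 3.0},
                ],
            )

    def test_neutral_class_must_be_one(self):
        with pytest.raises(ModelError, match="omega = 1"):
            SiteClassMixture("M1a", [0.5, 0.5], [
                {"background": 0.1, "foreground": 0.1},
                {"background": 0.9, "foreground": 0.9},
            ])


class TestConstrain:
    def test_two_ratio_constraint_drops_one_parameter(self):
        from opsel.likelihood import FAMILIES

        null = constrain("two-ratio", "omega_fg=1")
        assert null == "two-ratio-null"
        assert len(FAMILIES[null]["free"]) == len(FAMILIES["two-ratio"]["free"]) - 1

    def test_branch_site_constraint_gives_test2_null(self):
        assert constrain("branch-site-A", "omega2=1") == "branch-site-A-null"
        mix = branch_site(0.7, 0.2, 0.1, 5.0)
        null = constrain(mix, "omega2=1")
        assert null.family == "branch-site-A-null"
        assert null.class_omegas[2]["foreground"] == 1.0

    def test_constraining_fixed_parameter_rejected(self):
        with pytest.raises(ModelError, match="already fixed"):
            constrain("branch-site-A-null", "omega2=1")

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ModelError, match="unknown constraint"):
            constrain("one-ratio", "omega_fg=1")


class TestFit:
    def test_one_ratio_recovery(self, small_tree, simulated_one_ratio):
        res = fit(
            simulated_one_ratio.alignment, small_tree, "one-ratio",
            start_grid=[(2.0, 0.5)],
        )
        assert res.converged
        assert res.params["omega"] == pytest.approx(0.2, abs=0.05)

    def test_null_never_beats_alternative(self, small_tree, simulated_branch_site):
        aln = simulated_branch_site.alignment
        base = fit(aln, small_tree, "one-ratio", start_grid=[(2.0, 0.5)])
        null = fit(aln, base.tree, "branch-site-A-null", start_grid=[(2.0, 0.5)])
        alt = fit(
            aln, base.tree, "branch-site-A", start_grid=[(2.0, 0.5)],
            extra_starts=[dict(null.params, omega2=1.0 + 1e-6)],
        )
        assert alt.lnl >= null.lnl - 1e-6

    def test_multi_start_stability(self, small_tree, simulated_one_ratio):
        grid = [(1.0, 0.1), (5.0, 1.5)]
        res1 = fit(simulated_one_ratio.alignment, small_tree, "one-ratio",
                   start_grid=grid)
        res2 = fit(simulated_one_ratio.alignment, small_tree, "one-ratio",
                   start_grid=grid[::-1])
        assert res1.lnl == pytest.approx(res2.lnl, abs=1e-4)
        assert res1.n_starts == 2 and len(res1.start_lnls) == 2

    def test_fitted_branch_site_proportions_satisfy_constraint(
        self, small_tree, simulated_branch_site
    ):
        aln = simulated_branch_site.alignment
        base = fit(aln, small_tree, "one-ratio", start_grid=[(2.0, 0.5)])
        res = fit(aln, base.tree, "branch-site-A", start_grid=[(2.0, 0.5)])
        p0, p1, p2a, p2b = res.mixture.proportions
        assert p0 + p1 + p2a + p2b == pytest.approx(1.0)
        assert p2a * p1 == pytest.approx(p2b * p0, abs=1e-10)

    def test_foreground_required_for_branch_models(self):
        tree = read_labeled_tree(data="(A:0.1,B:0.1,C:0.1);")
        aln = CodonAlignment(["A", "B", "C"], ["ATGGCT"] * 3)
        with pytest.raises(Exception, match="foreground"):
            fit(aln, tree, "two-ratio")
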