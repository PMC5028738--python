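import numpy as np
import pytest

from opsel.fixtures import four_clade_tree
from opsel.likelihood import SiteClassMixture
from opsel.seqio import read_labeled_tree
from opsel.simulate import SimulationSpec, simulate_codon_alignment


def one_ratio(omega: float) -> SiteClassMixture:
    return SiteClassMixture(
        "one-ratio", [1.0], [{"background": omega, "foreground": omega}]
    )


def branch_site(p0, p1, omega0, omega2) -> SiteClassMixture:
    p2 = 1 - p0 - p1
    p2a, p2b = p2 * p0 / (p0 + p1), p2 * p1 / (p0 + p1)
    return SiteClassMixture(
        "branch-site-A",
        [p0, p1, p2a, p2b],
        [
            {"background": omega0, "foreground": omega0},
            {"background": 1.0, "foreground": 1.0},
            {"background": omega0, "foreground": omega2},
            {"background": 1.0, "foreground": omega2},
        ],
    )


@pytest.fixture(scope="session")
def small_tree():
    """8-taxon four-clade tree with the owl stem as foreground."""
    return four_clade_tree(
        {"owl": 2, "corac": 2, "falcon": 2, "accip": 2},
        branch_length=0.15, stem_length=0.4,
    )


@pytest.fixture(scope="session")
def quartet_tree():
    return read_labeled_tree(data="((A:0.1,B:0.15):0.05,(C:0.2,D:0.1):0.08);")


@pytest.fixture(scope="session")
def simulated_one_ratio(small_tree):
    """500 codons under one-ratio omega=0.2, kappa=2 (seeded)."""
    return simulate_codon_alignment(
        SimulationSpec(
            tree=small_tree, n_sites=500, seed=7, mixture=one_ratio(0.2), kappa=2.0
        )
    )


@pytest.fixture(scope="session")
def simulated_branch_site(small_tree):
    """300 codons with 10% of sites at omega2=8 on the owl stem (seeded)."""
    return simulate_codon_alignment(
        SimulationSpec(
            tree=small_tree, n_sites=300, seed=42,
            mixture=branch_site(0.72, 0.18, 0.1, 8.0), kappa=2.0,
        )
    )
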