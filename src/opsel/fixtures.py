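"""Self-contained synthetic study fixtures.

``make_fixture`` writes a small simulated study mirroring the four-clade
bird phylogeny of interest here — an unrooted tree
((Strigiformes, Coraciimorphae), Falconiformes, Accipitriformes) with the
owl stem marked as foreground — together with simulated codon alignments
and their ground-truth histories.  The default scale carries 3 genes over
26 taxa (the species count of the motivating study design); the tiny
scale is 1 gene over 6 taxa for quick smoke runs.
"""

from __future__ import annotations

import json
from pathlib import Path

from opsel.likelihood import SiteClassMixture
from opsel.seqio import LabeledTree, read_labeled_tree, write_alignment
from opsel.simulate import SimulationSpec, simulate_codon_alignment, write_truth_json

#: taxon counts per clade at the default scale (total 26)
DEFAULT_CLADES = {"owl": 7, "corac": 8, "falcon": 4, "accip": 7}
TINY_CLADES = {"owl": 2, "corac": 2, "falcon": 1, "accip": 1}


def _ladder(names: list[str], bl: float, mark: bool = False) -> str:
    """Pectinate newick subtree (no length on its own root); optionally #1-marked."""
    m = "#1" if mark else ""
    if len(names) == 1:
        return f"{names[0]}{m}"
    sub = f"({names[0]}{m}:{bl},{names[1]}{m}:{bl})"
    for n in names[2:]:
        sub = f"({sub}{m}:{bl},{n}{m}:{bl})"
    return sub


def four_clade_tree(
    clades: dict[str, int] | None = None,
    *,
    branch_length: float = 0.06,
    stem_length: float = 0.12,
    mark: str = "stem",
) -> LabeledTree:
    """The study topology with the owl clade's stem (or whole clade) as foreground.

    mark='stem' flags only the branch ancestral to the owls (branch and
    branch-site analyses); mark='clade' flags the stem plus every branch
    inside the owl clade (clade-model analyses).
    """
    if mark not in ("stem", "clade"):
        raise ValueError("mark must be 'stem' or 'clade'")
    clades = dict(clades or DEFAULT_CLADES)
    names = {k: [f"{k}{i + 1}" for i in range(v)] for k, v in clades.items()}
    owls = _ladder(names["owl"], branch_length, mark=(mark == "clade"))
    corac = _ladder(names["corac"], branch_length)
    falcon = _ladder(names["falcon"], branch_length)
    accip = _ladder(names["accip"], branch_length)
    owl_group = f"{owls}:{stem_length}" if owls.endswith("#1") else f"{owls}#1:{stem_length}"
    newick = (
        f"(({owl_group},{corac}:{stem_length}):{stem_length},"
        f"{falcon}:{stem_length},{accip}:{stem_length});"
    )
    return read_labeled_tree(data=newick)


#: Gene scenarios simulated by make_fixture: (name, family, omega2, n_codons)
FIXTURE_GENES = [
    ("geneA_selected", 8.0, 300),   # strong foreground selection
    ("geneB_weak", 2.5, 300),       # moderate foreground selection
    ("geneC_neutral", 1.0, 300),    # null: no positive selection
]


def make_fixture(seed: int, scale: str = "default", out_dir: str | Path = "fixture") -> Path:
    """Write a self-contained synthetic study; returns the directory path."""
    if scale not in ("default", "tiny"):
        raise ValueError("scale must be 'default' or 'tiny'")
    clades = DEFAULT_CLADES if scale == "default" else TINY_CLADES
    genes = FIXTURE_GENES if scale == "default" else FIXTURE_GENES[:1]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = four_clade_tree(clades)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    manifest = {"seed": seed, "scale": scale, "genes": []}
    for k, (name, omega2, n_codons) in enumerate(genes):
        mixture = SiteClassMixture(
            "branch-site-A",
            [0.70, 0.20, 0.0777778, 0.0222222],
            [
                {"background": 0.05, "foreground": 0.05},
                {"background": 1.0, "foreground": 1.0},
                {"background": 0.05, "foreground": omega2},
                {"background": 1.0, "foreground": omega2},
            ],
        )
        spec = SimulationSpec(
            tree=tree, n_sites=n_codons, seed=seed * 1000 + k, mixture=mixture, kappa=2.0
        )
        ds = simulate_codon_alignment(spec)
        write_alignment(ds.alignment, out / f"{name}.fasta")
        write_truth_json(ds, out / f"{name}.truth.json")
        manifest["genes"].append({"name": name, "alignment": f"{name}.fasta",
                                  "true_omega2": omega2, "n_codons": n_codons})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
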