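"""Phylogenetic likelihood and maximum-likelihood fitting for codon site-class models.

Model families
--------------
``one-ratio``          one omega shared by all branches and sites (M0).
``two-ratio``          branch model: separate omega on foreground branches.
``two-ratio-null``     branch model with foreground omega fixed at 1.
``M1a``                nearly-neutral site model: classes (0 < omega0 < 1, omega1 = 1).
``branch-site-A``      four site classes; classes 2a/2b allow omega2 >= 1 on the
                       foreground branches only (the "modified model A").
``branch-site-A-null`` the same with omega2 fixed at 1 (the Test 2 null).
``M2a_rel``            three shared classes (omega0, 1, omega2 >= 0); the relaxed
                       null for clade model C.
``clade-C``            three classes; the third has distinct omegas on the
                       foreground and background clade partitions.

The mixture likelihood at a site is the proportion-weighted sum of pruning
likelihoods, one per site class, each class using its branch-partition
omega.  All class generators share a common scale factor computed from the
background-branch mixture, so one unit of branch length is one expected
substitution per codon on background branches.

Fitting maximizes the likelihood with L-BFGS-B on transformed parameters
(log kappa/omega, logistic for probabilities and omega0, stick-breaking on
the simplex), with a multi-start grid over initial (kappa, omega) so that
results can be checked for optimizer stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from opsel._genetic_code import N_CODONS
from opsel._pruning import TreeIndex, site_log_likelihoods
from opsel.codon_model import (
    OMEGA_MAX,
    RateMatrix,
    equal_frequencies,
    expected_rate,
    f3x4_frequencies,
    unscaled_rate_matrix,
)
from opsel.seqio import CodonAlignment, LabeledTree

#: Omegas this close to a boundary are reported exactly at it.
_BOUNDARY_SNAP = 1e-4

#: Default multi-start grid over initial (kappa, omega).
DEFAULT_KAPPA_STARTS = (1.0, 2.0, 5.0)
DEFAULT_OMEGA_STARTS = (0.1, 0.5, 1.5)


class ModelError(ValueError):
    """Raised for invalid mixtures or unsupported model requests."""


# ---------------------------------------------------------------------------
# Site-class mixtures


@dataclass
class SiteClassMixture:
    """A model family's site classes.

    ``proportions[c]`` is the weight of class ``c``; ``class_omegas[c]`` maps
    branch partition ('background' / 'foreground') to the omega that class
    uses there.
    """

    family: str
    proportions: np.ndarray
    class_omegas: list[dict[str, float]]

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.family not in FAMILIES:
            raise ModelError(f"unknown model family {self.family!r}")
        if len(self.proportions) != len(self.class_omegas):
            raise ModelError("proportions and class_omegas differ in length")
        if (self.proportions < -1e-12).any():
            raise ModelError("negative class proportion")
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise ModelError("class proportions must sum to 1")
        for c in self.class_omegas:
            for part, w in c.items():
                if part not in ("background", "foreground"):
                    raise ModelError(f"unknown branch partition {part!r}")
                if not (0 <= w <= OMEGA_MAX):
                    raise ModelError(f"omega {w} outside [0, {OMEGA_MAX}]")
        spec = FAMILIES[self.family]
        if len(self.class_omegas) != spec["n_classes"]:
            raise ModelError(
                f"{self.family} requires {spec['n_classes']} site classes, "
                f"got {len(self.class_omegas)}"
            )
        for c in spec["neutral_classes"]:
            for part, w in self.class_omegas[c].items():
                if self.family == "branch-site-A" and part == "foreground" and c in (2, 3):
                    continue
                if w != 1.0:
                    raise ModelError(
                        f"class {c} of {self.family} must have omega = 1 on {part}"
                    )
        if self.family in ("branch-site-A", "branch-site-A-null"):
            p0, p1, p2a, p2b = self.proportions
            if p1 > 1e-12 and abs(p2a * p1 - p2b * p0) > 1e-6 * max(p0, p1, 1e-12):
                raise ModelError("branch-site model requires p2a/p2b = p0/p1")

    @property
    def n_classes(self) -> int:
        return len(self.proportions)

    def uses_foreground(self) -> bool:
        return any(
            c.get("foreground", c["background"]) != c["background"] for c in self.class_omegas
        ) or FAMILIES[self.family]["requires_foreground"]

    def omega_on(self, class_index: int, partition: str) -> float:
        c = self.class_omegas[class_index]
        return c.get(partition, c["background"])


# Family metadata: free parameters (transformed-space kinds) and builders.
# Kinds: 'prob' (logistic), 'omega01' (logistic), 'omega_pos' (log),
# 'omega_ge1' (1 + exp).


def _bs_a_classes(w0: float, w2: float) -> list[dict[str, float]]:
    return [
        {"background": w0, "foreground": w0},
        {"background": 1.0, "foreground": 1.0},
        {"background": w0, "foreground": w2},
        {"background": 1.0, "foreground": w2},
    ]


def _build_one_ratio(v: dict) -> SiteClassMixture:
    w = v["omega"]
    return SiteClassMixture("one-ratio", [1.0], [{"background": w, "foreground": w}])


def _build_two_ratio(v: dict) -> SiteClassMixture:
    return SiteClassMixture(
        "two-ratio", [1.0], [{"background": v["omega_bg"], "foreground": v["omega_fg"]}]
    )


def _build_two_ratio_null(v: dict) -> SiteClassMixture:
    return SiteClassMixture(
        "two-ratio-null", [1.0], [{"background": v["omega_bg"], "foreground": 1.0}]
    )


def _build_m1a(v: dict) -> SiteClassMixture:
    w0, p0 = v["omega0"], v["p0"]
    return SiteClassMixture(
        "M1a",
        [p0, 1 - p0],
        [{"background": w0, "foreground": w0}, {"background": 1.0, "foreground": 1.0}],
    )


def _bs_props(s: float, r: float) -> np.ndarray:
    # s = p0 + p1, r = p0 / (p0 + p1); p2a/p2b inherit the p0/p1 ratio,
    # enforcing the branch-site constraint by construction.
    return np.array([s * r, s * (1 - r), (1 - s) * r, (1 - s) * (1 - r)])


def _build_bs_a(v: dict) -> SiteClassMixture:
    return SiteClassMixture(
        "branch-site-A", _bs_props(v["p01"], v["r0"]), _bs_a_classes(v["omega0"], v["omega2"])
    )


def _build_bs_a_null(v: dict) -> SiteClassMixture:
    m = SiteClassMixture(
        "branch-site-A-null", _bs_props(v["p01"], v["r0"]), _bs_a_classes(v["omega0"], 1.0)
    )
    return m


def _simplex3(u: float, vv: float) -> np.ndarray:
    return np.array([u, (1 - u) * vv, (1 - u) * (1 - vv)])


def _build_m2a_rel(v: dict) -> SiteClassMixture:
    w0, w2 = v["omega0"], v["omega2"]
    return SiteClassMixture(
        "M2a_rel",
        _simplex3(v["u"], v["v"]),
        [
            {"background": w0, "foreground": w0},
            {"background": 1.0, "foreground": 1.0},
            {"background": w2, "foreground": w2},
        ],
    )


def _build_clade_c(v: dict) -> SiteClassMixture:
    w0 = v["omega0"]
    return SiteClassMixture(
        "clade-C",
        _simplex3(v["u"], v["v"]),
        [
            {"background": w0, "foreground": w0},
            {"background": 1.0, "foreground": 1.0},
            {"background": v["omega2_bg"], "foreground": v["omega2_fg"]},
        ],
    )


FAMILIES: dict[str, dict] = {
    "one-ratio": dict(
        free=[("omega", "omega_pos")],
        build=_build_one_ratio,
        n_classes=1,
        neutral_classes=(),
        requires_foreground=False,
    ),
    "two-ratio": dict(
        free=[("omega_bg", "omega_pos"), ("omega_fg", "omega_pos")],
        build=_build_two_ratio,
        n_classes=1,
        neutral_classes=(),
        requires_foreground=True,
    ),
    "two-ratio-null": dict(
        free=[("omega_bg", "omega_pos")],
        build=_build_two_ratio_null,
        n_classes=1,
        neutral_classes=(),
        requires_foreground=True,
    ),
    "M1a": dict(
        free=[("p0", "prob"), ("omega0", "omega01")],
        build=_build_m1a,
        n_classes=2,
        neutral_classes=(1,),
        requires_foreground=False,
    ),
    "branch-site-A": dict(
        free=[("p01", "prob"), ("r0", "prob"), ("omega0", "omega01"), ("omega2", "omega_ge1")],
        build=_build_bs_a,
        n_classes=4,
        neutral_classes=(1, 3),
        requires_foreground=True,
    ),
    "branch-site-A-null": dict(
        free=[("p01", "prob"), ("r0", "prob"), ("omega0", "omega01")],
        build=_build_bs_a_null,
        n_classes=4,
        neutral_classes=(1, 3),
        requires_foreground=True,
    ),
    "M2a_rel": dict(
        free=[("u", "prob"), ("v", "prob"), ("omega0", "omega01"), ("omega2", "omega_pos")],
        build=_build_m2a_rel,
        n_classes=3,
        neutral_classes=(1,),
        requires_foreground=False,
    ),
    "clade-C": dict(
        free=[
            ("u", "prob"),
            ("v", "prob"),
            ("omega0", "omega01"),
            ("omega2_bg", "omega_pos"),
            ("omega2_fg", "omega_pos"),
        ],
        build=_build_clade_c,
        n_classes=3,
        neutral_classes=(1,),
        requires_foreground=True,
    ),
}

_NESTED_CONSTRAINTS = {
    ("two-ratio", "omega_fg=1"): "two-ratio-null",
    ("branch-site-A", "omega2=1"): "branch-site-A-null",
}


def constrain(model: "SiteClassMixture | str", constraint: str) -> "SiteClassMixture | str":
    """Return the nested model obtained by fixing a parameter.

    ``constrain('two-ratio', 'omega_fg=1')`` -> ``'two-ratio-null'``;
    ``constrain('branch-site-A', 'omega2=1')`` -> ``'branch-site-A-null'``
    (the Test 2 null).  Given a fitted mixture, returns the constrained
    mixture with the fixed value substituted.  Constraining a parameter
    that the family already fixes is an error.
    """
    family = model if isinstance(model, str) else model.family
    key = (family, constraint.replace(" ", ""))
    if key not in _NESTED_CONSTRAINTS:
        for (fam, cons), _ in _NESTED_CONSTRAINTS.items():
            if cons == key[1] and _NESTED_CONSTRAINTS[(fam, cons)] == family:
                raise ModelError(f"{constraint!r} is already fixed in family {family!r}")
        raise ModelError(f"unknown constraint {constraint!r} for family {family!r}")
    null_family = _NESTED_CONSTRAINTS[key]
    if isinstance(model, str):
        return null_family
    if family == "two-ratio":
        return SiteClassMixture(
            null_family,
            model.proportions,
            [{"background": model.class_omegas[0]["background"], "foreground": 1.0}],
        )
    w0 = model.class_omegas[0]["background"]
    return SiteClassMixture(null_family, model.proportions, _bs_a_classes(w0, 1.0))


# ---------------------------------------------------------------------------
# Pattern compression and the mixture likelihood engine


def compress_codon_patterns(aln: CodonAlignment):
    """Unique site patterns of a codon alignment.

    Returns (tips (n_taxa, n_patterns, 61), weights (n_patterns,),
    inverse (n_sites,)) with ``inverse[h]`` the pattern index of site h.
    """
    cols = [tuple(aln.codon(i, h) for i in range(len(aln.taxa))) for h in range(aln.n_sites)]
    seen: dict[tuple, int] = {}
    inverse = np.empty(len(cols), dtype=int)
    uniques: list[tuple] = []
    for h, col in enumerate(cols):
        if col not in seen:
            seen[col] = len(uniques)
            uniques.append(col)
        inverse[h] = seen[col]
    weights = np.bincount(inverse, minlength=len(uniques)).astype(float)
    from opsel._genetic_code import compatible_codon_states

    cache: dict[str, np.ndarray] = {}
    tips = np.empty((len(aln.taxa), len(uniques), N_CODONS))
    for p, col in enumerate(uniques):
        for i, codon in enumerate(col):
            if codon not in cache:
                cache[codon] = compatible_codon_states(codon)
            tips[i, p] = cache[codon]
    return tips, weights, inverse


def mixture_scale(mixture: SiteClassMixture, kappa: float, pi: np.ndarray) -> float:
    """Common generator scale: expected rate of the background-branch mixture."""
    mu = 0.0
    for p, c in zip(mixture.proportions, mixture.class_omegas):
        Q = unscaled_rate_matrix(kappa, c["background"], pi)
        mu += p * expected_rate(Q, pi)
    return mu if mu > 1e-12 else 1.0


def class_site_log_likelihoods(
    tips: np.ndarray,
    idx: TreeIndex,
    leaf_rows: dict[int, int],
    mixture: SiteClassMixture,
    kappa: float,
    pi: np.ndarray,
    class_indices: list[int] | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """(n_classes, n_patterns) per-class pruning log-likelihoods.

    ``scale`` overrides the generator scale (used by BEB, which keeps the
    MLE mixture's branch-length calibration while varying the mixture).
    """
    mu = mixture_scale(mixture, kappa, pi) if scale is None else scale
    rate_cache: dict[float, RateMatrix] = {}

    def rm(w: float) -> RateMatrix:
        if w not in rate_cache:
            rate_cache[w] = RateMatrix(unscaled_rate_matrix(kappa, w, pi) / mu, pi, mu)
        return rate_cache[w]

    classes = list(range(mixture.n_classes)) if class_indices is None else list(class_indices)
    n_pat = tips.shape[1]
    out = np.empty((len(classes), n_pat))
    P = np.empty((idx.n_nodes, N_CODONS, N_CODONS))
    for row, c in enumerate(classes):
        groups: dict[float, list[int]] = {}
        for v in range(idx.n_nodes):
            if v == idx.root:
                continue
            part = "foreground" if idx.foreground[v] else "background"
            groups.setdefault(mixture.omega_on(c, part), []).append(v)
        for w, nodes in groups.items():
            P[nodes] = rm(w).transition_matrices(idx.lengths[nodes])
        out[row] = site_log_likelihoods(tips, idx, P, pi, leaf_rows)
    return out


def _mixture_log_likelihood(
    tips, weights, idx, leaf_rows, mixture, kappa, pi
) -> float:
    cls = class_site_log_likelihoods(tips, idx, leaf_rows, mixture, kappa, pi)
    with np.errstate(divide="ignore"):
        logp = np.log(np.maximum(mixture.proportions, 1e-300))[:, None]
    site = logsumexp(cls + logp, axis=0)
    return float(np.dot(site, weights))


def log_likelihood(
    alignment: CodonAlignment,
    tree: LabeledTree,
    mixture: SiteClassMixture,
    *,
    kappa: float,
    pi: np.ndarray,
) -> float:
    """Total log-likelihood of the alignment under a site-class mixture."""
    tree.validate_against(alignment)
    if mixture.uses_foreground() and FAMILIES[mixture.family]["requires_foreground"]:
        tree.require_foreground()
    idx = TreeIndex(tree)
    leaf_rows = idx.leaf_rows(alignment.taxa)
    tips, weights, _ = compress_codon_patterns(alignment)
    return _mixture_log_likelihood(tips, weights, idx, leaf_rows, mixture, kappa, pi)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """A maximized model fit.

    ``lnl`` is the maximum over restarts; ``params`` holds natural-scale
    MLEs (kappa, omegas, proportions); ``tree`` carries the branch lengths
    actually used (estimated under the model when requested).
    """

    family: str
    lnl: float
    kappa: float
    pi: np.ndarray
    mixture: SiteClassMixture
    params: dict[str, float]
    tree: LabeledTree
    converged: bool
    n_starts: int
    start_lnls: list[float] = field(default_factory=list)

    def foreground_omega(self) -> float:
        """The omega governing the foreground in this family's selected class."""
        if self.family in ("one-ratio",):
            return self.mixture.class_omegas[0]["background"]
        if self.family in ("two-ratio", "two-ratio-null"):
            return self.mixture.class_omegas[0]["foreground"]
        if self.family in ("branch-site-A", "branch-site-A-null"):
            return self.mixture.class_omegas[2]["foreground"]
        return self.mixture.class_omegas[-1]["foreground"]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "lnl": self.lnl,
            "kappa": self.kappa,
            "params": self.params,
            "proportions": self.mixture.proportions.tolist(),
            "class_omegas": self.mixture.class_omegas,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "start_lnls": self.start_lnls,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


_KAPPA_BOUNDS = (np.log(0.01), np.log(100.0))
_T_BOUNDS = (np.log(1e-6), np.log(50.0))
_PROB_BOUNDS = (-12.0, 12.0)
_OMEGA_POS_BOUNDS = (np.log(1e-6), np.log(OMEGA_MAX))
_OMEGA_GE1_BOUNDS = (np.log(1e-9), np.log(OMEGA_MAX - 1.0))


def _decode(kind: str, x: float) -> float:
    if kind == "prob" or kind == "omega01":
        return float(expit(x))
    if kind == "omega_pos":
        return float(min(np.exp(x), OMEGA_MAX))
    if kind == "omega_ge1":
        return float(min(1.0 + np.exp(x), OMEGA_MAX))
    raise AssertionError(kind)


def _encode(kind: str, v: float) -> float:
    if kind == "prob" or kind == "omega01":
        v = min(max(v, 1e-5), 1 - 1e-5)
        return float(np.log(v / (1 - v)))
    if kind == "omega_pos":
        return float(np.log(max(v, 1e-6)))
    if kind == "omega_ge1":
        return float(np.log(max(v - 1.0, 1e-9)))
    raise AssertionError(kind)


def _bounds(kind: str) -> tuple[float, float]:
    return {
        "prob": _PROB_BOUNDS,
        "omega01": _PROB_BOUNDS,
        "omega_pos": _OMEGA_POS_BOUNDS,
        "omega_ge1": _OMEGA_GE1_BOUNDS,
    }[kind]


def _start_values(family: str, kappa0: float, omega0: float) -> dict[str, float]:
    """Map a generic (kappa, omega) start onto a family's free parameters."""
    w01 = min(max(omega0, 0.05), 0.9)
    defaults = {
        "omega": omega0,
        "omega_bg": omega0,
        "omega_fg": omega0,
        "p0": 0.7,
        "p01": 0.85,
        "r0": 0.9,
        "u": 0.7,
        "v": 0.5,
        "omega0": w01,
        "omega2": max(omega0, 1.5),
        "omega2_bg": max(omega0, 0.5),
        "omega2_fg": max(omega0, 1.5),
    }
    return {name: defaults[name] for name, _ in FAMILIES[family]["free"]}


def _snap_boundaries(values: dict[str, float]) -> dict[str, float]:
    out = {}
    for k, v in values.items():
        if k.startswith("omega"):
            if abs(v - OMEGA_MAX) < OMEGA_MAX * _BOUNDARY_SNAP:
                v = OMEGA_MAX
            elif k in ("omega2",) and abs(v - 1.0) < _BOUNDARY_SNAP:
                v = 1.0
        out[k] = v
    return out


def fit(
    alignment: CodonAlignment,
    tree: LabeledTree,
    family: str,
    *,
    pi: "np.ndarray | str" = "f3x4",
    start_grid: "list[tuple[float, float]] | None" = None,
    extra_starts: "list[dict[str, float]] | None" = None,
    estimate_branch_lengths: "bool | None" = None,
    optimizer_tol: float = 1e-8,
    max_iter: int = 1000,
) -> FitResult:
    """Maximum-likelihood fit of one model family.

    Branch lengths are co-estimated for the one-ratio family by default and
    held at the input tree's lengths for the other families (pass
    ``estimate_branch_lengths`` to override); the usual workflow estimates
    them once under one-ratio and reuses them, which preserves nesting
    across the model ladder.  ``start_grid`` is a list of initial
    (kappa, omega) pairs; the default is the 3x3 grid
    kappa in {1, 2, 5} x omega in {0.1, 0.5, 1.5}.  The reported fit is the
    best over starts; per-start log-likelihoods are kept for stability
    audits.
    """
    if family not in FAMILIES:
        raise ModelError(f"unknown model family {family!r}")
    spec = FAMILIES[family]
    tree.validate_against(alignment)
    if spec["requires_foreground"]:
        tree.require_foreground()
    if isinstance(pi, str):
        pi_vec = f3x4_frequencies(alignment) if pi == "f3x4" else equal_frequencies()
    else:
        pi_vec = np.asarray(pi, dtype=float)
    if estimate_branch_lengths is None:
        estimate_branch_lengths = family == "one-ratio"
    if start_grid is None:
        start_grid = [(k, w) for k in DEFAULT_KAPPA_STARTS for w in DEFAULT_OMEGA_STARTS]

    idx = TreeIndex(tree)
    leaf_rows = idx.leaf_rows(alignment.taxa)
    tips, weights, _ = compress_codon_patterns(alignment)
    free = spec["free"]
    edge_nodes = [v for v in range(idx.n_nodes) if v != idx.root]

    def unpack(x: np.ndarray):
        kappa = float(np.exp(x[0]))
        values = {name: _decode(kind, x[1 + i]) for i, (name, kind) in enumerate(free)}
        mixture = spec["build"](values)
        if estimate_branch_lengths:
            lengths = idx.lengths.copy()
            lengths[edge_nodes] = np.exp(x[1 + len(free) :])
        else:
            lengths = idx.lengths
        return kappa, values, mixture, lengths

    def objective(x: np.ndarray) -> float:
        kappa, _, mixture, lengths = unpack(x)
        old = idx.lengths
        idx.lengths = lengths
        try:
            val = _mixture_log_likelihood(tips, weights, idx, leaf_rows, mixture, kappa, pi_vec)
        finally:
            idx.lengths = old
        if not np.isfinite(val):
            return 1e10
        return -val

    bounds = [_KAPPA_BOUNDS] + [_bounds(kind) for _, kind in free]
    if estimate_branch_lengths:
        bounds += [_T_BOUNDS] * len(edge_nodes)

    starts: list[list[float]] = []
    for kappa0, omega0 in start_grid:
        sv = _start_values(family, kappa0, omega0)
        starts.append(
            [np.log(kappa0)] + [_encode(kind, sv[name]) for name, kind in free]
        )
    for sv in extra_starts or []:
        # warm starts, e.g. from a nested null's MLEs: missing free
        # parameters fall back to the generic defaults
        base_sv = _start_values(family, sv.get("kappa", 2.0), 0.5)
        base_sv.update({k: v for k, v in sv.items() if k in base_sv})
        starts.append(
            [np.log(sv.get("kappa", 2.0))]
            + [_encode(kind, base_sv[name]) for name, kind in free]
        )

    best = None
    start_lnls: list[float] = []
    for x0 in starts:
        if estimate_branch_lengths:
            x0 = x0 + list(np.log(np.maximum(idx.lengths[edge_nodes], 1e-4)))
        res = minimize(
            objective,
            np.array(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(ftol=optimizer_tol, gtol=1e-7, maxiter=max_iter, eps=1e-6),
        )
        start_lnls.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res

    kappa, values, mixture, lengths = unpack(best.x)
    values = _snap_boundaries(values)
    mixture = spec["build"](values)
    out_tree = tree.with_lengths(lengths) if estimate_branch_lengths else tree
    params = dict(values)
    params["kappa"] = kappa
    return FitResult(
        family=family,
        lnl=-float(best.fun),
        kappa=kappa,
        pi=pi_vec,
        mixture=mixture,
        params=params,
        tree=out_tree,
        converged=bool(best.success),
        n_starts=len(starts),
        start_lnls=start_lnls,
    )
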