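"""Empirical-Bayes identification of positively selected sites under branch-site model A.

Two flavours:

* NEB (naive empirical Bayes): site-class posteriors computed by plugging
  the MLEs straight in — posterior(class c at site h) is proportional to
  p_c x L_h(c).
* BEB (Bayes empirical Bayes): the same posterior averaged over a uniform
  grid on the mixture proportions and omega2 (kappa, omega0 and branch
  lengths stay at their MLEs), weighting each grid point by its posterior
  given the whole alignment.  This integrates out the sampling error in
  the mixture parameters that NEB ignores.

The "positive selection" probability of a site is the posterior mass of
classes 2a + 2b (the classes with omega2 on the foreground).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from opsel._pruning import TreeIndex
from opsel.likelihood import (
    FitResult,
    SiteClassMixture,
    _bs_a_classes,
    _bs_props,
    class_site_log_likelihoods,
    compress_codon_patterns,
)
from opsel.seqio import CodonAlignment, LabeledTree, NumberingMap

#: Conventional posterior-probability reporting tiers.
THRESHOLDS = (0.50, 0.95, 0.99)

#: BEB grid resolution per integrated dimension (p0+p1, p0/(p0+p1), omega2).
BEB_GRID = 10

#: BEB omega2 grid range; equal steps on [1, 11].
BEB_OMEGA2_RANGE = (1.0, 11.0)


@dataclass
class SitePosterior:
    """Per-site class posteriors and selected-site flags.

    ``table`` has one row per alignment codon site (1-based ``site``),
    columns ``p_class0, p_class1, p_class2a, p_class2b``, their sum
    ``p_positive`` over the positive-selection classes, and boolean flags
    at the reporting thresholds.
    """

    method: str
    table: pd.DataFrame

    def selected_sites(self, threshold: float = 0.95) -> list[int]:
        return self.table.loc[self.table["p_positive"] > threshold, "site"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _posterior_frame(post: np.ndarray, numbering: NumberingMap | None) -> pd.DataFrame:
    n_sites = post.shape[0]
    frame = pd.DataFrame(
        {
            "site": np.arange(1, n_sites + 1),
            "p_class0": post[:, 0],
            "p_class1": post[:, 1],
            "p_class2a": post[:, 2],
            "p_class2b": post[:, 3],
        }
    )
    frame["p_positive"] = frame["p_class2a"] + frame["p_class2b"]
    if numbering is not None:
        frame["reference_site"] = [numbering.to_reference(int(s)) for s in frame["site"]]
    for thr in THRESHOLDS:
        frame[f"selected_{int(thr * 100):02d}"] = frame["p_positive"] > thr
    return frame


def site_posteriors(
    fit: FitResult,
    alignment: CodonAlignment,
    tree: LabeledTree,
    method: str = "BEB",
    *,
    numbering: NumberingMap | None = None,
) -> SitePosterior:
    """Posterior probability that each codon belongs to each branch-site class.

    ``fit`` must be a branch-site-A fit (the alternative of Test 2); the
    tree should carry the branch lengths used in that fit.
    """
    if fit.family != "branch-site-A":
        raise ValueError(
            f"site posteriors require a branch-site-A fit, got {fit.family!r}"
        )
    method = method.upper()
    if method not in ("NEB", "BEB"):
        raise ValueError(f"method must be NEB or BEB, got {method!r}")
    tree.validate_against(alignment)
    idx = TreeIndex(tree)
    leaf_rows = idx.leaf_rows(alignment.taxa)
    tips, weights, inverse = compress_codon_patterns(alignment)

    if method == "NEB":
        cls = class_site_log_likelihoods(
            tips, idx, leaf_rows, fit.mixture, fit.kappa, fit.pi
        )
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(fit.mixture.proportions, 1e-300))[:, None]
        joint = cls + logw
        post_pat = np.exp(joint - logsumexp(joint, axis=0, keepdims=True)).T
        post = post_pat[inverse]
        return SitePosterior("NEB", _posterior_frame(post, numbering))

    return SitePosterior("BEB", _posterior_frame(
        _beb_posteriors(fit, tips, weights, inverse, idx, leaf_rows), numbering
    ))


def _beb_posteriors(fit, tips, weights, inverse, idx, leaf_rows) -> np.ndarray:
    """Grid-average site-class posteriors (BEB_GRID^3 points, uniform prior)."""
    n = BEB_GRID
    mids = (np.arange(n) + 0.5) / n  # grid midpoints on (0, 1)
    w2_lo, w2_hi = BEB_OMEGA2_RANGE
    omega2_grid = w2_lo + (w2_hi - w2_lo) * mids
    omega0 = fit.params["omega0"]

    # Class site log-likelihoods: classes 0 and 1 do not involve omega2;
    # classes 2a/2b are recomputed for each grid omega2.
    # Branch lengths keep the MLE fit's calibration: every grid point reuses
    # the fitted mixture's generator scale.
    from opsel.likelihood import mixture_scale

    mu = mixture_scale(fit.mixture, fit.kappa, fit.pi)
    base = SiteClassMixture(
        "branch-site-A", _bs_props(0.25, 0.5), _bs_a_classes(omega0, 2.0)
    )
    fixed = class_site_log_likelihoods(
        tips, idx, leaf_rows, base, fit.kappa, fit.pi, class_indices=[0, 1], scale=mu
    )
    n_pat = tips.shape[1]
    sel = np.empty((n, 2, n_pat))
    for k, w2 in enumerate(omega2_grid):
        mix_k = SiteClassMixture(
            "branch-site-A", _bs_props(0.25, 0.5), _bs_a_classes(omega0, w2)
        )
        sel[k] = class_site_log_likelihoods(
            tips, idx, leaf_rows, mix_k, fit.kappa, fit.pi, class_indices=[2, 3], scale=mu
        )

    post_pat = np.zeros((n_pat, 4))
    log_marg = np.full((n, n, n), -np.inf)
    logliks = np.empty((n, n, n, 4, n_pat))
    for a, s in enumerate(mids):  # s = p0 + p1
        for b, r in enumerate(mids):  # r = p0 / (p0 + p1)
            props = _bs_props(s, r)
            logp = np.log(np.maximum(props, 1e-300))[:, None]
            for k in range(n):
                cls = np.vstack([fixed, sel[k]])
                joint = cls + logp  # (4, n_pat)
                site_log = logsumexp(joint, axis=0)
                log_marg[a, b, k] = float(np.dot(site_log, weights))
                logliks[a, b, k] = joint - site_log[None, :]
    log_post_grid = log_marg - logsumexp(log_marg)
    grid_w = np.exp(log_post_grid)
    for a in range(n):
        for b in range(n):
            for k in range(n):
                if grid_w[a, b, k] < 1e-14:
                    continue
                post_pat += grid_w[a, b, k] * np.exp(logliks[a, b, k]).T
    post_pat /= post_pat.sum(axis=1, keepdims=True)
    return post_pat[inverse]
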