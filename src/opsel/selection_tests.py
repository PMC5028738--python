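"""Likelihood-ratio tests and the per-gene positive-selection test battery.

The battery mirrors the standard codeml workflow for a focal lineage:

(a) two-ratio vs one-ratio branch model (df 1): does the foreground have
    its own omega?
(b) two-ratio vs two-ratio with omega_fg = 1 (df 1, one-sided
    interpretation): is the foreground omega significantly above 1?
(c) branch-site Test 2: modified model A vs the omega2 = 1 null (df 1).
(d) clade model C vs M1a (df 3).
(e) clade model C vs M2a_rel (df 1), the revised null that better absorbs
    among-site variation in constraint.

A gene is flagged per test when p < alpha and the relevant foreground
omega exceeds 1 (for clade C: the divergent-class foreground omega).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from opsel.likelihood import FitResult, fit
from opsel.seqio import CodonAlignment, LabeledTree


class FitError(RuntimeError):
    """Raised when a nested fit is inconsistent (alt below null beyond tolerance)."""


@dataclass
class LRTResult:
    """A likelihood-ratio test between nested models."""

    two_delta_l: float
    df: int
    p: float
    alt: str = ""
    null: str = ""


def lrt(
    lnl_alt: float,
    lnl_null: float,
    df: int,
    *,
    alt: str = "",
    null: str = "",
    tol: float = 0.02,
) -> LRTResult:
    """Upper-tail chi-square LRT; 2dL negative within tolerance is clamped to 0.

    A deficit beyond ``tol`` signals a failed fit (the alternative must
    reach at least the null's likelihood) and raises FitError rather than
    returning a bogus statistic.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < -tol:
        raise FitError(
            f"alternative lnL {lnl_alt:.6f} below null {lnl_null:.6f} "
            f"(2dL = {stat:.6f}); refit with more starts"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df))
    return LRTResult(two_delta_l=stat, df=df, p=p, alt=alt, null=null)


def branch_site_test2(
    alignment: CodonAlignment,
    tree: LabeledTree,
    *,
    pi: "np.ndarray | str" = "f3x4",
    start_grid=None,
    lrt_tol: float = 0.02,
) -> tuple[LRTResult, FitResult, FitResult]:
    """Branch-site Test 2 alone: (LRT, alternative fit, null fit).

    Branch lengths are estimated under one-ratio and fixed; the
    alternative is warm-started from the null's optimum.
    """
    base = fit(alignment, tree, "one-ratio", pi=pi, start_grid=start_grid,
               estimate_branch_lengths=True)
    null = fit(alignment, base.tree, "branch-site-A-null", pi=pi,
               start_grid=start_grid, estimate_branch_lengths=False)
    alt = fit(alignment, base.tree, "branch-site-A", pi=pi, start_grid=start_grid,
              extra_starts=[dict(null.params, omega2=1.0 + 1e-6)],
              estimate_branch_lengths=False)
    res = lrt(alt.lnl, null.lnl, 1, alt="branch-site-A", null="branch-site-A-null",
              tol=lrt_tol)
    return res, alt, null


#: The five nested comparisons of the battery: (name, alt family, null family, df).
BATTERY_TESTS = [
    ("branch:two-ratio-vs-one-ratio", "two-ratio", "one-ratio", 1),
    ("branch:omega_fg>1", "two-ratio", "two-ratio-null", 1),
    ("branch-site:test2", "branch-site-A", "branch-site-A-null", 1),
    ("clade:C-vs-M1a", "clade-C", "M1a", 3),
    ("clade:C-vs-M2a_rel", "clade-C", "M2a_rel", 1),
]


def run_test_battery(
    alignment: CodonAlignment,
    tree: LabeledTree,
    gene: str = "gene",
    *,
    alpha: float = 0.05,
    pi: "np.ndarray | str" = "f3x4",
    start_grid=None,
    add_bh_column: bool = False,
) -> pd.DataFrame:
    """Run the full positive-selection test battery for one gene.

    Branch lengths are estimated once under the one-ratio model and fixed
    for all other families.  Per-test fit failures are reported in the
    ``error`` column without aborting the remaining tests.  Returns a tidy
    frame: gene, test, lnl_alt, lnl_null, two_delta_l, df, p,
    foreground_omega, selected, error.
    """
    tree.require_foreground()
    tree.validate_against(alignment)

    base = fit(
        alignment, tree, "one-ratio", pi=pi, start_grid=start_grid,
        estimate_branch_lengths=True,
    )
    bl_tree = base.tree
    fits: dict[str, FitResult] = {"one-ratio": base}

    # Warm starts derived from the nested null's MLEs: starting the
    # alternative at the null optimum guarantees lnL_alt >= lnL_null up to
    # optimizer tolerance.
    _WARM = {
        "two-ratio": ("two-ratio-null", lambda p: dict(p, omega_fg=1.0)),
        "branch-site-A": ("branch-site-A-null", lambda p: dict(p, omega2=1.0 + 1e-6)),
        "clade-C": (
            "M2a_rel",
            lambda p: dict(p, omega2_bg=p["omega2"], omega2_fg=p["omega2"]),
        ),
    }

    def get_fit(family: str) -> FitResult:
        if family not in fits:
            extra = []
            if family in _WARM:
                null_family, lift = _WARM[family]
                extra.append(lift(get_fit(null_family).params))
            if family == "two-ratio":
                w = base.params["omega"]
                extra.append(dict(kappa=base.kappa, omega_bg=w, omega_fg=w))
            if family == "clade-C":
                m1a = get_fit("M1a").params
                extra.append(
                    dict(kappa=m1a["kappa"], u=m1a["p0"], v=0.99,
                         omega0=m1a["omega0"], omega2_bg=1.0, omega2_fg=1.0)
                )
            fits[family] = fit(
                alignment, bl_tree, family, pi=pi, start_grid=start_grid,
                extra_starts=extra or None, estimate_branch_lengths=False,
            )
        return fits[family]

    rows = []
    for name, alt_family, null_family, df in BATTERY_TESTS:
        row: dict = {"gene": gene, "test": name, "df": df}
        try:
            alt = get_fit(alt_family)
            null = get_fit(null_family)
            res = lrt(alt.lnl, null.lnl, df, alt=alt_family, null=null_family)
            fg_omega = alt.foreground_omega()
            if alt_family == "clade-C":
                divergent = (
                    alt.mixture.class_omegas[-1]["foreground"]
                    > alt.mixture.class_omegas[-1]["background"]
                )
                selected = res.p < alpha and fg_omega > 1.0 and divergent
            else:
                selected = res.p < alpha and fg_omega > 1.0
            row.update(
                lnl_alt=alt.lnl,
                lnl_null=null.lnl,
                two_delta_l=res.two_delta_l,
                p=res.p,
                foreground_omega=fg_omega,
                selected=bool(selected),
                error="",
            )
        except Exception as e:  # isolate per-test failures
            row.update(
                lnl_alt=np.nan, lnl_null=np.nan, two_delta_l=np.nan, p=np.nan,
                foreground_omega=np.nan, selected=False, error=str(e),
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    if add_bh_column:
        frame["p_bh"] = _benjamini_hochberg(frame["p"].to_numpy())
    cols = [
        "gene", "test", "lnl_alt", "lnl_null", "two_delta_l", "df", "p",
        "foreground_omega", "selected", "error",
    ]
    if add_bh_column:
        cols.append("p_bh")
    return frame[cols]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def write_battery_report(frame: pd.DataFrame, path) -> None:
    """Write the battery report as TSV."""
    frame.to_csv(path, sep="\t", index=False)
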