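"""Opsin lambda-max shift prediction from critical-site substitutions.

Visual-pigment spectral sensitivity is governed by a handful of critical
residues; site-directed mutagenesis has measured the lambda-max effect of
specific replacements at these sites, indexed in bovine rhodopsin
(NP_001014890) numbering.  ``predict_shift`` matches substitution events
(in reference numbering) against a rule table and sums the matched
effects; the sign convention is negative = short-wavelength (blue) shift.

Rules are exact (opsin class, site, ancestral, derived) matches — measured
effects are replacement-specific, so no site-level wildcards and no
assumed reversal antisymmetry: an event at a critical site with no
matching residue pair is reported as unmatched, never silently dropped.

The packaged default table carries the replacements relevant to crepuscular
spectral tuning in birds (S164A and T269A in LWS, S292A in SWS2) plus two
classic RH1 rules; users may extend it with further transcribed literature
values via ``load_tuning_table``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from opsel.ancestral import SubstitutionEvent

OPSIN_CLASSES = ("LWS", "SWS1", "SWS2", "RH1", "RH2")

_COLUMNS = ["class", "site", "from", "to", "delta_nm", "citation"]


class TuningTableError(ValueError):
    """Raised for malformed tuning-rule tables."""


@dataclass(frozen=True)
class TuningRule:
    """One measured critical-site effect: ancestral->derived shifts lambda-max by delta_nm."""

    opsin_class: str
    site: int  # bovine RH1 numbering, 1-based
    ancestral: str
    derived: str
    delta_nm: float
    citation: str = ""

    def __post_init__(self) -> None:
        if self.opsin_class not in OPSIN_CLASSES:
            raise TuningTableError(f"unknown opsin class {self.opsin_class!r}")
        if self.site < 1:
            raise TuningTableError(f"reference site must be >= 1, got {self.site}")
        if self.ancestral == self.derived:
            raise TuningTableError("ancestral and derived residues must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.opsin_class, self.site, self.ancestral, self.derived)

    def label(self) -> str:
        return f"{self.ancestral}{self.site}{self.derived}"


def load_tuning_table(path=None) -> list[TuningRule]:
    """Load tuning rules from a TSV (columns: class, site, from, to, delta_nm, citation).

    With no path, returns the packaged default table.  Malformed rows and
    duplicate (class, site, from, to) entries are reported with their line
    numbers.
    """
    if path is None:
        source = resources.files("opsel").joinpath("data/tuning_rules.tsv")
        with resources.as_file(source) as p:
            return load_tuning_table(p)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as e:
        raise TuningTableError(f"cannot parse tuning table {path}: {e}") from e
    missing = [c for c in _COLUMNS[:-1] if c not in frame.columns]
    if missing:
        raise TuningTableError(f"tuning table missing column(s): {', '.join(missing)}")
    rules: list[TuningRule] = []
    seen: dict[tuple, int] = {}
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            site = int(row["site"])
            delta = float(row["delta_nm"])
        except ValueError:
            raise TuningTableError(
                f"line {line}: non-numeric site or delta_nm "
                f"({row['site']!r}, {row['delta_nm']!r})"
            ) from None
        try:
            rule = TuningRule(
                opsin_class=row["class"], site=site, ancestral=row["from"],
                derived=row["to"], delta_nm=delta, citation=row.get("citation", ""),
            )
        except TuningTableError as e:
            raise TuningTableError(f"line {line}: {e}") from None
        if rule.key in seen:
            raise TuningTableError(
                f"line {line}: duplicate rule {rule.key} (first at line {seen[rule.key]})"
            )
        seen[rule.key] = line
        rules.append(rule)
    return rules


@dataclass
class ShiftPrediction:
    """Matched rules, unmatched events, and the additive total shift in nm."""

    opsin_class: str
    matched: list[tuple[SubstitutionEvent, TuningRule]]
    unmatched: list[SubstitutionEvent]
    total_nm: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "event": e.label(), "site": r.site, "delta_nm": r.delta_nm,
                "matched": True, "citation": r.citation,
            }
            for e, r in self.matched
        ] + [
            {
                "event": e.label(),
                "site": e.reference_site if e.reference_site is not None else e.site,
                "delta_nm": float("nan"), "matched": False, "citation": "",
            }
            for e in self.unmatched
        ]
        return pd.DataFrame(rows, columns=["event", "site", "delta_nm", "matched", "citation"])


def predict_shift(
    events: list[SubstitutionEvent],
    opsin_class: str,
    table: list[TuningRule] | None = None,
) -> ShiftPrediction:
    """Predict the total lambda-max shift implied by substitution events.

    Events must carry reference (bovine RH1) site numbers, either via
    ``reference_site`` or — for events constructed directly in reference
    coordinates — via ``site``.  Matched rule effects add; negative totals
    are short-wavelength shifts.
    """
    if opsin_class not in OPSIN_CLASSES:
        raise TuningTableError(f"unknown opsin class {opsin_class!r}")
    if table is None:
        table = load_tuning_table()
    index = {r.key: r for r in table if r.opsin_class == opsin_class}
    matched: list[tuple[SubstitutionEvent, TuningRule]] = []
    unmatched: list[SubstitutionEvent] = []
    for e in events:
        site = e.reference_site if e.reference_site is not None else e.site
        rule = index.get((opsin_class, site, e.ancestral, e.derived))
        if rule is None:
            unmatched.append(e)
        else:
            matched.append((e, rule))
    total = float(sum(r.delta_nm for _, r in matched))
    return ShiftPrediction(
        opsin_class=opsin_class, matched=matched, unmatched=unmatched, total_nm=total
    )
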