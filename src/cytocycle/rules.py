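"""Canonical vs noncanonical cell-state discretization.

A declarative rule table encodes literature expectations of marker state per
phase (e.g. Ki67 should be high in S-phase; CDT1 should be negative after
S-phase; SLBP should be low after the S/G2 transition). A cell violates a
rule when its gated phase is in the rule's phase set and its marker value
contradicts the expectation relative to the resolved threshold. A cell with
one or more violations is noncanonical.

Default thresholds are quantile-based over all cells (the published absolute
gates are not available numerically); rules are evaluated on the normalized
asinh scale and the shipped table is user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RuleError
from .matrix import PHASES, ExpressionMatrix

EXPECTATIONS = ("high", "low", "positive", "negative")
#: Expectations violated by a value *below* the threshold.
_BELOW_VIOLATES = {"high", "positive"}


@dataclass(frozen=True)
class CanonicalRule:
    rule_id: str
    marker: str
    phases: frozenset
    expectation: str
    threshold_mode: str  # quantile | absolute
    threshold_value: float

    def __post_init__(self) -> None:
        if not self.phases:
            raise RuleError(f"{self.rule_id}: empty phase set")
        bad = set(self.phases) - set(PHASES)
        if bad:
            raise RuleError(f"{self.rule_id}: unknown phases {sorted(bad)}")
        if self.expectation not in EXPECTATIONS:
            raise RuleError(
                f"{self.rule_id}: unknown expectation {self.expectation!r}"
            )
        if self.threshold_mode not in ("quantile", "absolute"):
            raise RuleError(
                f"{self.rule_id}: unknown threshold_mode {self.threshold_mode!r}"
            )
        if self.threshold_mode == "quantile" and not 0 < self.threshold_value < 1:
            raise RuleError(
                f"{self.rule_id}: quantile threshold must be in (0, 1)"
            )


@dataclass
class CanonicalCalls:
    """Per-cell violation counts and rule-level violation masks."""

    violation_count: np.ndarray
    violated: dict[str, np.ndarray]
    resolved_thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def canonical(self) -> np.ndarray:
        return self.violation_count == 0

    def violated_rules(self, cell: int) -> list[str]:
        return [rid for rid, mask in self.violated.items() if mask[cell]]


def default_rules_path():
    return resources.files("cytocycle.data") / "canonical_rules.tsv"


def load_rules(path=None) -> list[CanonicalRule]:
    """Load a TSV rule table (phases '+'-joined, e.g. ``G2+M``)."""
    if path is None:
        path = default_rules_path()
    df = pd.read_csv(path, sep="\t")
    required = {"rule_id", "marker", "phases", "expectation",
                "threshold_mode", "threshold_value"}
    missing = required - set(df.columns)
    if missing:
        raise RuleError(f"rule table missing columns: {sorted(missing)}")
    if df.empty:
        raise RuleError(f"rule table {path} contains no rules")

    rules: list[CanonicalRule] = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.rule_id in seen:
            raise RuleError(f"duplicate rule_id {row.rule_id!r}")
        seen.add(row.rule_id)
        if row.expectation not in EXPECTATIONS:
            raise RuleError(
                f"line {lineno}: unknown expectation {row.expectation!r}"
            )
        rules.append(
            CanonicalRule(
                rule_id=str(row.rule_id),
                marker=str(row.marker),
                phases=frozenset(str(row.phases).split("+")),
                expectation=str(row.expectation),
                threshold_mode=str(row.threshold_mode),
                threshold_value=float(row.threshold_value),
            )
        )
    return rules


def evaluate_rules(m: ExpressionMatrix, phases: np.ndarray,
                   rules: Sequence[CanonicalRule]) -> CanonicalCalls:
    """Evaluate every rule on every cell.

    Quantile thresholds are resolved per marker over all cells. ``high`` and
    ``positive`` expectations are violated by values below the threshold;
    ``low`` and ``negative`` by values above it.
    """
    phases = np.asarray(phases)
    if len(phases) != m.n_cells:
        raise RuleError("phase labels do not align with the matrix")
    missing = sorted({r.marker for r in rules} - set(m.channel_names))
    if missing:
        raise RuleError(f"rule markers missing from matrix: {missing}")

    counts = np.zeros(m.n_cells, dtype=int)
    violated: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for rule in rules:
        x = m.channel(rule.marker)
        if rule.threshold_mode == "quantile":
            t = float(np.quantile(x, rule.threshold_value))
        else:
            t = rule.threshold_value
        thresholds[rule.rule_id] = t
        in_scope = np.isin(phases, list(rule.phases))
        if rule.expectation in _BELOW_VIOLATES:
            mask = in_scope & (x < t)
        else:
            mask = in_scope & (x > t)
        violated[rule.rule_id] = mask
        counts += mask
    return CanonicalCalls(counts, violated, thresholds)


def noncanonical_fraction(calls: CanonicalCalls, groups) -> pd.DataFrame:
    """Per-group noncanonical fraction (noncanonical count / group size).

    ``groups`` is a per-cell label vector or a DataFrame of label columns
    (e.g. cell line x phase). Zero-size groups simply do not appear.
    """
    if isinstance(groups, pd.DataFrame):
        keys = groups.reset_index(drop=True)
    else:
        keys = pd.DataFrame({"group": np.asarray(groups)})
    if len(keys) != len(calls.violation_count):
        raise RuleError("group labels do not align with the calls")
    df = keys.copy()
    df["noncanonical"] = ~calls.canonical
    out = (
        df.groupby(list(keys.columns), observed=True)["noncanonical"]
        .agg(fraction="mean", n="size")
        .reset_index()
    )
    return out
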