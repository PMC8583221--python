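"""Marker positivity calls and subclass assignment.

A cell is called positive for a marker when its intensity is *strictly*
greater than the marker's threshold (ties are negative — stated once here and
tested).  Cells are then assigned to immune subclasses by ordered Boolean
co-expression rules: the first rule whose requirements the call vector
satisfies wins, and cells matching no rule fall back to ``"other"``.
Pan-cytokeratin-positive (epithelial) cells can never receive an immune
subclass because every rule requires panCK negativity.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_model import CellTable, PanelDefinition, ThresholdSet, get_panel

OTHER_LABEL = "other"


@dataclass(frozen=True)
class GatingRule:
    """Declarative positivity requirements defining one immune subclass.

    ``all_of`` markers must all be positive, at least one ``any_of`` marker
    must be positive (when the clause is non-empty), and every ``none_of``
    marker must be negative.
    """

    subclass: str
    panel: str
    all_of: tuple[str, ...] = ()
    any_of: tuple[str, ...] = ()
    none_of: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pdef = get_panel(self.panel)
        positives = set(self.all_of) | set(self.any_of)
        for m in positives | set(self.none_of):
            if m not in pdef.markers:
                raise ConfigError(
                    f"rule {self.subclass!r}: marker {m!r} is not in panel {self.panel!r}"
                )
        if positives & set(self.none_of):
            raise ConfigError(
                f"rule {self.subclass!r}: markers required both positive and negative: "
                f"{sorted(positives & set(self.none_of))}"
            )
        if not positives:
            raise ConfigError(f"rule {self.subclass!r}: no positive requirement")
        if "panCK" in positives:
            raise ConfigError(
                f"rule {self.subclass!r}: immune subclasses must be panCK-negative"
            )

    def matches(self, calls: dict[str, bool]) -> bool:
        """Evaluate this rule on one complete marker call vector."""
        if any(not calls[m] for m in self.all_of):
            return False
        if self.any_of and not any(calls[m] for m in self.any_of):
            return False
        if any(calls[m] for m in self.none_of):
            return False
        return True


@dataclass(frozen=True)
class RuleSet:
    """Ordered gating rules; precedence is list order, first match wins."""

    rules: tuple[GatingRule, ...]
    fallback: str = OTHER_LABEL

    def __post_init__(self) -> None:
        names = [r.subclass for r in self.rules]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate subclass name(s): {dup}")

    @property
    def subclasses(self) -> tuple[str, ...]:
        return tuple(r.subclass for r in self.rules)

    def for_panel(self, panel: str) -> tuple[GatingRule, ...]:
        return tuple(r for r in self.rules if r.panel == panel)

    def panels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.panel, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def apply_thresholds(cells: CellTable, thresholds: ThresholdSet) -> pd.DataFrame:
    """Binary marker calls for every cell: ``intensity > threshold`` (strict).

    Returns a boolean DataFrame with one column per panel marker, aligned with
    the cell table's rows.
    """
    if thresholds.panel != cells.panel.name:
        raise ConfigError(
            f"threshold set is for panel {thresholds.panel!r}, "
            f"cells are panel {cells.panel.name!r}"
        )
    for m in cells.panel.markers:
        if m not in thresholds.thresholds:
            raise ConfigError(f"marker {m!r} has no threshold")
    intens = cells.intensity_matrix()
    cut = pd.Series({m: thresholds[m] for m in cells.panel.markers})
    return intens.gt(cut, axis=1)


# ---------------------------------------------------------------------------
# Phenotype assignment
# ---------------------------------------------------------------------------


def assign_phenotype(calls: dict[str, bool], rules: RuleSet, panel: str) -> str:
    """Assign one call vector to a subclass (scalar form; see assign_phenotypes)."""
    for rule in rules.for_panel(panel):
        if rule.matches(calls):
            return rule.subclass
    return rules.fallback


def assign_phenotypes(calls: pd.DataFrame, rules: RuleSet, panel: str) -> pd.Series:
    """Vectorized first-match-wins assignment over a call matrix."""
    labels = pd.Series(rules.fallback, index=calls.index, dtype=object)
    unassigned = np.ones(len(calls), dtype=bool)
    for rule in rules.for_panel(panel):
        mask = np.ones(len(calls), dtype=bool)
        for m in rule.all_of:
            mask &= calls[m].to_numpy()
        if rule.any_of:
            any_mask = np.zeros(len(calls), dtype=bool)
            for m in rule.any_of:
                any_mask |= calls[m].to_numpy()
            mask &= any_mask
        for m in rule.none_of:
            mask &= ~calls[m].to_numpy()
        hit = mask & unassigned
        labels.iloc[np.flatnonzero(hit)] = rule.subclass
        unassigned &= ~hit
    return labels


# ---------------------------------------------------------------------------
# Rule-set audit
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of the exhaustive rule-set audit; report-only, never raises."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    unreachable: list[str] = field(default_factory=list)
    #: (panel, call-vector, [matching subclasses]) for vectors matched by >1 rule
    overlaps: list[tuple[str, tuple[bool, ...], list[str]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_rules(
    rules: RuleSet, panels: dict[str, PanelDefinition] | None = None
) -> ValidationReport:
    """Audit a rule set by exhaustive enumeration of all call vectors.

    Each panel has at most 7 markers, so all <= 2^7 Boolean call vectors are
    enumerated.  The report lists (a) structural errors, (b) vectors matched
    by more than one rule — resolved by rule order, hence warnings — and
    (c) rules shadowed by earlier rules (unreachable: they never win).
    """
    report = ValidationReport()
    if panels is None:
        from .io_model import PANELS as panels  # noqa: N811

    for panel_name in rules.panels():
        pdef = panels.get(panel_name)
        if pdef is None:
            report.errors.append(f"rules reference unknown panel {panel_name!r}")
            continue
        panel_rules = rules.for_panel(panel_name)
        markers = pdef.markers
        winners: dict[str, int] = {r.subclass: 0 for r in panel_rules}
        for bits in itertools.product((False, True), repeat=len(markers)):
            calls = dict(zip(markers, bits))
            matching = [r.subclass for r in panel_rules if r.matches(calls)]
            if len(matching) > 1:
                report.overlaps.append((panel_name, bits, matching))
                report.warnings.append(
                    f"panel {panel_name}: call vector {dict(zip(markers, bits))} "
                    f"matches {matching}; resolved by order to {matching[0]!r}"
                )
            if matching:
                winners[matching[0]] += 1
        for r in panel_rules:
            if winners[r.subclass] == 0:
                report.unreachable.append(r.subclass)
                report.errors.append(
                    f"rule {r.subclass!r} is unreachable (shadowed by earlier rules)"
                )
    return report


# ---------------------------------------------------------------------------
# Full gating of a table
# ---------------------------------------------------------------------------


def gate_table(
    cells: CellTable,
    thresholds: ThresholdSet,
    rules: RuleSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold and phenotype a cell table.

    Returns ``(phenotyped, counts)`` where *phenotyped* is the cell table plus
    one boolean ``call_<marker>`` column per marker and a ``subclass`` column,
    and *counts* is the per-core subclass tally (one row per core_id x label,
    including ``"other"``).  The counts partition the input: they sum to the
    number of cells.
    """
    calls = apply_thresholds(cells, thresholds)
    labels = assign_phenotypes(calls, rules, cells.panel.name)
    phenotyped = cells.df.copy()
    for m in cells.panel.markers:
        phenotyped[f"call_{m}"] = calls[m]
    phenotyped["subclass"] = labels

    panel_labels = [r.subclass for r in rules.for_panel(cells.panel.name)]
    panel_labels.append(rules.fallback)
    counts = (
        phenotyped.groupby(["core_id", "subclass"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    return phenotyped, counts
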