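"""Itemized cost ledger for a screening program, with per-scenario values.

A program's costs are recorded as an ordered list of line items.  Each item
belongs to a *category* (``capital`` for one-time equipment investment,
``recurrent`` for per-cycle running costs) and a *bucket* (the spending group
used for subtotals and sensitivity analysis: equipment, medical supplies,
staff, transport, maintenance, resident travel).  Every item carries one
whole-dollar value per declared funding scenario, because real discounts are
item-specific (a partial flight grant, a free software subscription) and do
not follow any single global rule.

The three canonical scenarios describe a program with or without a visiting
medical resident (R) and with or without humanitarian grants and discounts
(H):

* ``model1`` — gross cost, resident included, no discounts (R, not H)
* ``model2`` — the program as actually run: resident plus discounts (R, H)
* ``model3`` — locally sustained, no resident, no discounts (not R, not H)

A fourth scenario, ``model2_no_resident`` (not R, H), can be derived from
``model2`` by zeroing the resident's travel and salary; it prices a locally
run program that keeps its humanitarian support.

All ledger arithmetic is exact integer USD; no floating point enters totals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "BUCKETS",
    "CAPITAL",
    "RECURRENT",
    "CostItem",
    "ScenarioSpec",
    "CostLedger",
    "ScenarioTotals",
    "LedgerError",
    "DEFAULT_SCENARIOS",
    "NO_RESIDENT_VARIANT",
    "load_ledger",
    "save_ledger",
    "scenario_totals",
    "bucket_subtotal",
    "cost_share",
    "bucket_shares",
    "add_no_resident_variant",
]

CAPITAL = "capital"
RECURRENT = "recurrent"

#: Spending buckets.  ``equipment`` is the only capital bucket; all others
#: are recurrent.
BUCKETS = (
    "equipment",
    "medical_supplies",
    "staff",
    "transport",
    "maintenance",
    "resident_travel",
)

_BUCKET_CATEGORY = {b: (CAPITAL if b == "equipment" else RECURRENT) for b in BUCKETS}


class LedgerError(ValueError):
    """Raised when a ledger file or ledger object violates its contract."""


@dataclass(frozen=True)
class CostItem:
    """One ledger line: a named cost with a value per scenario."""

    name: str
    category: str
    bucket: str
    values: Mapping[str, int]

    def value(self, scenario_label: str) -> int:
        try:
            return self.values[scenario_label]
        except KeyError:
            raise LedgerError(
                f"item {self.name!r} has no value for scenario {scenario_label!r}"
            ) from None


@dataclass(frozen=True)
class ScenarioSpec:
    """A funding scenario: resident involvement (R) and humanitarian aid (H)."""

    label: str
    include_resident: bool
    apply_humanitarian: bool


DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("model1", include_resident=True, apply_humanitarian=False),
    ScenarioSpec("model2", include_resident=True, apply_humanitarian=True),
    ScenarioSpec("model3", include_resident=False, apply_humanitarian=False),
)

#: Label of the derived no-resident humanitarian scenario (P−R+H).
NO_RESIDENT_VARIANT = "model2_no_resident"


@dataclass(frozen=True)
class ScenarioTotals:
    """Capital/recurrent/bucket subtotals for one scenario, integer USD."""

    label: str
    capital: int
    recurrent: int
    total: int
    by_bucket: Mapping[str, int]


def _is_resident_salary(item: CostItem) -> bool:
    # The resident's stipend sits in the staff bucket; identified by name.
    return item.bucket == "staff" and "resident" in item.name.lower()


@dataclass(frozen=True)
class CostLedger:
    """An ordered collection of cost items plus the scenarios they price.

    ``n_schools_base`` is the number of schools the ledger's costs actually
    covered (4 in the Malindi program); per-school metrics divide by it.
    """

    items: tuple[CostItem, ...]
    scenarios: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIOS
    n_schools_base: int = 4

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if not self.items:
            raise LedgerError("ledger has no items")
        if self.n_schools_base < 1:
            raise LedgerError("n_schools_base must be >= 1")
        labels = [s.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise LedgerError("duplicate scenario labels")
        seen: set[str] = set()
        for item in self.items:
            if item.name in seen:
                raise LedgerError(f"duplicate item name {item.name!r}")
            seen.add(item.name)
            if item.bucket not in BUCKETS:
                raise LedgerError(f"item {item.name!r}: unknown bucket {item.bucket!r}")
            if item.category != _BUCKET_CATEGORY[item.bucket]:
                raise LedgerError(
                    f"item {item.name!r}: bucket {item.bucket!r} implies category "
                    f"{_BUCKET_CATEGORY[item.bucket]!r}, got {item.category!r}"
                )
            for label in labels:
                v = item.value(label)
                if not isinstance(v, int) or isinstance(v, bool):
                    raise LedgerError(f"item {item.name!r}: non-integer value for {label!r}")
                if v < 0:
                    raise LedgerError(f"item {item.name!r}: negative value for {label!r}")
        self._validate_flags()

    def _validate_flags(self) -> None:
        """Check the R/H flags against the explicit per-scenario values.

        Scenarios without the resident must carry zero resident travel and
        zero resident salary; humanitarian aid may only lower an item's value
        relative to the same resident-flag scenario without it.
        """
        by_flags = {(s.include_resident, s.apply_humanitarian): s for s in self.scenarios}
        for s in self.scenarios:
            if not s.include_resident:
                for item in self.items:
                    if item.bucket == "resident_travel" or _is_resident_salary(item):
                        if item.value(s.label) != 0:
                            raise LedgerError(
                                f"scenario {s.label!r} excludes the resident but item "
                                f"{item.name!r} is nonzero"
                            )
            if s.apply_humanitarian:
                base = by_flags.get((s.include_resident, False))
                if base is not None:
                    for item in self.items:
                        if item.value(s.label) > item.value(base.label):
                            raise LedgerError(
                                f"humanitarian scenario {s.label!r} raises item "
                                f"{item.name!r} above {base.label!r}"
                            )

    # -- convenience -----------------------------------------------------

    @property
    def scenario_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.scenarios)

    def scenario(self, label: str) -> ScenarioSpec:
        for s in self.scenarios:
            if s.label == label:
                return s
        raise LedgerError(f"unknown scenario label {label!r}")

    def items_in_bucket(self, bucket: str) -> tuple[CostItem, ...]:
        if bucket not in BUCKETS:
            raise LedgerError(f"unknown bucket {bucket!r}")
        return tuple(i for i in self.items if i.bucket == bucket)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ("name", "category", "bucket")

_KNOWN_FLAGS = {s.label: (s.include_resident, s.apply_humanitarian) for s in DEFAULT_SCENARIOS}
_KNOWN_FLAGS[NO_RESIDENT_VARIANT] = (False, True)


def load_ledger(path: str | Path, n_schools_base: int = 4) -> CostLedger:
    """Read a ledger CSV (columns ``name,category,bucket,<scenario>...``).

    Scenario columns are every column after the three fixed ones; labels
    matching the canonical scenarios get their R/H flags, unknown labels
    default to the actualized-program flags (resident, humanitarian).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"name": str, "category": str, "bucket": str})
    for col in _FIXED_COLUMNS:
        if col not in df.columns:
            raise LedgerError(f"{path}: missing required column {col!r}")
    scen_cols = [c for c in df.columns if c not in _FIXED_COLUMNS]
    if not scen_cols:
        raise LedgerError(f"{path}: no scenario columns")
    items = []
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        values = {}
        for label in scen_cols:
            raw = row[label]
            try:
                v = int(raw)
                exact = float(raw) == v
            except (TypeError, ValueError):
                v, exact = 0, False
            if not exact:
                raise LedgerError(
                    f"{path} row {row_no} ({row['name']!r}): non-integer value {raw!r} "
                    f"in column {label!r}"
                )
            values[label] = v
        items.append(CostItem(str(row["name"]), str(row["category"]), str(row["bucket"]), values))
    scenarios = tuple(
        ScenarioSpec(label, *_KNOWN_FLAGS.get(label, (True, True))) for label in scen_cols
    )
    try:
        return CostLedger(tuple(items), scenarios, n_schools_base)
    except LedgerError as exc:
        raise LedgerError(f"{path}: {exc}") from None


def save_ledger(ledger: CostLedger, path: str | Path) -> None:
    """Write a ledger back out in the same CSV dialect ``load_ledger`` reads."""
    path = Path(path)
    labels = ledger.scenario_labels
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_FIXED_COLUMNS) + list(labels))
        for item in ledger.items:
            writer.writerow(
                [item.name, item.category, item.bucket] + [item.value(l) for l in labels]
            )


# ---------------------------------------------------------------------------
# Totals and shares
# ---------------------------------------------------------------------------


def _resolve(ledger: CostLedger, scenario: ScenarioSpec | str) -> ScenarioSpec:
    label = scenario if isinstance(scenario, str) else scenario.label
    return ledger.scenario(label)


def scenario_totals(ledger: CostLedger, scenario: ScenarioSpec | str) -> ScenarioTotals:
    """Exact integer capital/recurrent/bucket subtotals for one scenario."""
    spec = _resolve(ledger, scenario)
    by_bucket = {b: 0 for b in BUCKETS}
    capital = recurrent = 0
    for item in ledger.items:
        v = item.value(spec.label)
        by_bucket[item.bucket] += v
        if item.category == CAPITAL:
            capital += v
        else:
            recurrent += v
    return ScenarioTotals(spec.label, capital, recurrent, capital + recurrent, by_bucket)


def bucket_subtotal(ledger: CostLedger, scenario: ScenarioSpec | str, bucket: str) -> int:
    """Sum of item values in one bucket under one scenario."""
    if bucket not in BUCKETS:
        raise LedgerError(f"unknown bucket {bucket!r}")
    spec = _resolve(ledger, scenario)
    return sum(i.value(spec.label) for i in ledger.items if i.bucket == bucket)


def cost_share(ledger: CostLedger, scenario: ScenarioSpec | str, bucket: str) -> float:
    """Fraction of the scenario total spent in one bucket (exact, unrounded)."""
    totals = scenario_totals(ledger, scenario)
    if totals.total == 0:
        raise LedgerError(f"scenario {totals.label!r} has zero total cost")
    return bucket_subtotal(ledger, scenario, bucket) / totals.total


def bucket_shares(ledger: CostLedger, scenario: ScenarioSpec | str) -> dict[str, float]:
    """Bucket shares as one-decimal percentages (display convention)."""
    from ._round import pct1

    totals = scenario_totals(ledger, scenario)
    if totals.total == 0:
        raise LedgerError(f"scenario {totals.label!r} has zero total cost")
    return {b: pct1(totals.by_bucket[b], totals.total) for b in BUCKETS}


# ---------------------------------------------------------------------------
# Derived scenario
# ---------------------------------------------------------------------------


def add_no_resident_variant(
    ledger: CostLedger,
    base_label: str = "model2",
    label: str = NO_RESIDENT_VARIANT,
) -> CostLedger:
    """Append the no-resident humanitarian scenario (P−R+H) to a ledger.

    The derived scenario copies ``base_label`` and zeroes the resident travel
    bucket and the resident salary line — the costs that exist only because a
    visiting resident takes part.
    """
    ledger.scenario(base_label)  # raises if missing
    if label in ledger.scenario_labels:
        raise LedgerError(f"scenario label {label!r} already declared")
    new_items = []
    for item in ledger.items:
        base_value = item.value(base_label)
        if item.bucket == "resident_travel" or _is_resident_salary(item):
            base_value = 0
        new_items.append(replace(item, values={**item.values, label: base_value}))
    spec = ScenarioSpec(label, include_resident=False, apply_humanitarian=True)
    return CostLedger(tuple(new_items), ledger.scenarios + (spec,), ledger.n_schools_base)
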