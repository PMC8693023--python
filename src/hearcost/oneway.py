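"""Deterministic one-way sensitivity analysis and tornado ordering.

Each sensitivity parameter is a *bucket*: either a group of ledger spending
buckets perturbed together by a relative half-width (component kind), or a
global economic-variation factor applied to the whole total (currency
fluctuation affects every cost element at once).  One parameter is moved to
its lower/upper bound while all others stay at base, and the program total
and cost per identified case are recomputed.

The tornado ordering sorts parameters by *swing* — upper-bound total minus
lower-bound total — largest first, which is the bar order of a tornado
diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._round import round_half_away
from .effectiveness import cost_per_case
from .ledger import BUCKETS, CostLedger, ScenarioSpec, scenario_totals

__all__ = [
    "SensitivityBucket",
    "OneWayRow",
    "default_buckets",
    "one_way",
    "tornado_order",
]

COMPONENT = "component"
GLOBAL_ECONOMIC = "global_economic"


@dataclass(frozen=True)
class SensitivityBucket:
    """One sensitivity parameter.

    ``selector`` names the ledger buckets a component parameter perturbs;
    it is empty for the global economic parameter.  ``rel_halfwidth`` is the
    relative range (0.20 means +/-20%).
    """

    name: str
    kind: str
    selector: frozenset[str]
    rel_halfwidth: float

    def __post_init__(self) -> None:
        if self.kind not in (COMPONENT, GLOBAL_ECONOMIC):
            raise ValueError(f"unknown sensitivity kind {self.kind!r}")
        if not 0 <= self.rel_halfwidth < 1:
            raise ValueError("rel_halfwidth must be in [0, 1)")
        if self.kind == GLOBAL_ECONOMIC and self.selector:
            raise ValueError("global economic bucket takes no selector")
        unknown = self.selector - set(BUCKETS)
        if unknown:
            raise ValueError(f"unknown ledger buckets in selector: {sorted(unknown)}")
        if "resident_travel" in self.selector:
            raise ValueError("resident_travel is held fixed and cannot be perturbed")


@dataclass(frozen=True)
class OneWayRow:
    """Lower/base/upper totals and per-case costs for one parameter."""

    name: str
    total_lower: int
    total_base: int
    total_upper: int
    percase_lower: int
    percase_base: int
    percase_upper: int

    @property
    def swing(self) -> int:
        return self.total_upper - self.total_lower


def default_buckets(
    component_halfwidth: float = 0.20, economic_halfwidth: float = 0.05
) -> tuple[SensitivityBucket, ...]:
    """The five standard sensitivity parameters.

    Capital costs, equipment maintenance, medical supplies, and staff
    salaries plus ground transportation each vary +/-20%; the economic
    parameter varies the whole total +/-5%.  Resident travel is never
    perturbed.
    """
    return (
        SensitivityBucket("Capital Costs", COMPONENT, frozenset({"equipment"}), component_halfwidth),
        SensitivityBucket("Economic Variation", GLOBAL_ECONOMIC, frozenset(), economic_halfwidth),
        SensitivityBucket(
            "Equipment Maintenance Cost", COMPONENT, frozenset({"maintenance"}), component_halfwidth
        ),
        SensitivityBucket(
            "Staff Salaries and Ground Transportation",
            COMPONENT,
            frozenset({"staff", "transport"}),
            component_halfwidth,
        ),
        SensitivityBucket(
            "Medical Supplies", COMPONENT, frozenset({"medical_supplies"}), component_halfwidth
        ),
    )


def validate_buckets(
    buckets: Sequence[SensitivityBucket], nonzero_buckets: Iterable[str] = ()
) -> None:
    """Component selectors must be disjoint and cover every analyzed bucket."""
    seen: set[str] = set()
    for b in buckets:
        overlap = seen & b.selector
        if overlap:
            raise ValueError(f"overlapping selectors: {sorted(overlap)}")
        seen |= b.selector
    uncovered = {b for b in nonzero_buckets if b != "resident_travel"} - seen
    if uncovered:
        raise ValueError(f"nonzero ledger buckets not covered by any selector: {sorted(uncovered)}")


def one_way(
    ledger: CostLedger,
    scenario: ScenarioSpec | str,
    buckets: Sequence[SensitivityBucket] | None = None,
    *,
    n_cases: int,
) -> list[OneWayRow]:
    """One-way sensitivity rows for one scenario.

    Component parameters shift the total by ``rel_halfwidth`` times the
    perturbed buckets' base sum; the economic parameter scales the whole
    total.  Totals are rounded to the nearest dollar for display; per-case
    columns are computed from the unrounded bounds.
    """
    if buckets is None:
        buckets = default_buckets()
    totals = scenario_totals(ledger, scenario)
    nonzero = [b for b, v in totals.by_bucket.items() if v > 0]
    validate_buckets(buckets, nonzero)
    base = totals.total
    rows = []
    for b in buckets:
        if b.kind == GLOBAL_ECONOMIC:
            delta = b.rel_halfwidth * base
        else:
            delta = b.rel_halfwidth * sum(totals.by_bucket[s] for s in b.selector)
        lower, upper = base - delta, base + delta
        rows.append(
            OneWayRow(
                name=b.name,
                total_lower=round_half_away(lower),
                total_base=base,
                total_upper=round_half_away(upper),
                percase_lower=cost_per_case(lower, n_cases),
                percase_base=cost_per_case(base, n_cases),
                percase_upper=cost_per_case(upper, n_cases),
            )
        )
    return rows


def tornado_order(rows: Sequence[OneWayRow]) -> list[OneWayRow]:
    """Rows sorted by swing, largest first; ties broken alphabetically."""
    if not rows:
        raise ValueError("no rows to order")
    return sorted(rows, key=lambda r: (-r.swing, r.name))
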