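"""One-way sensitivity rows, swing arithmetic, and tornado ordering."""

import pytest

import hearcost as hc
from hearcost.oneway import COMPONENT, GLOBAL_ECONOMIC, SensitivityBucket

# Published one-way table for the no-resident scenario (totals carry the
# source's mixed rounding, hence the +/-1 USD tolerance on totals below).
PRINTED_TABLE = {
    "Capital Costs": (5831, 6783, 7735, 182, 212, 242),
    "Economic Variation": (6444, 6783, 7122, 201, 212, 223),
    "Equipment Maintenance Cost": (6513, 6783, 7052, 204, 212, 220),
    "Staff Salaries and Ground Transportation": (6684, 6783, 6882, 209, 212, 215),
    "Medical Supplies": (6746, 6783, 6819, 211, 212, 213),
}


def test_default_buckets():
    buckets = hc.default_buckets()
    assert len(buckets) == 5
    by_name = {b.name: b for b in buckets}
    assert by_name["Capital Costs"].rel_halfwidth == 0.20
    assert by_name["Economic Variation"].rel_halfwidth == 0.05
    assert by_name["Economic Variation"].kind == GLOBAL_ECONOMIC
    assert by_name["Staff Salaries and Ground Transportation"].selector == {"staff", "transport"}
    assert all(
        b.kind == COMPONENT for name, b in by_name.items() if name != "Economic Variation"
    )


def test_model3_rows_match_printed_table(malindi_ledger):
    rows = {r.name: r for r in hc.one_way(malindi_ledger, "model3", n_cases=32)}
    assert set(rows) == set(PRINTED_TABLE)
    for name, (tl, tb, tu, pl, pb, pu) in PRINTED_TABLE.items():
        r = rows[name]
        assert abs(r.total_lower - tl) <= 1
        assert r.total_base == tb
        assert abs(r.total_upper - tu) <= 1
        assert (r.percase_lower, r.percase_base, r.percase_upper) == (pl, pb, pu)
        assert r.total_lower <= r.total_base <= r.total_upper


def test_component_swing_identity(malindi_ledger):
    """Swing of a component parameter is 2 r x (bucket base sum), pre-rounding."""
    totals = hc.scenario_totals(malindi_ledger, "model3")
    rows = {r.name: r for r in hc.one_way(malindi_ledger, "model3", n_cases=32)}
    checks = {
        "Capital Costs": {"equipment"},
        "Equipment Maintenance Cost": {"maintenance"},
        "Staff Salaries and Ground Transportation": {"staff", "transport"},
        "Medical Supplies": {"medical_supplies"},
    }
    for name, selector in checks.items():
        base_sum = sum(totals.by_bucket[b] for b in selector)
        assert rows[name].swing == pytest.approx(2 * 0.20 * base_sum, abs=1)


def test_tornado_order(malindi_ledger):
    rows = hc.tornado_order(hc.one_way(malindi_ledger, "model3", n_cases=32))
    assert [r.name for r in rows] == [
        "Capital Costs",
        "Economic Variation",
        "Equipment Maintenance Cost",
        "Staff Salaries and Ground Transportation",
        "Medical Supplies",
    ]
    assert rows[0].swing == 1904
    assert rows[1].swing == 678
    assert abs(rows[2].swing - 539) <= 1
    assert rows[3].swing == 198
    assert abs(rows[4].swing - 73) <= 1


def test_tornado_tie_breaks_alphabetically():
    row = lambda name: hc.OneWayRow(name, 90, 100, 110, 9, 10, 11)
    ordered = hc.tornado_order([row("Zeta"), row("Alpha")])
    assert [r.name for r in ordered] == ["Alpha", "Zeta"]
    single = hc.tornado_order([row("Only")])
    assert [r.name for r in single] == ["Only"]


def test_zero_halfwidth_collapses(malindi_ledger):
    buckets = (
        SensitivityBucket("Capital Costs", COMPONENT, frozenset({"equipment"}), 0.0),
        SensitivityBucket("Economic Variation", GLOBAL_ECONOMIC, frozenset(), 0.0),
        SensitivityBucket("Maintenance", COMPONENT, frozenset({"maintenance"}), 0.0),
        SensitivityBucket("Staff+Transport", COMPONENT, frozenset({"staff", "transport"}), 0.0),
        SensitivityBucket("Supplies", COMPONENT, frozenset({"medical_supplies"}), 0.0),
    )
    for r in hc.one_way(malindi_ledger, "model3", buckets, n_cases=32):
        assert r.total_lower == r.total_base == r.total_upper
        assert r.swing == 0


def test_overlapping_selectors_rejected(malindi_ledger):
    buckets = hc.default_buckets() + (
        SensitivityBucket("Shadow Capital", COMPONENT, frozenset({"equipment"}), 0.1),
    )
    with pytest.raises(ValueError, match="overlapping"):
        hc.one_way(malindi_ledger, "model3", buckets, n_cases=32)


def test_uncovered_bucket_rejected(malindi_ledger):
    buckets = tuple(b for b in hc.default_buckets() if b.name != "Medical Supplies")
    with pytest.raises(ValueError, match="not covered"):
        hc.one_way(malindi_ledger, "model3", buckets, n_cases=32)


def test_resident_travel_never_perturbable():
    with pytest.raises(ValueError, match="resident_travel"):
        SensitivityBucket("Travel", COMPONENT, frozenset({"resident_travel"}), 0.2)


def test_resident_travel_held_fixed_in_model1(malindi_ledger):
    """For scenarios with the resident, travel stays at base in every row."""
    rows = hc.one_way(malindi_ledger, "model1", n_cases=32)
    travel = hc.bucket_subtotal(malindi_ledger, "model1", "resident_travel")
    base = hc.scenario_totals(malindi_ledger, "model1").total
    capital_row = next(r for r in rows if r.name == "Capital Costs")
    # the swing reflects only the equipment bucket, not the 2151 travel sum
    assert capital_row.swing == pytest.approx(2 * 0.2 * 4760, abs=1)
    assert travel == 2151
    assert capital_row.total_base == base


def test_all_zero_ledger_is_stable():
    """A ledger of zero costs yields equal columns in every row."""
    from hearcost.ledger import CostItem, CostLedger, DEFAULT_SCENARIOS

    zeros = {s.label: 0 for s in DEFAULT_SCENARIOS}
    items = tuple(
        CostItem(name, "recurrent" if bucket != "equipment" else "capital", bucket, zeros)
        for name, bucket in [
            ("Software", "equipment"),
            ("Gloves", "medical_supplies"),
            ("CHW", "staff"),
            ("Van", "transport"),
            ("Calibration", "maintenance"),
        ]
    )
    ledger = CostLedger(items)
    for r in hc.one_way(ledger, "model1", n_cases=5):
        assert r.total_lower == r.total_base == r.total_upper == 0
        assert r.percase_lower == r.percase_base == r.percase_upper == 0
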