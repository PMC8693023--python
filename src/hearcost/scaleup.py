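"""Scale-up projection: per-school cost extrapolated to a school network.

The projection assumes constant per-school cost (the four studied schools
and the remaining sub-county schools sit under the same county government,
so unit costs are taken as similar).  The Malindi sub-county has 77 primary
public schools; projecting the no-resident scenario across all of them is
the headline budget-impact figure.

Two deterministic rounding conventions are supported because published
program reports use both:

* ``results_style`` (default): truncate the per-school cost to whole
  dollars, then multiply by the target school count
  ($6,783 / 4 -> $1,695; x77 = $130,515).
* ``abstract_style``: scale the unrounded total and round once at the end
  ($6,783 x 77/4 = 130,572.75 -> $130,573).

``per_school_rounding`` can override the per-school step of
``results_style`` with nearest-dollar rounding; with the humanitarian
no-resident variant this yields the $720-per-school, $55,440 projection.

Uncertainty is propagated by scaling each Monte Carlo total draw (unrounded)
to the target school count and reading the empirical interval of the scaled
draws — rounding per-draw would bias the endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._round import round_half_away
from .effectiveness import cost_per_school
from .ledger import CostLedger, LedgerError, ScenarioSpec, scenario_totals
from .psa import PSAResult

__all__ = [
    "ScaleUpSpec",
    "ScaleUpResult",
    "scale_up",
    "scale_up_interval",
    "RESULTS_STYLE",
    "ABSTRACT_STYLE",
]

RESULTS_STYLE = "results_style"
ABSTRACT_STYLE = "abstract_style"

#: Primary public schools in the Malindi sub-county.
DEFAULT_N_SCHOOLS_TARGET = 77


@dataclass(frozen=True)
class ScaleUpSpec:
    """Target of a projection: how many schools, which scenario."""

    scenario_label: str
    n_schools_target: int = DEFAULT_N_SCHOOLS_TARGET

    def __post_init__(self) -> None:
        if self.n_schools_target < 1:
            raise ValueError("n_schools_target must be >= 1")


@dataclass(frozen=True)
class ScaleUpResult:
    """Deterministic projection, optionally with a propagated interval."""

    scenario_label: str
    n_schools_target: int
    per_school: int
    total: int
    rounding_convention: str
    interval: tuple[int, int] | None = None


def scale_up(
    ledger: CostLedger,
    spec: ScaleUpSpec,
    rounding_convention: str = RESULTS_STYLE,
    per_school_rounding: str | None = None,
) -> ScaleUpResult:
    """Deterministic scale-up of one scenario's total cost."""
    totals = scenario_totals(ledger, spec.scenario_label)
    base_n = ledger.n_schools_base
    if rounding_convention == RESULTS_STYLE:
        per_school = cost_per_school(totals.total, base_n, per_school_rounding or "truncate")
        total = per_school * spec.n_schools_target
    elif rounding_convention == ABSTRACT_STYLE:
        per_school = cost_per_school(totals.total, base_n, per_school_rounding or "nearest")
        total = round_half_away(totals.total * spec.n_schools_target / base_n)
    else:
        raise ValueError(f"unknown rounding convention {rounding_convention!r}")
    return ScaleUpResult(
        scenario_label=totals.label,
        n_schools_target=spec.n_schools_target,
        per_school=per_school,
        total=total,
        rounding_convention=rounding_convention,
    )


def scale_up_interval(
    psa_result: PSAResult,
    ledger: CostLedger,
    spec: ScaleUpSpec,
    with_range: bool = False,
):
    """Empirical interval of the scaled-up total under PSA uncertainty.

    Each Monte Carlo total draw is converted per school (unrounded) and
    multiplied by the target school count; the central interval at the PSA's
    ``interval_mass`` is read from the scaled draws.  With ``with_range``
    the observed min/max of the scaled draws is returned as well.
    """
    if psa_result.scenario_label != spec.scenario_label:
        raise LedgerError(
            f"PSA ran on scenario {psa_result.scenario_label!r} but the projection "
            f"targets {spec.scenario_label!r}"
        )
    scaled = psa_result.totals * (spec.n_schools_target / ledger.n_schools_base)
    tail = 100.0 * (1.0 - psa_result.interval_mass) / 2.0
    lo, hi = np.percentile(scaled, [tail, 100.0 - tail])
    interval = (round_half_away(float(lo)), round_half_away(float(hi)))
    if with_range:
        observed = (round_half_away(float(scaled.min())), round_half_away(float(scaled.max())))
        return interval, observed
    return interval
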