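"""Synthetic cost ledgers and screening cohorts.

Two generators let every pipeline stage be exercised without any external
data:

* :func:`simulate_cohort` draws a school cohort through the screening
  cascade — latent hearing status per child, teacher preselection, initial
  screen, diagnostic audiometry — and aggregates the counts into a
  :class:`~hearcost.effectiveness.CascadeRecord`.
* :func:`perturb_ledger` applies multiplicative noise to a template cost
  ledger, one independent uniform factor per line item, for property tests
  of the deterministic and probabilistic cost analyses.

Model of the cascade: each child carries a latent severity drawn from
``prevalence_by_severity`` (the remaining mass is normal hearing).  Teachers
preselect impaired children with probability ``preselection_sensitivity``
and exclude normal-hearing children with probability
``preselection_specificity``.  Preselected children are screened; impaired
children fail the screen with probability 1 (in the observed program every
screen failure went on to a hearing-loss diagnosis), normal-hearing children
fail with probability ``screen_fail_rate_normal`` (default 0).  Diagnostic
audiometry assigns each impaired screen-failure its latent severity.

The defaults sketch a semi-rural school pool in which teacher triage
(sensitivity 0.9 — a documented placeholder, not a measured value —
specificity 0.9) enriches a ~2.5% background hearing-loss prevalence to
roughly the one-in-five screen-failure rate the program observed; the
severity split follows the observed 23:1:2:3:3 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .effectiveness import SEVERITIES, CascadeRecord
from .ledger import BUCKETS, CostLedger, LedgerError

__all__ = [
    "CohortParams",
    "LedgerPerturbParams",
    "simulate_cohort",
    "perturb_ledger",
]

def _default_prevalence() -> dict[str, float]:
    total = 0.025
    weights = {"mild": 23, "moderate": 1, "moderately_severe": 2, "severe": 3, "profound": 3}
    scale = total / sum(weights.values())
    return {s: w * scale for s, w in weights.items()}


@dataclass(frozen=True)
class CohortParams:
    """Cohort size, teacher-triage operating characteristics, prevalence."""

    n_children: int = 1000
    preselection_sensitivity: float = 0.9
    preselection_specificity: float = 0.9
    prevalence_by_severity: Mapping[str, float] = field(default_factory=_default_prevalence)
    screen_fail_rate_normal: float = 0.0
    seed: int = 20181001

    def __post_init__(self) -> None:
        if self.n_children < 0:
            raise ValueError("n_children must be nonnegative")
        probs = [
            self.preselection_sensitivity,
            self.preselection_specificity,
            self.screen_fail_rate_normal,
            *self.prevalence_by_severity.values(),
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p!r}")
        for s in self.prevalence_by_severity:
            if s not in SEVERITIES:
                raise ValueError(f"unknown severity category {s!r}")
        if sum(self.prevalence_by_severity.values()) > 1.0 + 1e-12:
            raise ValueError("severity probabilities sum to more than 1")


@dataclass(frozen=True)
class LedgerPerturbParams:
    """Template ledger plus per-bucket relative noise half-widths."""

    template: CostLedger
    rel_noise_by_bucket: Mapping[str, float] = field(default_factory=dict)
    seed: int = 20181001

    def __post_init__(self) -> None:
        for bucket, r in self.rel_noise_by_bucket.items():
            if bucket not in BUCKETS:
                raise ValueError(f"unknown bucket {bucket!r}")
            if not 0.0 <= r < 1.0:
                raise ValueError(f"noise fraction for {bucket!r} must be in [0, 1)")


def simulate_cohort(params: CohortParams) -> CascadeRecord:
    """Draw one cohort through preselection, screening, and diagnosis."""
    rng = np.random.default_rng(params.seed)
    probs = np.array(
        [params.prevalence_by_severity.get(s, 0.0) for s in SEVERITIES] + [0.0]
    )
    probs[-1] = max(0.0, 1.0 - probs[:-1].sum())  # normal hearing
    probs /= probs.sum()
    latent = rng.choice(len(probs), size=params.n_children, p=probs)
    impaired = latent < len(SEVERITIES)

    preselect = np.where(
        impaired,
        rng.random(params.n_children) < params.preselection_sensitivity,
        rng.random(params.n_children) >= params.preselection_specificity,
    )
    screened = preselect
    fail = screened & np.where(
        impaired, True, rng.random(params.n_children) < params.screen_fail_rate_normal
    )
    # Diagnostic audiometry recovers the latent severity of impaired failures.
    severity_counts = {
        s: int(np.sum(fail & (latent == i))) for i, s in enumerate(SEVERITIES)
    }
    return CascadeRecord(
        n_screened=int(np.sum(screened)),
        n_failed_screen=int(np.sum(fail)),
        severity_counts=severity_counts,
    )


def perturb_ledger(params: LedgerPerturbParams) -> CostLedger:
    """Multiplicative noise on a template ledger, one factor per item.

    A single uniform(1-r, 1+r) factor (r from the item's bucket) multiplies
    all scenario values of an item, so cross-scenario structure — zeros for
    an absent resident, humanitarian discounts never exceeding the
    undiscounted value — survives perturbation and the result re-validates.
    """
    rng = np.random.default_rng(params.seed)
    template = params.template
    new_items = []
    for item in template.items:
        r = params.rel_noise_by_bucket.get(item.bucket, 0.0)
        factor = rng.uniform(1.0 - r, 1.0 + r) if r > 0 else 1.0
        values = {
            label: int(round(item.value(label) * factor))
            for label in template.scenario_labels
        }
        new_items.append(replace(item, values=values))
    try:
        return CostLedger(tuple(new_items), template.scenarios, template.n_schools_base)
    except LedgerError as exc:
        raise LedgerError(f"perturbed ledger violates invariants: {exc}") from None
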