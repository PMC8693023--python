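"""Screening-cascade summaries and cost-effectiveness denominators.

The screening cascade counts children at each stage: teacher-preselected and
screened, failures referred to diagnostic audiometry, and diagnosed hearing
loss by severity category (mild through profound).  "Disabling" hearing loss
is moderate or worse, the WHO convention.

Cost-effectiveness here is cost per case of newly identified hearing loss:
program total divided by the number of diagnosed children.  The default
denominator is any hearing loss; moderate-or-worse is available via
``denominator="disabling"``.

Rounding conventions (fixed, documented):

* per-case costs round half away from zero ($6,783 / 32 = 211.97 -> $212);
* per-school costs truncate toward zero by default ($6,783 / 4 = 1695.75 ->
  $1,695), with ``rounding="nearest"`` available — program reports in this
  field use both conventions, so both are first-class;
* percentages are reported to one decimal, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._round import pct1, round_half_away

__all__ = [
    "SEVERITIES",
    "DISABLING_SEVERITIES",
    "CascadeRecord",
    "EffectivenessSummary",
    "CascadeError",
    "load_cascade",
    "save_cascade",
    "summarize_cascade",
    "cost_per_case",
    "cost_per_school",
]

#: Diagnostic severity categories, mildest first.
SEVERITIES = ("mild", "moderate", "moderately_severe", "severe", "profound")

#: Moderate-or-worse categories counted as disabling hearing loss.
DISABLING_SEVERITIES = SEVERITIES[1:]


class CascadeError(ValueError):
    """Raised for invalid cascade counts or files."""


@dataclass(frozen=True)
class CascadeRecord:
    """Counts from one screening campaign.

    ``pathology_counts`` stores ear findings from video-otoscopy (cerumen
    impactions, effusions, ...); they are descriptive only and feed no cost
    metric.
    """

    n_screened: int
    n_failed_screen: int
    severity_counts: Mapping[str, int]
    pathology_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        counts = [self.n_screened, self.n_failed_screen, *self.severity_counts.values()]
        if self.pathology_counts:
            counts += list(self.pathology_counts.values())
        for c in counts:
            if not isinstance(c, int) or isinstance(c, bool) or c < 0:
                raise CascadeError(f"cascade counts must be nonnegative integers, got {c!r}")
        for k in self.severity_counts:
            if k not in SEVERITIES:
                raise CascadeError(f"unknown severity category {k!r}")
        if not (self.n_cases_any <= self.n_failed_screen <= self.n_screened):
            raise CascadeError(
                f"cascade ordering violated: sum(severities)={self.n_cases_any} "
                f"<= n_failed={self.n_failed_screen} <= n_screened={self.n_screened} required"
            )

    @property
    def n_cases_any(self) -> int:
        """Children diagnosed with any degree of hearing loss."""
        return sum(self.severity_counts.values())

    @property
    def n_cases_disabling(self) -> int:
        """Children diagnosed with moderate-or-worse hearing loss."""
        return sum(self.severity_counts.get(s, 0) for s in DISABLING_SEVERITIES)

    def n_cases(self, denominator: str = "any") -> int:
        if denominator == "any":
            return self.n_cases_any
        if denominator == "disabling":
            return self.n_cases_disabling
        raise CascadeError(f"unknown denominator {denominator!r}")


@dataclass(frozen=True)
class EffectivenessSummary:
    """Cascade percentages (on the screened denominator) and case counts."""

    n_screened: int
    n_cases_any: int
    n_cases_disabling: int
    pct_failed: float
    pct_by_severity: Mapping[str, float]
    pct_disabling: float


def load_cascade(path: str | Path) -> CascadeRecord:
    """Read a flat ``field,value`` cascade CSV.

    Recognized fields: ``n_screened``, ``n_failed_screen``, ``severity_<cat>``
    for each severity category, and optional ``pathology_<name>`` rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("field", "value"):
        if col not in df.columns:
            raise CascadeError(f"{path}: missing required column {col!r}")
    fields = dict(zip(df["field"].astype(str), df["value"]))
    try:
        n_screened = int(fields.pop("n_screened"))
        n_failed = int(fields.pop("n_failed_screen"))
    except KeyError as exc:
        raise CascadeError(f"{path}: missing field {exc}") from None
    severities = {}
    pathologies = {}
    for key, raw in fields.items():
        if key.startswith("severity_"):
            severities[key[len("severity_"):]] = int(raw)
        elif key.startswith("pathology_"):
            pathologies[key[len("pathology_"):]] = int(raw)
        else:
            raise CascadeError(f"{path}: unrecognized field {key!r}")
    return CascadeRecord(n_screened, n_failed, severities, pathologies or None)


def save_cascade(cascade: CascadeRecord, path: str | Path) -> None:
    """Write a cascade in the same flat CSV dialect ``load_cascade`` reads."""
    rows = [("n_screened", cascade.n_screened), ("n_failed_screen", cascade.n_failed_screen)]
    rows += [(f"severity_{s}", cascade.severity_counts.get(s, 0)) for s in SEVERITIES]
    if cascade.pathology_counts:
        rows += [(f"pathology_{k}", v) for k, v in cascade.pathology_counts.items()]
    pd.DataFrame(rows, columns=["field", "value"]).to_csv(path, index=False)


def summarize_cascade(cascade: CascadeRecord) -> EffectivenessSummary:
    """Cascade percentages on the screened denominator, one-decimal rounding."""
    if cascade.n_screened == 0:
        raise CascadeError("no children screened")
    n = cascade.n_screened
    return EffectivenessSummary(
        n_screened=n,
        n_cases_any=cascade.n_cases_any,
        n_cases_disabling=cascade.n_cases_disabling,
        pct_failed=pct1(cascade.n_failed_screen, n),
        pct_by_severity={s: pct1(cascade.severity_counts.get(s, 0), n) for s in SEVERITIES},
        pct_disabling=pct1(cascade.n_cases_disabling, n),
    )


def cost_per_case(total: float, n_cases: int) -> int:
    """Program cost per identified case, rounded to the nearest dollar."""
    if n_cases <= 0:
        raise CascadeError("no identified cases")
    return round_half_away(total / n_cases)


def cost_per_school(total: int, n_schools: int, rounding: str = "truncate") -> int:
    """Program cost per school covered.

    ``rounding="truncate"`` drops cents (the convention behind the $1,695 /
    $130,515 figures); ``rounding="nearest"`` rounds half away from zero (the
    convention behind the $720 / $55,440 figures).
    """
    if n_schools <= 0:
        raise CascadeError("n_schools must be positive")
    if rounding == "truncate":
        return int(total // n_schools) if total >= 0 else -int((-total) // n_schools)
    if rounding == "nearest":
        return round_half_away(total / n_schools)
    raise ValueError(f"unknown rounding convention {rounding!r}")
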