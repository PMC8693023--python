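"""Probabilistic sensitivity analysis by Monte Carlo over triangular draws.

Each uncertain cost element gets an independent triangular multiplier with
mode 1 and endpoints ``1 - r`` / ``1 + r`` (the same relative ranges the
one-way analysis uses).  Per iteration the perturbed program total is formed,
scaled by an independent global economic multiplier (mode 1, +/-5% by
default), and converted to cost per identified case.  Repeating this many
times (10,000 draws by default) yields an empirical distribution of program
cost and cost-effectiveness from which percentile intervals are read.

Granularity: by default each ledger *line item* receives its own multiplier
(``granularity="item"``); ``granularity="bucket"`` instead draws one
multiplier per sensitivity parameter and applies it to that parameter's
bucket sum.  Item-level draws average out within multi-item buckets and give
a tighter distribution; see the methods note for why it is the default.

Resident travel is never perturbed: it enters every draw at its base value,
mirroring the one-way analysis where it has no sensitivity parameter.

Per-draw per-case values are kept unrounded; rounding inside draws would
bias the interval endpoints.  Summaries round only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from ._round import round_half_away
from .effectiveness import CascadeRecord
from .ledger import CostLedger, ScenarioSpec, scenario_totals
from .oneway import (
    COMPONENT,
    GLOBAL_ECONOMIC,
    SensitivityBucket,
    default_buckets,
    validate_buckets,
)

__all__ = [
    "TriangleDist",
    "PSAConfig",
    "PSAResult",
    "sample_triangle",
    "run_psa",
    "psa_histogram",
]

#: Default Monte Carlo seed (the program ran in October 2018).
DEFAULT_SEED = 20181001


@dataclass(frozen=True)
class TriangleDist:
    """Triangular distribution on [low, high] with density peaking at mode."""

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.mode <= self.high):
            raise ValueError(
                f"triangle requires 0 < low <= mode <= high, got "
                f"({self.low}, {self.mode}, {self.high})"
            )

    @classmethod
    def symmetric(cls, rel_halfwidth: float) -> "TriangleDist":
        """Multiplier triangle with mode 1 and endpoints 1 -/+ rel_halfwidth."""
        return cls(1.0 - rel_halfwidth, 1.0, 1.0 + rel_halfwidth)


def sample_triangle(dist: TriangleDist, u):
    """Inverse-CDF transform of uniform variates ``u`` in [0, 1].

    For u below the mode's CDF value F(c) = (c-a)/(b-a):
    ``x = a + sqrt(u (b-a)(c-a))``; above it,
    ``x = b - sqrt((1-u)(b-a)(b-c))``.  Accepts scalars or arrays.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("uniform variates must lie in [0, 1]")
    a, c, b = dist.low, dist.mode, dist.high
    span = b - a
    if span == 0:
        out = np.full_like(u, a)
        return float(out) if out.ndim == 0 else out
    fc = (c - a) / span
    left = a + np.sqrt(u * span * (c - a))
    right = b - np.sqrt((1.0 - u) * span * (b - c))
    out = np.where(u < fc, left, right)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings: draw count, seed, parameter set, interval mass."""

    n_draws: int = 10_000
    seed: int = DEFAULT_SEED
    buckets: tuple[SensitivityBucket, ...] = field(default_factory=default_buckets)
    interval_mass: float = 0.95
    granularity: str = "item"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0 < self.interval_mass < 1:
            raise ValueError("interval_mass must be in (0, 1)")
        if self.granularity not in ("item", "bucket"):
            raise ValueError(f"unknown granularity {self.granularity!r}")


@dataclass(frozen=True)
class PSAResult:
    """Draw vectors (unrounded) plus whole-dollar summaries."""

    scenario_label: str
    totals: np.ndarray
    percase: np.ndarray
    n_cases: int
    n_draws: int
    seed: int
    interval_mass: float

    @property
    def mean(self) -> int:
        return round_half_away(float(np.mean(self.percase)))

    @property
    def min(self) -> int:
        return round_half_away(float(np.min(self.percase)))

    @property
    def max(self) -> int:
        return round_half_away(float(np.max(self.percase)))

    @property
    def interval(self) -> tuple[int, int]:
        lo, hi = self.percentiles(self.percase)
        return round_half_away(lo), round_half_away(hi)

    @property
    def total_interval(self) -> tuple[int, int]:
        lo, hi = self.percentiles(self.totals)
        return round_half_away(lo), round_half_away(hi)

    def percentiles(self, draws: np.ndarray) -> tuple[float, float]:
        """Unrounded empirical central interval at ``interval_mass``."""
        tail = 100.0 * (1.0 - self.interval_mass) / 2.0
        lo, hi = np.percentile(draws, [tail, 100.0 - tail])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.interval
        return {
            "scenario": self.scenario_label,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
            "ci_lower": lo,
            "ci_upper": hi,
        }


def run_psa(
    ledger: CostLedger,
    scenario: ScenarioSpec | str,
    cascade: CascadeRecord | int,
    config: PSAConfig | None = None,
) -> PSAResult:
    """Monte Carlo distribution of program total and cost per case.

    ``cascade`` may be a :class:`CascadeRecord` (its any-loss case count is
    used) or the case count itself.
    """
    if config is None:
        config = PSAConfig()
    totals = scenario_totals(ledger, scenario)
    nonzero = [b for b, v in totals.by_bucket.items() if v > 0]
    validate_buckets(config.buckets, nonzero)
    n_cases = cascade.n_cases_any if isinstance(cascade, CascadeRecord) else int(cascade)
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")

    economic = [b for b in config.buckets if b.kind == GLOBAL_ECONOMIC]
    components = [b for b in config.buckets if b.kind == COMPONENT]

    # Base values the triangles multiply: either each ledger line inside a
    # perturbed bucket (item granularity) or each parameter's bucket sum.
    if config.granularity == "item":
        unit_values = []
        unit_halfwidths = []
        for b in components:
            for item in ledger.items:
                if item.bucket in b.selector:
                    unit_values.append(item.value(totals.label))
                    unit_halfwidths.append(b.rel_halfwidth)
    else:
        unit_values = [sum(totals.by_bucket[s] for s in b.selector) for b in components]
        unit_halfwidths = [b.rel_halfwidth for b in components]

    perturbed_base = sum(unit_values)
    fixed = totals.total - perturbed_base  # resident travel + uncovered zeros

    rng = np.random.default_rng(config.seed)
    draw_totals = np.full(config.n_draws, float(fixed))
    for value, r in zip(unit_values, unit_halfwidths):
        u = rng.random(config.n_draws)
        draw_totals += value * sample_triangle(TriangleDist.symmetric(r), u)
    for b in economic:
        u = rng.random(config.n_draws)
        draw_totals *= sample_triangle(TriangleDist.symmetric(b.rel_halfwidth), u)

    return PSAResult(
        scenario_label=totals.label,
        totals=draw_totals,
        percase=draw_totals / n_cases,
        n_cases=n_cases,
        n_draws=config.n_draws,
        seed=config.seed,
        interval_mass=config.interval_mass,
    )


def psa_histogram(
    draws: np.ndarray | PSAResult, n_bins: int, which: str = "percase"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bin a draw vector for a cost histogram.

    Returns ``(counts, bin_edges, mean)``; counts sum to the number of draws
    and the mean marks the dashed reference line of the usual figure.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if isinstance(draws, PSAResult):
        draws = draws.percase if which == "percase" else draws.totals
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws to bin")
    counts, edges = np.histogram(draws, bins=n_bins)
    return counts, edges, float(np.mean(draws))
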