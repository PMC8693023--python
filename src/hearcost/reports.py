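"""Report writers: per-stage CSV/JSON exports and the full analysis bundle.

Outputs deliberately contain no timestamps, so two runs with the same
configuration produce byte-identical files; every report embeds the config
hash and the Monte Carlo seed instead.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .effectiveness import (
    CascadeRecord,
    cost_per_case,
    cost_per_school,
    load_cascade,
    summarize_cascade,
)
from .ledger import (
    CostLedger,
    add_no_resident_variant,
    bucket_shares,
    load_ledger,
    scenario_totals,
    NO_RESIDENT_VARIANT,
)
from .oneway import OneWayRow, default_buckets, one_way, tornado_order
from .psa import PSAConfig, PSAResult, run_psa
from .scaleup import ScaleUpSpec, scale_up, scale_up_interval

__all__ = [
    "totals_frame",
    "oneway_frame",
    "write_totals_report",
    "write_oneway_report",
    "write_psa_report",
    "write_histogram_csv",
    "run_report",
]


def totals_frame(ledger: CostLedger) -> pd.DataFrame:
    """Capital/recurrent/total rows, one column per scenario."""
    cols = {}
    for label in ledger.scenario_labels:
        t = scenario_totals(ledger, label)
        cols[label] = {"capital": t.capital, "recurrent": t.recurrent, "total": t.total}
    return pd.DataFrame(cols)


def oneway_frame(rows: Sequence[OneWayRow]) -> pd.DataFrame:
    """Six numeric columns plus swing, mirroring the one-way results table."""
    return pd.DataFrame(
        [
            {
                "parameter": r.name,
                "total_lower": r.total_lower,
                "total_base": r.total_base,
                "total_upper": r.total_upper,
                "percase_lower": r.percase_lower,
                "percase_base": r.percase_base,
                "percase_upper": r.percase_upper,
                "swing": r.swing,
            }
            for r in rows
        ]
    )


def write_totals_report(ledger: CostLedger, out_dir: Path, scenario: str | None = None) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = totals_frame(ledger)
    if scenario is not None:
        frame = frame[[scenario]]
    path = out_dir / "scenario_totals.csv"
    frame.to_csv(path, index_label="component")
    shares = {label: bucket_shares(ledger, label) for label in frame.columns}
    (out_dir / "bucket_shares.json").write_text(json.dumps(shares, indent=2) + "\n")
    return path


def write_oneway_report(rows: Sequence[OneWayRow], out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "oneway.csv"
    oneway_frame(rows).to_csv(path, index=False)
    order = [r.name for r in tornado_order(rows)]
    (out_dir / "tornado_order.json").write_text(json.dumps(order, indent=2) + "\n")
    return path


def write_psa_report(
    result: PSAResult, out_dir: Path, dump_draws: bool = False, n_bins: int = 30
) -> Path:
    from .psa import psa_histogram

    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"psa_{result.scenario_label}.json"
    path.write_text(json.dumps(result.summary(), indent=2) + "\n")
    counts, edges, _ = psa_histogram(result, n_bins)
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(out_dir / f"psa_{result.scenario_label}_histogram.csv", index=False)
    if dump_draws:
        pd.DataFrame({"percase": result.percase}).to_csv(
            out_dir / f"psa_{result.scenario_label}_draws.csv", index=False
        )
    return path


def write_histogram_csv(counts, edges, path: Path) -> None:
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(path, index=False)


def run_report(config: RunConfig, precise: bool = False) -> dict:
    """Run the full pipeline and write one JSON bundle plus per-stage files.

    Stages: scenario totals -> cascade effectiveness -> one-way sensitivity
    -> probabilistic sensitivity -> scale-up.  A stage failure aborts the
    run with the stage name attached.
    """
    config = config.resolved()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "hearcost_version": __version__,
        "config": {
            "scenario": config.scenario,
            "psa_draws": config.psa_draws,
            "n_schools_target": config.n_schools_target,
            "rounding_convention": config.rounding_convention,
        },
    }
    if config.psa_draws < 1000:
        bundle["note"] = "psa_draws below 1000: interval estimates carry widened Monte Carlo error"

    stage = "load"
    try:
        ledger = load_ledger(config.ledger_path)
        if NO_RESIDENT_VARIANT not in ledger.scenario_labels and "model2" in ledger.scenario_labels:
            ledger = add_no_resident_variant(ledger)
        cascade = load_cascade(config.cascade_path)

        stage = "totals"
        write_totals_report(ledger, out_dir)
        bundle["totals"] = {}
        for label in ledger.scenario_labels:
            t = scenario_totals(ledger, label)
            bundle["totals"][label] = {
                "capital": t.capital,
                "recurrent": t.recurrent,
                "total": t.total,
                "by_bucket": dict(t.by_bucket),
            }

        stage = "effectiveness"
        summary = summarize_cascade(cascade)
        n_cases = cascade.n_cases(config.denominator)
        total = scenario_totals(ledger, config.scenario).total
        bundle["effectiveness"] = {
            "n_screened": summary.n_screened,
            "n_cases_any": summary.n_cases_any,
            "n_cases_disabling": summary.n_cases_disabling,
            "pct_failed": summary.pct_failed,
            "pct_disabling": summary.pct_disabling,
            "pct_by_severity": dict(summary.pct_by_severity),
            "cost_per_case": cost_per_case(total, n_cases),
            "cost_per_school": cost_per_school(total, ledger.n_schools_base),
        }

        stage = "oneway"
        buckets = default_buckets(config.component_halfwidth, config.economic_halfwidth)
        rows = tornado_order(one_way(ledger, config.scenario, buckets, n_cases=n_cases))
        write_oneway_report(rows, out_dir)
        bundle["oneway"] = oneway_frame(rows).to_dict(orient="records")

        stage = "psa"
        psa_cfg = PSAConfig(n_draws=config.psa_draws, seed=config.seed, buckets=buckets)
        psa_result = run_psa(ledger, config.scenario, n_cases, psa_cfg)
        write_psa_report(psa_result, out_dir, dump_draws=precise)
        bundle["psa"] = psa_result.summary()

        stage = "scaleup"
        spec = ScaleUpSpec(config.scenario, config.n_schools_target)
        projection = scale_up(ledger, spec, config.rounding_convention)
        ci = scale_up_interval(psa_result, ledger, spec)
        bundle["scaleup"] = {
            "scenario": projection.scenario_label,
            "n_schools_target": projection.n_schools_target,
            "per_school": projection.per_school,
            "total": projection.total,
            "ci_lower": ci[0],
            "ci_upper": ci[1],
            "rounding_convention": projection.rounding_convention,
        }
    except Exception as exc:
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc

    (out_dir / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
    return bundle
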