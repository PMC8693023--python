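"""Synthetic cohorts and perturbed ledgers: validity, recovery, closure."""

import numpy as np
import pytest

import hearcost as hc


def observed_cohort_params(seed=20181001, n=155):
    """Everyone preselected; severity mix matching the observed 2018 cascade."""
    return hc.CohortParams(
        n_children=n,
        preselection_sensitivity=1.0,
        preselection_specificity=0.0,
        prevalence_by_severity={
            "mild": 23 / 155,
            "moderate": 1 / 155,
            "moderately_severe": 2 / 155,
            "severe": 3 / 155,
            "profound": 3 / 155,
        },
        screen_fail_rate_normal=0.0,
        seed=seed,
    )


class TestSimulateCohort:
    def test_zero_prevalence_zero_failures(self):
        params = hc.CohortParams(
            n_children=50,
            prevalence_by_severity={s: 0.0 for s in hc.SEVERITIES},
            screen_fail_rate_normal=0.0,
            preselection_specificity=0.0,
            seed=3,
        )
        record = hc.simulate_cohort(params)
        assert record.n_screened == 50
        assert record.n_failed_screen == 0
        assert record.n_cases_any == 0

    def test_fixed_seed_reproducible(self):
        a = hc.simulate_cohort(observed_cohort_params())
        b = hc.simulate_cohort(observed_cohort_params())
        assert a == b

    def test_cascade_always_valid(self):
        """Constructed records satisfy severities <= failed <= screened."""
        for seed in range(10):
            record = hc.simulate_cohort(
                hc.CohortParams(n_children=200, screen_fail_rate_normal=0.1, seed=seed)
            )
            assert record.n_cases_any <= record.n_failed_screen <= record.n_screened

    def test_emulates_observed_cascade_statistics(self):
        """With parameters matching the observed campaign the failure count sits near 32/155."""
        fails = [
            hc.simulate_cohort(observed_cohort_params(seed=s)).n_failed_screen for s in range(30)
        ]
        p = 32 / 155
        se = np.sqrt(p * (1 - p) * 155 / 30)  # SE of the mean of 30 cohorts
        assert abs(np.mean(fails) - 32) < 3 * se + 1

    def test_parameter_recovery_large_n(self):
        """At n=10,000 the screened fraction and failure rate recover the
        preselection and prevalence parameters within 3 standard errors."""
        params = hc.CohortParams(n_children=10_000, seed=11)
        record = hc.simulate_cohort(params)
        prev = sum(params.prevalence_by_severity.values())
        p_screen = params.preselection_sensitivity * prev + (
            1 - params.preselection_specificity
        ) * (1 - prev)
        se_screen = np.sqrt(p_screen * (1 - p_screen) * params.n_children)
        assert abs(record.n_screened - p_screen * params.n_children) < 3 * se_screen
        # among screened, failures = impaired (normals never fail by default)
        p_fail = params.preselection_sensitivity * prev / p_screen
        se_fail = np.sqrt(p_fail * (1 - p_fail) * record.n_screened)
        assert abs(record.n_failed_screen - p_fail * record.n_screened) < 3 * se_fail

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            hc.CohortParams(preselection_sensitivity=1.5)
        with pytest.raises(ValueError, match="sum"):
            hc.CohortParams(prevalence_by_severity={"mild": 0.8, "severe": 0.4})


class TestPerturbLedger:
    def test_zero_noise_identity(self, malindi_ledger):
        out = hc.perturb_ledger(hc.LedgerPerturbParams(malindi_ledger))
        for a, b in zip(out.items, malindi_ledger.items):
            assert dict(a.values) == dict(b.values)

    def test_capital_noise_leaves_recurrent_unchanged(self, malindi_ledger):
        out = hc.perturb_ledger(
            hc.LedgerPerturbParams(malindi_ledger, {"equipment": 0.2}, seed=5)
        )
        for label in malindi_ledger.scenario_labels:
            assert (
                hc.scenario_totals(out, label).recurrent
                == hc.scenario_totals(malindi_ledger, label).recurrent
            )

    def test_perturbed_ledgers_validate_and_keep_invariants(self, malindi_ledger):
        noise = {b: 0.2 for b in hc.BUCKETS if b != "resident_travel"}
        for seed in range(20):
            out = hc.perturb_ledger(hc.LedgerPerturbParams(malindi_ledger, noise, seed=seed))
            for label in out.scenario_labels:
                t = hc.scenario_totals(out, label)
                assert t.capital + t.recurrent == t.total

    def test_mean_total_near_template(self, malindi_ledger):
        """Law of large numbers: multiplicative noise is unbiased on average."""
        noise = {b: 0.1 for b in hc.BUCKETS}
        totals = [
            hc.scenario_totals(
                hc.perturb_ledger(hc.LedgerPerturbParams(malindi_ledger, noise, seed=s)),
                "model1",
            ).total
            for s in range(400)
        ]
        assert np.mean(totals) == pytest.approx(9839, rel=0.01)

    def test_invalid_noise_rejected(self, malindi_ledger):
        with pytest.raises(ValueError, match="noise fraction"):
            hc.LedgerPerturbParams(malindi_ledger, {"equipment": 1.0})
        with pytest.raises(ValueError, match="unknown bucket"):
            hc.LedgerPerturbParams(malindi_ledger, {"catering": 0.1})


def test_pipeline_closure_without_fixture_files():
    """Simulated cohort + perturbed ledger run the whole pipeline end to end."""
    cohort = hc.simulate_cohort(observed_cohort_params(seed=42, n=400))
    assert cohort.n_cases_any > 0
    template = hc.load_ledger(hc.packaged_fixture("malindi_2018.csv"))
    ledger = hc.perturb_ledger(
        hc.LedgerPerturbParams(template, {"equipment": 0.1, "maintenance": 0.1}, seed=42)
    )
    summary = hc.summarize_cascade(cohort)
    assert 0 <= summary.pct_failed <= 100
    total = hc.scenario_totals(ledger, "model3").total
    per_case = hc.cost_per_case(total, cohort.n_cases_any)
    rows = hc.tornado_order(hc.one_way(ledger, "model3", n_cases=cohort.n_cases_any))
    assert len(rows) == 5
    psa = hc.run_psa(
        ledger, "model3", cohort, hc.PSAConfig(n_draws=2000, seed=42)
    )
    lo, hi = psa.interval
    assert lo <= per_case <= hi
    ci = hc.scale_up_interval(psa, ledger, hc.ScaleUpSpec("model3", 77))
    assert ci[0] < hc.scale_up(ledger, hc.ScaleUpSpec("model3", 77)).total < ci[1]
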