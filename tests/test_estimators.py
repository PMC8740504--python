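import math

import numpy as np
import pytest

from refsurv import (
    RateTable,
    all_cause_cumhaz,
    crude_probabilities,
    estimate,
    expected_hazard_path,
    reference_adjusted_cumhaz,
    risk_sets,
    variance_ci,
)
from refsurv.estimators import EstimationError
from refsurv.simulate import PiecewiseHazard, SimulationSpec, StratumSpec, simulate_cohort, truth

from conftest import make_subjects
from reference_impls import ederer2_net_cumhaz, literal_series, pohar_perme_net_cumhaz


class TestAllCauseCumhaz:
    def test_nelson_aalen_hand_computation(self, tiny_cohort):
        series = all_cause_cumhaz(tiny_cohort)
        assert series.table["H"].to_numpy() == pytest.approx([1 / 3, 1 / 3 + 1 / 2], abs=1e-15)
        assert series.table["F"].to_numpy() == pytest.approx(
            [1 - math.exp(-1 / 3), 1 - math.exp(-5 / 6)], abs=1e-15
        )

    def test_no_deaths_flat(self):
        with pytest.warns(UserWarning):
            series = all_cause_cumhaz(make_subjects([1.0, 2.0], [0, 0]))
        assert series.times.size == 0
        assert series.at([5.0])["H"].iloc[0] == 0.0
        assert series.at([5.0])["F"].iloc[0] == 0.0

    def test_matches_lifelines_nelson_aalen(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        times = rng.exponential(2.0, 300) + 1e-3
        events = rng.integers(0, 2, 300)
        events[0] = 1
        series = all_cause_cumhaz(make_subjects(times, events))
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times, events)
        theirs = naf.cumulative_hazard_.loc[series.times].to_numpy().ravel()
        assert np.allclose(series.table["H"].to_numpy(), theirs, atol=1e-12)

    def test_tracks_true_cumulative_hazard(self):
        # all-dying exponential cohort: H(t) should track lambda * t
        rng = np.random.default_rng(12)
        lam = 0.5
        times = rng.exponential(1 / lam, 100)
        series = all_cause_cumhaz(make_subjects(times, [1] * 100))
        series = variance_ci(series)
        t0 = 1.5
        row = series.at([t0])
        assert abs(row["H"].iloc[0] - lam * t0) < 2 * row["se_H"].iloc[0] + 0.05


class TestReferenceAdjusted:
    def test_zero_hazard_two_subject_hand_computation(self, zero_table):
        subjects = make_subjects([1.0, 2.0], [1, 1])
        series = reference_adjusted_cumhaz(subjects, zero_table, zero_table)
        assert series.table["H_R"].to_numpy() == pytest.approx([0.5, 1.5], abs=1e-15)
        assert series.table["S_R"].iloc[-1] == pytest.approx(math.exp(-1.5), abs=1e-12)
        # zero hazards: collapse to Nelson-Aalen is exact
        na = all_cause_cumhaz(subjects)
        assert np.array_equal(series.table["H_R"].to_numpy(), na.table["H"].to_numpy())

    def test_collapse_to_nelson_aalen_with_identical_tables(self):
        cohort = _simulated_cohort(seed=2, n=300)
        table = _age_varying_table()
        series = reference_adjusted_cumhaz(cohort, table, table)
        na = all_cause_cumhaz(cohort)
        assert np.max(np.abs(series.table["H_R"].to_numpy() - na.table["H"].to_numpy())) < 1e-12

    def test_pohar_perme_matches_independent_implementation(self):
        cohort = _simulated_cohort(seed=3, n=120)
        table = _age_varying_table()
        series = reference_adjusted_cumhaz(cohort, table, mode="pohar_perme")
        ev, lam = pohar_perme_net_cumhaz(cohort, table)
        assert np.allclose(series.times, ev)
        assert np.max(np.abs(series.table["Lambda_R"].to_numpy() - lam)) < 1e-12
        assert np.all(series.table["H_R_pop"].to_numpy() == 0.0)

    def test_ederer2_matches_independent_implementation(self):
        cohort = _simulated_cohort(seed=4, n=120)
        table = _age_varying_table()
        series = reference_adjusted_cumhaz(cohort, table, mode="ederer2")
        ev, lam = ederer2_net_cumhaz(cohort, table)
        assert np.max(np.abs(series.table["Lambda_R"].to_numpy() - lam)) < 1e-12

    def test_sasieni_brentnall_drops_population_part(self):
        cohort = _simulated_cohort(seed=5, n=80)
        expected = _age_varying_table()
        reference = expected.scaled(0.5)
        sb = reference_adjusted_cumhaz(cohort, expected, reference, mode="sasieni_brentnall")
        ra = reference_adjusted_cumhaz(cohort, expected, reference, mode="reference_adjusted")
        assert np.allclose(sb.table["Lambda_R"], ra.table["Lambda_R"], atol=1e-15)
        assert np.all(sb.table["H_R_pop"].to_numpy() == 0.0)
        assert np.all(sb.table["H_R"].to_numpy() == sb.table["Lambda_R"].to_numpy())

    def test_missing_reference_table_rejected(self):
        cohort = make_subjects([1.0], [1])
        with pytest.raises(EstimationError, match="reference"):
            reference_adjusted_cumhaz(cohort, RateTable.constant(0.01), None)


class TestBruteForceOracle:
    """Small hand-built cohorts against a literal transcription of the formulas."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_quantities_match_literal_transcription(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        times = np.round(rng.uniform(0.3, 5.0, n), 3)
        events = rng.integers(0, 2, n)
        events[rng.integers(0, n)] = 1
        cohort = make_subjects(times, events, age=62.4, date=2008.7)
        for i, s in enumerate(cohort):
            s.age_at_diagnosis = 55.0 + 5 * i  # heterogeneous expected hazards
        expected = _age_varying_table()
        reference = expected.scaled(0.6)
        wB = [0.8, 1.2, 1.0, 0.9, 1.1]

        horizon = times.max() + 1e-9
        pe = [expected_hazard_path(s, expected, horizon) for s in cohort]
        pr = [expected_hazard_path(s, reference, horizon) for s in cohort]
        oracle = literal_series(cohort, pe, pr, wB)

        series = reference_adjusted_cumhaz(cohort, expected, reference, weights=np.array(wB))
        series = crude_probabilities(series, allocation="literal")
        for ours, theirs in [
            ("Lambda_R", "Lambda_R"), ("H_R_pop", "H_R_pop"),
            ("H_R", "H_R"), ("S_R", "S_R"),
            ("F_R_C", "F_C_literal"), ("F_R_O", "F_O_literal"),
        ]:
            assert np.max(np.abs(series.table[ours].to_numpy() - oracle[theirs])) < 1e-12, ours

        prop = crude_probabilities(
            reference_adjusted_cumhaz(cohort, expected, reference, weights=np.array(wB))
        )
        # proportional allocation: split of S(u-) - S(u) by increment shares
        S = prop.table["S_R"].to_numpy()
        Sprev = np.concatenate([[1.0], S[:-1]])
        dLam = np.diff(prop.table["Lambda_R"].to_numpy(), prepend=0.0)
        dPop = np.diff(prop.table["H_R_pop"].to_numpy(), prepend=0.0)
        dH = dLam + dPop
        expected_fc = np.cumsum((Sprev - S) * dLam / dH)
        assert np.allclose(prop.table["F_R_C"].to_numpy(), expected_fc, atol=1e-12)


class TestCrudeProbabilities:
    def test_zero_reference_hazard_single_cause(self, zero_table):
        cohort = _simulated_cohort(seed=6, n=150)
        table = _age_varying_table()
        series = crude_probabilities(reference_adjusted_cumhaz(cohort, table, zero_table))
        F_O = series.table["F_R_O"].to_numpy()
        assert np.max(np.abs(F_O)) < 1e-12
        assert np.allclose(
            series.table["F_R_C"], 1.0 - series.table["S_R"], atol=1e-12
        )

    def test_zero_excess_cohort_attributes_nothing_to_cancer(self):
        # all-cause mortality equals the expected rates: F_R_C ~ 0
        spec = SimulationSpec(
            n=4000,
            strata=[StratumSpec("all", 1.0, PiecewiseHazard.constant(0.0))],
            expected=0.05, reference=0.05, admin_censoring=6.0,
        )
        subs = simulate_cohort(spec, seed=21)
        series = estimate(subs, spec.expected_table, spec.reference_table,
                          mode="reference_adjusted")
        row = series.at([5.0])
        assert abs(row["F_R_C"].iloc[0]) < 3 * row["se_F_R_C"].iloc[0] + 1e-3
        target_other = 1 - math.exp(-0.25)
        assert row["F_R_O"].iloc[0] == pytest.approx(target_other, abs=0.02)

    def test_competing_risks_closed_form_recovery(self):
        # lambda=0.2, mu*=mu**=0.05: F_C(5) = 0.8(1-e^-1.25), F_O(5) = 0.2(1-e^-1.25)
        spec = SimulationSpec(
            n=6000,
            strata=[StratumSpec("all", 1.0, PiecewiseHazard.constant(0.2))],
            expected=0.05, reference=0.05, admin_censoring=6.0,
        )
        subs = simulate_cohort(spec, seed=8)
        series = estimate(subs, spec.expected_table, spec.reference_table,
                          mode="reference_adjusted")
        row = series.at([5.0])
        tr = truth(spec, [5.0])
        fc = tr.value("sample", "crude_cancer_reference", 5.0)
        fo = tr.value("sample", "crude_other_reference", 5.0)
        assert fc == pytest.approx(0.8 * (1 - math.exp(-1.25)), abs=1e-12)
        assert abs(row["F_R_C"].iloc[0] - fc) < 3 * row["se_F_R_C"].iloc[0]
        assert abs(row["F_R_O"].iloc[0] - fo) < 0.01

    def test_additivity_and_monotonicity(self):
        cohort = _simulated_cohort(seed=9, n=400)
        expected = _age_varying_table()
        series = crude_probabilities(
            reference_adjusted_cumhaz(cohort, expected, expected.scaled(0.7))
        )
        t = series.table
        assert np.max(np.abs(t["F_R_C"] + t["F_R_O"] - (1 - t["S_R"]))) < 1e-12
        for col in ("Lambda_R", "H_R_pop", "H_R", "F_R_C", "F_R_O"):
            assert np.all(np.diff(t[col].to_numpy()) >= -1e-12), col
        assert np.all((t["S_R"] >= 0) & (t["S_R"] <= 1))


class TestVarianceCI:
    def test_unweighted_variance_is_poisson_nelson_aalen(self, tiny_cohort):
        series = variance_ci(all_cause_cumhaz(tiny_cohort))
        car = risk_sets(tiny_cohort)
        expected_var = np.cumsum(car.n_deaths / car.n_at_risk.astype(float) ** 2)
        assert np.allclose(series.table["se_H"].to_numpy() ** 2, expected_var, atol=1e-15)

    def test_weights_scale_invariance(self):
        cohort = _simulated_cohort(seed=10, n=200)
        expected = _age_varying_table()
        reference = expected.scaled(0.5)
        w = np.ones(len(cohort))
        a = variance_ci(crude_probabilities(
            reference_adjusted_cumhaz(cohort, expected, reference, weights=w)))
        b = variance_ci(crude_probabilities(
            reference_adjusted_cumhaz(cohort, expected, reference, weights=2.0 * w)))
        for col in ("Lambda_R", "H_R", "S_R", "F_R_C", "se_Lambda_R", "se_F_R_C"):
            assert np.allclose(a.table[col], b.table[col], atol=1e-12), col

    def test_ci_bounds_bracket_estimate_and_respect_ranges(self):
        cohort = _simulated_cohort(seed=13, n=300)
        expected = _age_varying_table()
        series = variance_ci(crude_probabilities(
            reference_adjusted_cumhaz(cohort, expected, expected.scaled(0.8))))
        t = series.table
        inner = (t["F_R_C"] > 1e-6) & (t["F_R_C"] < 1 - 1e-6)
        assert np.all(t.loc[inner, "lo_F_R_C"] <= t.loc[inner, "F_R_C"])
        assert np.all(t.loc[inner, "hi_F_R_C"] >= t.loc[inner, "F_R_C"])
        assert np.all((t["lo_F_R_C"] >= 0) & (t["hi_F_R_C"] <= 1))
        assert np.all(t["lo_H_R"] <= t["H_R"])

    def test_level_must_be_probability(self, tiny_cohort):
        with pytest.raises(ValueError):
            variance_ci(all_cause_cumhaz(tiny_cohort), level=1.5)


class TestEstimateDriver:
    def test_observed_mode_without_tables(self, tiny_cohort):
        series = estimate(tiny_cohort, mode="observed")
        assert {"H", "F", "se_H"} <= set(series.table.columns)

    def test_merged_table_has_observed_and_adjusted_columns(self):
        cohort = _simulated_cohort(seed=14, n=100)
        table = _age_varying_table()
        series = estimate(cohort, table, table, mode="reference_adjusted")
        assert {"H", "F", "H_R", "F_R_C", "se_F_R_C", "lo_F_R_C"} <= set(series.table.columns)

    def test_report_time_before_first_event(self, tiny_cohort):
        series = estimate(tiny_cohort, mode="observed")
        row = series.at([0.5])
        assert row["H"].iloc[0] == 0.0 and row["F"].iloc[0] == 0.0

    def test_lvcf_between_event_times(self, tiny_cohort):
        series = estimate(tiny_cohort, mode="observed", level=None)
        assert series.value_at(1.5, "H") == pytest.approx(1 / 3)
        assert series.value_at(2.7, "H") == pytest.approx(5 / 6)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _age_varying_table():
    import pandas as pd

    rows = [(a, y, 0.001 * math.exp(0.06 * (a - 40))) for a in range(40, 105) for y in range(2000, 2025)]
    return RateTable.from_frame(pd.DataFrame(rows, columns=["age", "year", "rate"]))


def _simulated_cohort(seed, n):
    spec = SimulationSpec(
        n=n,
        strata=[StratumSpec("all", 1.0, PiecewiseHazard.constant(0.15), age=("uniform", 50, 85))],
        expected=0.03, reference=0.03, admin_censoring=6.0,
    )
    return simulate_cohort(spec, seed=seed)
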