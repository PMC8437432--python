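import numpy as np
import pytest

from ahba1c import (
    FitConfig,
    GapSpec,
    HbA1cMeasurement,
    HbA1cValue,
    KineticParameters,
    SimulationConfig,
    extract_sections,
    fit_subject,
    generate_subject,
    inject_gaps,
    simulate_hba1c,
    steady_state_hba1c,
    variability_score,
)
from ahba1c.errors import EligibilityError
from ahba1c.estimation import ExclusionReason, _section_residuals

from conftest import make_constant_trace, make_daily_trace

NOISELESS = dict(sensor_noise_sd=0.0, assay_noise_ngsp=0.0)


def measurements_at(trajectory, days):
    return [HbA1cMeasurement(d, trajectory.at(d)) for d in days]


class TestExtractSections:
    def test_three_visits_yield_two_sections(self, constant_trace):
        params = KineticParameters(K=5.8e-6, k_age=0.01)
        traj = simulate_hba1c(constant_trace, params, HbA1cValue(0.07))
        sections = extract_sections(
            measurements_at(traj, [0.0, 91.0, 182.0]), constant_trace
        )
        assert len(sections) == 2
        assert all(s.coverage == 1.0 for s in sections)

    def test_single_measurement_is_ineligible(self, constant_trace):
        assert extract_sections(
            [HbA1cMeasurement(0.0, HbA1cValue(0.07))], constant_trace
        ) == []

    def test_long_gap_drops_section_for_coverage(self):
        trace = make_daily_trace([150.0 + 10 * np.sin(d / 5) for d in range(91)])
        gapped = inject_gaps(trace, GapSpec(windows=((15.0, 60.0),)))
        m = [
            HbA1cMeasurement(0.0, HbA1cValue(0.07)),
            HbA1cMeasurement(91.0, HbA1cValue(0.075)),
        ]
        (section,) = extract_sections(m, gapped)
        assert section.coverage == pytest.approx(31 / 91, abs=0.02)
        assert section.exclusion is ExclusionReason.INSUFFICIENT_COVERAGE

    def test_short_gap_is_bridged_and_section_kept(self):
        trace = make_daily_trace([150.0 + 20 * np.sin(d / 3) for d in range(91)])
        gapped = inject_gaps(trace, GapSpec(windows=((40.0, 2.0),)))
        m = [
            HbA1cMeasurement(0.0, HbA1cValue(0.07)),
            HbA1cMeasurement(91.0, HbA1cValue(0.075)),
        ]
        (section,) = extract_sections(m, gapped)
        assert section.eligible


class TestVariability:
    def test_constant_glucose_scores_zero_and_is_gated(self):
        trace = make_daily_trace([150.0] * 91)
        m = [
            HbA1cMeasurement(0.0, HbA1cValue(0.07)),
            HbA1cMeasurement(91.0, HbA1cValue(0.07)),
        ]
        (section,) = extract_sections(m, trace)
        assert section.exclusion is ExclusionReason.INSUFFICIENT_VARIABILITY
        assert variability_score(section) == 0.0

    def test_alternating_days_give_two_point_sd(self):
        trace = make_daily_trace([120.0, 180.0] * 46)
        m = [
            HbA1cMeasurement(0.0, HbA1cValue(0.07)),
            HbA1cMeasurement(92.0, HbA1cValue(0.07)),
        ]
        (section,) = extract_sections(m, trace)
        assert variability_score(section) == pytest.approx(30.0)

    def test_generator_daily_sd_is_recovered(self):
        subject = generate_subject(
            SimulationConfig(n_subjects=1, seed=3, daily_sd=25.0, **NOISELESS), 0
        )
        sections = extract_sections(subject.measurements, subject.trace)
        scores = [variability_score(s) for s in sections]
        assert np.mean(scores) == pytest.approx(25.0, rel=0.25)

    def test_too_few_days_is_eligibility_error(self):
        trace = make_daily_trace([150.0])
        m = [
            HbA1cMeasurement(0.0, HbA1cValue(0.07)),
            HbA1cMeasurement(1.0, HbA1cValue(0.07)),
        ]
        (section,) = extract_sections(m, trace)
        with pytest.raises(EligibilityError):
            variability_score(section)


class TestFitSubject:
    def test_noiseless_subject_recovered_within_a_day(self):
        cfg = SimulationConfig(n_subjects=1, seed=11, **NOISELESS)
        subject = generate_subject(cfg, 0)
        # lifespans are drawn in 60-150 d; this one is interior
        assert 55 < subject.true_lifespan_days < 155
        result = fit_subject(extract_sections(subject.measurements, subject.trace))
        assert result.converged
        assert result.lifespan_days == pytest.approx(
            subject.true_lifespan_days, abs=1.0
        )

    def test_objective_at_true_parameters_is_zero(self):
        cfg = SimulationConfig(n_subjects=1, seed=5, **NOISELESS)
        subject = generate_subject(cfg, 0)
        sections = [
            s for s in extract_sections(subject.measurements, subject.trace) if s.eligible
        ]
        res = _section_residuals(sections, subject.params.k_age, subject.params.K)
        assert float(np.sum(res**2)) <= 1e-10

    def test_constant_glucose_flagged_not_fitted(self):
        trace = make_constant_trace(160.0, days=182)
        params = KineticParameters(K=5.8e-6, k_age=0.01)
        traj = simulate_hba1c(trace, params, steady_state_hba1c(5.8e-6, 160.0, 0.01))
        result = fit_subject(
            extract_sections(measurements_at(traj, [0.0, 91.0, 182.0]), trace)
        )
        assert not result.converged
        assert result.exclusion_reason is ExclusionReason.INSUFFICIENT_VARIABILITY
        assert result.params is None

    def test_out_of_bounds_true_lifespan_is_pinned_and_excluded(self):
        cfg = SimulationConfig(
            n_subjects=1, seed=2, lifespan_range_days=(40.0, 40.0), **NOISELESS
        )
        subject = generate_subject(cfg, 0)
        assert subject.true_lifespan_days == pytest.approx(40.0)
        result = fit_subject(extract_sections(subject.measurements, subject.trace))
        assert not result.converged
        assert result.exclusion_reason is ExclusionReason.LIFESPAN_OUT_OF_BOUNDS
        # pinned at (or hard against) the lower bound
        assert result.params is not None
        assert result.params.lifespan_days <= 51.0

    def test_every_result_is_converged_or_carries_a_reason(self):
        cfg = SimulationConfig(n_subjects=6, seed=9, assay_noise_ngsp=0.2)
        for i in range(cfg.n_subjects):
            subject = generate_subject(cfg, i)
            result = fit_subject(extract_sections(subject.measurements, subject.trace))
            if result.converged:
                assert 50.0 <= result.lifespan_days <= 180.0
                assert np.all(np.isfinite(result.residuals))
            else:
                assert result.exclusion_reason is not ExclusionReason.NONE

    def test_no_sections_reports_too_few_measurements(self):
        result = fit_subject([])
        assert not result.converged
        assert result.exclusion_reason is ExclusionReason.TOO_FEW_MEASUREMENTS


class TestIdentifiability:
    def test_estimator_spread_shrinks_with_between_day_variability(self):
        """Across assay-noise replicates, higher between-day glucose SD
        gives a tighter lifespan estimate (more identifiable problem)."""

        def spread(daily_sd: float) -> float:
            estimates = []
            for rep in range(8):
                cfg = SimulationConfig(
                    n_subjects=1,
                    seed=100 + rep,
                    daily_sd=daily_sd,
                    lifespan_range_days=(100.0, 100.0),
                    assay_noise_ngsp=0.05,
                    sensor_noise_sd=0.0,
                )
                subject = generate_subject(cfg, 0)
                result = fit_subject(
                    extract_sections(subject.measurements, subject.trace)
                )
                life = (
                    result.params.lifespan_days
                    if result.params is not None
                    else 180.0
                )
                estimates.append(np.clip(life, 50.0, 180.0))
            return float(np.std(estimates))

        assert spread(40.0) < spread(8.0)
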