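"""Phase-shift estimation, PRC regression, dose-response and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circaluc.resetting import (
    PhaseShiftEstimate,
    ShiftConfig,
    compare_groups,
    dose_response,
    fit_prc,
    phase_shift,
    prc_extremum,
)
from circaluc.rhythm import treatment_phase_degrees
from circaluc.synthetic import (
    OscillatorParams,
    TreatmentResponse,
    expected_shift,
    generate_cohort,
    packaged_cohort_spec,
    simulate_trace,
)
from circaluc.traces import TreatmentEvent

from conftest import constant_prc

CLEAN = OscillatorParams(noise_sd=0.0, damping_rate=0.0, duration_h=168.0)


def shifted_trace(inj, params=CLEAN, te=74.0, seed=0):
    resp = constant_prc(inj)
    return simulate_trace(params, resp, [TreatmentEvent(te, "CONST", 1e9)], seed=seed)


def fake_estimate(phase_deg, shift_h, peptide="X", dose=450.0, sample_id="s"):
    """Estimate carrying only the fields the statistics functions read."""
    tp = treatment_phase_degrees(50.0 + ((phase_deg - 90) % 360) / 360 * 24.0, 50.0, 24.0)
    return PhaseShiftEstimate(
        sample_id=sample_id, shift_h=shift_h, treatment_phase=tp,
        peptide=peptide, dose_nM=dose, pre_fit=None, post_fit=None,
    )


class TestPhaseShift:
    def test_vehicle_noiseless_is_zero(self):
        tr = simulate_trace(CLEAN, None, [TreatmentEvent(74.0, "PBS", 0.0)], seed=0)
        est = phase_shift(tr)
        assert abs(est.shift_h) < 0.05

    def test_injected_delay_recovered_noiseless(self):
        tr = shifted_trace(-4.0)
        est = phase_shift(tr)
        assert est.shift_h == pytest.approx(-4.0, abs=0.05)
        assert est.pre_fit.period_h == pytest.approx(24.0, rel=1e-3)

    def test_shift_wrapped_to_nearest_cycle(self):
        """Injecting s and s + tau produces bit-identical traces, hence
        identical (wrapped) estimates."""
        a = shifted_trace(-4.0)
        b = shifted_trace(-4.0 + 24.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-4)
        ea, eb = phase_shift(a), phase_shift(b)
        assert ea.shift_h == pytest.approx(eb.shift_h, abs=1e-3)
        assert -12.0 < ea.shift_h <= 12.0

    def test_estimator_unbiased_at_5pct_noise(self):
        """Mean error over seeded replicates within +/-0.1 h across the
        paper-scale shift range."""
        p = OscillatorParams(noise_sd=5.0, damping_rate=0.01, duration_h=180.0)
        for inj in (-8.0, -3.0, 0.0, 2.0):
            errs = []
            for seed in range(25):
                tr = shifted_trace(inj, params=p, seed=seed)
                errs.append(phase_shift(tr).shift_h - inj)
            assert abs(np.mean(errs)) < 0.1, f"bias at injected {inj}"

    def test_treatment_phase_estimated_from_pre_fit(self):
        tr = shifted_trace(-4.0)
        est = phase_shift(tr)
        true_phase = tr.ground_truth.events[0].phase_deg
        assert est.treatment_phase.degrees == pytest.approx(true_phase, abs=3.0)

    def test_insufficient_pre_cycles_raises(self):
        from circaluc.rhythm import InsufficientCyclesError
        tr = shifted_trace(-4.0, te=30.0)
        with pytest.raises(InsufficientCyclesError):
            phase_shift(tr)


class TestFitPrc:
    def test_exact_recovery_of_known_coefficients(self):
        rng = np.random.default_rng(0)
        beta = np.array([-2.5, 0.3, 4.0, -0.2, -1.5])
        phases = rng.uniform(0, 360, 40)
        phi = np.deg2rad(phases)
        shifts = (
            beta[0] + beta[1] * np.sin(phi) + beta[2] * np.cos(phi)
            + beta[3] * np.sin(2 * phi) + beta[4] * np.cos(2 * phi)
        )
        model = fit_prc(phases, shifts)
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_shifts(self):
        phases = np.arange(0, 360, 30.0)
        model = fit_prc(phases, np.zeros_like(phases))
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-12)
        assert model.r_squared is None
        assert "zero-variance" in model.flags

    def test_prediction_is_periodic(self):
        model = fit_prc(np.arange(0, 360, 24.0), np.sin(np.arange(0, 360, 24.0) / 40))
        assert model.predict(0.0) == pytest.approx(model.predict(360.0), abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="8"):
            fit_prc(np.arange(0, 350, 60.0)[:5], np.zeros(5))

    def test_clustered_phases_rejected(self):
        with pytest.raises(ValueError, match="quadrant"):
            fit_prc(np.full(10, 180.0) + np.arange(10) * 0.1, np.zeros(10))


class TestPrcExtremum:
    def test_flat_model_flagged(self):
        phases = np.arange(0, 360, 30.0)
        ext = prc_extremum(fit_prc(phases, np.zeros_like(phases)))
        assert ext.flat

    def test_pure_first_harmonic(self):
        phases = np.arange(0, 360, 15.0)
        shifts = -4.0 * np.sin(np.deg2rad(phases))
        ext = prc_extremum(fit_prc(phases, shifts))
        assert ext.phase_deg == pytest.approx(90.0, abs=1.0)
        assert ext.shift_h == pytest.approx(-4.0, abs=1e-6)

    def test_packaged_dex_biphasic_recovery(self):
        """Dexamethasone cohort: delays for early-phase treatments, advances
        for mid-phase ones."""
        from circaluc.synthetic import generate_prc_cohort, packaged_prc_cohort_spec
        from circaluc.resetting import estimate_cohort_shifts

        spec = packaged_prc_cohort_spec("DEX", dose_nM=100000.0, seed=4)
        traces = generate_prc_cohort(spec, n_phases=24)
        model = fit_prc(estimate_cohort_shifts(traces))
        early = model.predict(np.arange(20.0, 80.0, 10.0))
        mid = model.predict(np.arange(110.0, 170.0, 10.0))
        assert np.all(early < -0.5)
        assert np.all(mid > 0.5)


def anova_oneway_oracle(groups):
    """Textbook one-way ANOVA, coded independently of scipy."""
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    return (ssb / (k - 1)) / (ssw / (N - k))


class TestDoseResponse:
    def test_identical_constant_groups_no_significance(self):
        ests = [fake_estimate(190, 1.0, "GLP-1", d, f"a{d}{i}") for d in (1, 10) for i in range(5)]
        ests += [fake_estimate(190, 1.0, "PBS", 0.0, f"v{i}") for i in range(5)]
        table = dose_response(ests)
        assert table.anova["GLP-1"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert (table.table.query("peptide == 'GLP-1'")["stars"] == "ns").all()

    def test_f_statistic_matches_textbook_oracle(self):
        rng = np.random.default_rng(1)
        g1, g2, veh = rng.normal(-3, 1, 5), rng.normal(-1, 1, 5), rng.normal(0, 1, 5)
        ests = (
            [fake_estimate(190, v, "OXM", 45.0, f"a{i}") for i, v in enumerate(g1)]
            + [fake_estimate(190, v, "OXM", 450.0, f"b{i}") for i, v in enumerate(g2)]
            + [fake_estimate(190, v, "PBS", 0.0, f"v{i}") for i, v in enumerate(veh)]
        )
        table = dose_response(ests)
        assert table.anova["OXM"]["F"] == pytest.approx(
            anova_oneway_oracle([g1, g2, veh]), abs=1e-9
        )

    def test_missing_vehicle_rejected(self):
        with pytest.raises(ValueError, match="vehicle"):
            dose_response([fake_estimate(190, -1.0, "OXM", 450.0)])

    def test_strong_effect_flagged_significant(self):
        rng = np.random.default_rng(2)
        ests = [fake_estimate(190, v, "OXM", 450.0, f"a{i}")
                for i, v in enumerate(rng.normal(-8, 0.3, 5))]
        ests += [fake_estimate(190, v, "PBS", 0.0, f"v{i}")
                 for i, v in enumerate(rng.normal(0, 0.3, 5))]
        table = dose_response(ests)
        row = table.table.query("peptide == 'OXM'").iloc[0]
        assert row["stars"] == "***"

    def test_dose_monotonicity_on_hill_cohort(self):
        """|mean shift| is non-decreasing in dose up to one pooled SEM."""
        spec = packaged_cohort_spec(("OXM",), doses_nM=(1.5, 15.0, 450.0),
                                    replicates=3, seed=6)
        from circaluc.resetting import estimate_cohort_shifts

        table = dose_response(estimate_cohort_shifts(generate_cohort(spec)))
        sub = table.table.query("peptide == 'OXM'").sort_values("dose_nM")
        mags = sub["mean_shift_h"].abs().to_numpy()
        sems = sub["sem_h"].to_numpy()
        for i in range(len(mags) - 1):
            assert mags[i + 1] >= mags[i] - (sems[i] + sems[i + 1])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rep = compare_groups([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert rep.p_value > 0.05
        assert not rep.significant

    def test_complete_separation_u_zero(self):
        rep = compare_groups([1.0, 2, 3], [10.0, 11, 12], method="mann_whitney")
        assert rep.statistic == 0.0

    def test_type_one_error_calibrated(self):
        """Simulated null: rejection rate ~5% over 1000 replicates."""
        rng = np.random.default_rng(0)
        rejections = sum(
            compare_groups(rng.normal(size=8), rng.normal(size=8)).significant
            for _ in range(1000)
        )
        assert 0.02 <= rejections / 1000 <= 0.08

    def test_two_way_anova_with_bonferroni_posttests(self):
        rng = np.random.default_rng(3)
        blocks = [0, 0, 0, 60, 60, 60, 120, 120, 120]
        a = np.concatenate([rng.normal(1, 0.2, 3), rng.normal(4, 0.2, 3), rng.normal(1, 0.2, 3)])
        b = rng.normal(1, 0.2, 9)
        rep = compare_groups(a, b, method="anova2_bonferroni", design=(blocks, blocks))
        assert rep.significant
        post = rep.posttests.set_index("block")
        assert post.loc[60, "p_adj"] < 0.001
        assert post.loc[0, "p_adj"] > 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
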