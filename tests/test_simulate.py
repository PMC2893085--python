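"""Synthetic-data generator: wave forms, plates, shifts, seeding contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aralogic import (
    DiauxicScenario,
    DoseResponse,
    GradientDesign,
    IntegrationCoefficients,
    LossModel,
    NoiseModel,
    PulseParams,
    ReporterCalibration,
    RiseParams,
    arac_activity_rise,
    crp_activity_pulse,
    forward_expression,
    infer_activity,
    integrate_expression,
    loss_rate,
    repression_forward,
    simulate_diauxic_experiment,
    simulate_gradient_expression,
    simulate_gradient_plate,
)
from aralogic.io import write_plate_csv


class TestPulse:
    def test_baseline_before_onset(self):
        p = PulseParams(baseline=0.2, onset_min=40.0)
        assert crp_activity_pulse(0.0, p) == 0.2
        assert crp_activity_pulse(40.0, p) == 0.2

    def test_returns_to_baseline(self):
        p = PulseParams(baseline=0.2, amplitude=3.0, onset_min=40.0)
        assert crp_activity_pulse(2000.0, p) == pytest.approx(0.2, abs=0.002)

    def test_single_interior_maximum_in_expected_window(self):
        """Brute-force scan: exactly one local maximum, located between onset
        and onset + rise + 3*decay."""
        p = PulseParams(baseline=0.1, amplitude=2.5, onset_min=40.0,
                        rise_min=6.0, decay_min=10.0)
        t = np.linspace(0.0, 200.0, 4001)
        v = crp_activity_pulse(t, p)
        interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
        peaks = np.flatnonzero(interior) + 1
        assert len(peaks) == 1
        t_peak = t[peaks[0]]
        assert p.onset_min < t_peak < p.onset_min + p.rise_min + 3 * p.decay_min

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            crp_activity_pulse(np.nan, PulseParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PulseParams(rise_min=0.0)


class TestRise:
    def test_baseline_before_onset(self):
        p = RiseParams(baseline=0.05, onset_min=70.0)
        assert arac_activity_rise(10.0, p) == pytest.approx(0.05)

    def test_zero_rate_stays_at_baseline(self):
        p = RiseParams(baseline=0.4, rate=0.0, onset_min=10.0, ceiling=3.0)
        t = np.linspace(0, 500, 100)
        np.testing.assert_allclose(arac_activity_rise(t, p), 0.4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        rate=st.floats(0.0, 1.0),
        onset=st.floats(0.0, 100.0),
        ceiling=st.floats(0.5, 10.0),
    )
    def test_monotone_and_bounded(self, rate, onset, ceiling):
        p = RiseParams(baseline=0.1, rate=rate, onset_min=onset,
                       ceiling=max(ceiling, 0.1))
        t = np.linspace(0.0, 300.0, 301)
        v = arac_activity_rise(t, p)
        assert np.all(np.diff(v) >= -1e-12)
        assert np.all(v <= p.ceiling + 1e-12)


class TestGradientDesign:
    def test_default_is_96_wells(self, design):
        assert design.n_wells == 96

    def test_more_than_96_combinations_rejected(self):
        with pytest.raises(ValueError, match="96"):
            GradientDesign(
                arabinose_levels=tuple(np.linspace(0, 0.2, 13)),
                camp_levels=tuple(np.linspace(0, 1, 8)),
            )

    def test_negative_concentrations_rejected(self):
        with pytest.raises(ValueError):
            GradientDesign(arabinose_levels=(-0.1, 0.0))


class TestGradientPlate:
    def test_noise_free_promoter_channel_equals_forward_model(
        self, design, arabad_truth, plate_cal, noise_free
    ):
        plate, layout, truth_prof = simulate_gradient_plate(
            design, arabad_truth, plate_cal, plate_cal, noise=noise_free
        )
        expr = plate.expression()
        dose = DoseResponse()
        for well in plate.wells:
            if plate.reporter_id[well] != "araBAD":
                continue
            ara, camp = layout.condition(well)
            a, c, s = dose.activities(ara, camp)
            expected = forward_expression(float(a), float(c), float(s), arabad_truth)
            observed = expr[well].dropna()
            np.testing.assert_allclose(observed, expected, rtol=1e-9)

    def test_one_well_per_condition_per_channel(self, design, arabad_truth, plate_cal,
                                                noise_free):
        plate, layout, _ = simulate_gradient_plate(
            design, arabad_truth, plate_cal, plate_cal, noise=noise_free
        )
        counts = plate.reporter_id.value_counts()
        assert (counts == 96).all() and len(counts) == 4

    def test_same_seed_bit_identical_different_seed_differs(
        self, tmp_path, design, arabad_truth, plate_cal
    ):
        def render(seed):
            noise = NoiseModel(lum_lognormal_sigma=0.05, od_gaussian_sd=0.002,
                               seed=seed)
            plate, _, _ = simulate_gradient_plate(
                design, arabad_truth, plate_cal, plate_cal, noise=noise
            )
            path = tmp_path / f"plate_{seed}_{render.calls}.csv"
            render.calls += 1
            write_plate_csv(plate, path)
            return path.read_bytes()

        render.calls = 0
        assert render(1) == render(1)
        assert render(1) != render(2)

    def test_noise_free_reporter_channels_invert_to_truth(
        self, design, arabad_truth, plate_cal, noise_free
    ):
        """Downstream activity inference applied to the noise-free reporter
        channels recovers the generator's true activities."""
        plate, layout, truth_prof = simulate_gradient_plate(
            design, arabad_truth, plate_cal, plate_cal, noise=noise_free
        )
        expr = plate.expression()
        truth = truth_prof.to_frame()
        for i, cond_well in enumerate(truth.index):
            a_true = truth_prof.a_star[i]
            if a_true >= plate_cal.activity_cap:
                continue
            well = f"synARA:{cond_well}"
            inferred = infer_activity(float(expr[well].dropna().iloc[0]), plate_cal)
            assert inferred == pytest.approx(a_true, rel=1e-9, abs=1e-9)


class TestGradientExpression:
    def test_noise_requires_rng(self, design, arabad_truth):
        with pytest.raises(ValueError, match="rng"):
            simulate_gradient_expression(design, arabad_truth, noise_sigma=0.05)

    def test_activities_span_expected_range(self, design, arabad_truth):
        df = simulate_gradient_expression(design, arabad_truth)
        assert df["A_star"].min() == 0.0 and df["A_star"].max() <= 3.0
        assert df["C_star"].min() == 0.0 and df["C_star"].max() <= 3.0


class TestDiauxicExperiment:
    def test_seven_replicates_with_distinct_onsets(self, diauxic_dataset):
        ex = [r.exhaustion_min for r in diauxic_dataset.replicates]
        assert len(ex) == 7
        assert len(set(ex)) == 7
        peaks = [
            r.times[np.argmax(r.truth_profile.c_star)]
            for r in diauxic_dataset.replicates
        ]
        assert len(set(peaks)) > 1

    def test_constant_inputs_relax_to_basal_over_mu(self, plate_cal, noise_free):
        """Zero-amplitude pulse and zero-rate rise: production is constant,
        so expression must sit at production/mu for all time."""
        scenario = DiauxicScenario(
            crp_pulse=PulseParams(baseline=0.5, amplitude=0.0, onset_min=0.0),
            arac_rise=RiseParams(baseline=0.5, rate=0.0, onset_min=10.0),
        )
        truth = IntegrationCoefficients(alpha=2.0, gamma=4.0, basal=3.0)
        loss = LossModel(tau_min=30.0)
        ds = simulate_diauxic_experiment(
            scenario, truth, loss, plate_cal, plate_cal, noise=noise_free
        )
        mu = loss_rate(loss)
        production = forward_expression(0.5, 0.5, 1.0, truth)
        for rep in ds.replicates:
            np.testing.assert_allclose(
                rep.promoter_expression, production / mu, rtol=1e-9
            )

    def test_noise_free_self_consistency(self, diauxic_dataset):
        """Integrating the returned true activities with the generating
        coefficients reproduces the promoter channel exactly."""
        for rep in diauxic_dataset.replicates:
            b = integrate_expression(
                rep.truth_profile,
                diauxic_dataset.truth,
                diauxic_dataset.loss,
                b0=float(rep.promoter_expression[0]),
            )
            np.testing.assert_allclose(b, rep.promoter_expression, rtol=1e-12)

    def test_nonpositive_tau_rejected(self, plate_cal, arabad_truth, noise_free):
        with pytest.raises(ValueError, match="tau"):
            simulate_diauxic_experiment(
                DiauxicScenario(),
                arabad_truth,
                LossModel(tau_min=-1.0),
                plate_cal,
                plate_cal,
                noise=noise_free,
            )

    def test_seeded_determinism(self, plate_cal, arabad_truth):
        def run(seed):
            noise = NoiseModel(seed=seed)
            ds = simulate_diauxic_experiment(
                DiauxicScenario(n_replicates=3),
                arabad_truth,
                LossModel(30.0),
                plate_cal,
                plate_cal,
                noise=noise,
            )
            return np.concatenate([r.promoter_expression for r in ds.replicates])

        np.testing.assert_array_equal(run(9), run(9))
        assert not np.array_equal(run(9), run(10))
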