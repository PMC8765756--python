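"""Hippus cycle detection, phase assignment, and phase-triggered maps."""

import numpy as np
import pytest

from lcacc import synth
from lcacc.pupil_phase import (
    assign_phase,
    detect_hippus_cycles,
    fit_phase_slope,
    phase_occurrence_times,
    phase_triggered_rate_map,
    phase_triggered_rsc_map,
)


def sinusoid(period_ms=1000.0, length_ms=3000.0, phi0=np.pi, amplitude=1.0):
    t = np.arange(0.0, length_ms)
    return amplitude * np.sin(2 * np.pi * t / period_ms + phi0)


class TestCycleDetection:
    def test_noiseless_landmarks_analytic(self):
        """phi0=pi puts minima at 250+k*1000; landmarks fall at quarter
        periods between them."""
        cycles = detect_hippus_cycles(sinusoid(), 1.0, smoothing_ms=1.0)
        assert len(cycles) == 2
        assert np.allclose(cycles[0].landmarks, [250, 500, 750, 1000, 1250], atol=1.5)
        assert np.allclose(cycles[1].landmarks, [1250, 1500, 1750, 2000, 2250], atol=1.5)

    def test_flat_trace_no_cycles(self):
        assert detect_hippus_cycles(np.zeros(3000), 1.0) == []

    def test_zero_amplitude_with_noise_no_cycles(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0.0, 0.05, 3000)
        assert detect_hippus_cycles(trace, 1.0, smoothing_ms=50.0) == []

    def test_noisy_landmarks_within_30ms(self):
        rng = np.random.default_rng(1)
        trace = sinusoid() + rng.normal(0.0, 0.1, 3000)  # SNR ~ 10
        cycles = detect_hippus_cycles(trace, 1.0, smoothing_ms=100.0)
        assert len(cycles) >= 1
        target = np.array([250, 500, 750, 1000, 1250])
        err = np.abs(cycles[0].landmarks - target)
        assert err.max() <= 30

    def test_offset_invariance(self):
        """Adding a constant to the trace changes no landmark."""
        trace = sinusoid()
        c1 = detect_hippus_cycles(trace, 1.0, smoothing_ms=1.0)
        c2 = detect_hippus_cycles(trace + 17.3, 1.0, smoothing_ms=1.0)
        assert np.allclose(c1[0].landmarks, c2[0].landmarks)

    def test_periods_positive_and_ordered(self):
        cycles = detect_hippus_cycles(sinusoid(), 1.0, smoothing_ms=1.0)
        for c in cycles:
            assert np.all(np.diff(c.landmarks) > 0)
            assert c.period_ms == pytest.approx(1000.0, abs=3.0)


class TestPhaseAssignment:
    def test_landmark_phases(self):
        cycles = detect_hippus_cycles(sinusoid(), 1.0, smoothing_ms=1.0)
        phase = assign_phase(3000, cycles, 1.0)
        c = cycles[0]
        assert phase[int(c.t_max_dil_rate)] == pytest.approx(0.0, abs=1.0)
        assert phase[int(c.t_max)] == pytest.approx(90.0, abs=1.0)
        assert phase[int(c.t_max_con_rate)] == pytest.approx(180.0, abs=1.0)
        assert phase[int(c.t_min_next) - 1] == pytest.approx(270.0, abs=1.5)

    def test_linear_interpolation_midpoint(self):
        cycles = detect_hippus_cycles(sinusoid(), 1.0, smoothing_ms=1.0)
        c = cycles[0]
        phase = assign_phase(3000, cycles, 1.0)
        mid = int((c.t_max_dil_rate + c.t_max) / 2)
        assert phase[mid] == pytest.approx(45.0, abs=1.5)

    def test_undefined_outside_cycles(self):
        cycles = detect_hippus_cycles(sinusoid(), 1.0, smoothing_ms=1.0)
        phase = assign_phase(3000, cycles, 1.0)
        assert np.isnan(phase[:int(cycles[0].t_min_prev)]).all()
        assert np.isnan(phase[int(cycles[-1].t_min_next) + 1:]).all()

    def test_sawtooth_landmarks_anchor_phase(self):
        """Asymmetric cycles still hit 0/90/180/270 exactly at landmarks."""
        t = np.arange(0.0, 1000.0)
        saw = np.where(t < 700, t / 700.0, (1000 - t) / 300.0)
        trace = np.concatenate([saw, saw, saw])
        cycles = detect_hippus_cycles(trace, 1.0, smoothing_ms=20.0)
        assert cycles
        phase = assign_phase(trace.size, cycles, 1.0)
        c = cycles[0]
        assert phase[int(c.t_max)] == pytest.approx(90.0, abs=2.0)
        assert phase[int(c.t_max_con_rate)] == pytest.approx(180.0, abs=2.0)

    def test_occurrence_times_invert_phase(self):
        cycles = detect_hippus_cycles(sinusoid(), 1.0, smoothing_ms=1.0)
        occ = phase_occurrence_times(cycles, np.array([0.0, 90.0, 180.0, 270.0]))
        assert np.allclose(occ[0], [500, 750, 1000, 1250], atol=1.5)


def lc_session(seed, period_ms=600.0, lead_ms=270.0, coupling=1.0, n_trials=200):
    cfg = synth.SimConfig(
        n_trials=n_trials,
        trial_len_ms=3000.0,
        beep_fraction=0.0,
        acc_pairs=[],
        lc_rate_hz=5.0,
        lc_zero_inflation=0.0,
        lc_phase_coupling=coupling,
        lc_pupil_lead_ms=lead_ms,
        hippus=synth.HippusConfig(period_ms=period_ms),
        seed=seed,
    )
    return synth.simulate_session(cfg)[0]


class TestPhaseMapAndSlope:
    def test_slope_and_delay_recovery(self):
        """T=600, lead 270: slope ~ -360/T and zero-phase time ~ lead."""
        slopes, zts = [], []
        for seed in (0, 1):
            pm = phase_triggered_rate_map(lc_session(seed), "LC_0")
            fit = fit_phase_slope(pm, mode="peaks")
            assert fit.reliable
            slopes.append(fit.slope_deg_per_ms)
            zts.append(fit.zero_phase_time_ms)
        assert -0.66 <= np.median(slopes) <= -0.54
        assert 220 <= np.median(zts) <= 320

    @pytest.mark.parametrize("period_ms", [800.0, 1000.0])
    def test_slope_tracks_period(self, period_ms):
        pm = phase_triggered_rate_map(lc_session(3, period_ms=period_ms), "LC_0")
        fit = fit_phase_slope(pm, mode="peaks")
        assert fit.slope_deg_per_ms == pytest.approx(-360.0 / period_ms, rel=0.10)

    def test_uncoupled_map_flat(self):
        """m=0: the map's structure collapses relative to a coupled unit."""
        pm0 = phase_triggered_rate_map(lc_session(4, coupling=0.0), "LC_0", zscore=False)
        pm1 = phase_triggered_rate_map(lc_session(4, coupling=1.0), "LC_0", zscore=False)
        range0 = np.nanmax(pm0.values) - np.nanmin(pm0.values)
        range1 = np.nanmax(pm1.values) - np.nanmin(pm1.values)
        assert range0 < range1 / 2

    def test_flat_map_unreliable(self):
        """A constant map has no extremum precession: degenerate fit."""
        from lcacc.pupil_phase import PhaseMap

        offsets = np.arange(-500.0, 501.0, 100.0)
        centers = np.arange(5.0, 360.0, 10.0)
        pm = PhaseMap(
            offsets_ms=offsets,
            phase_centers_deg=centers,
            values=np.ones((offsets.size, centers.size)),
            n=np.full((offsets.size, centers.size), 100),
            quantity="zscored_rate",
        )
        fit = fit_phase_slope(pm, mode="peaks")
        assert not fit.reliable and fit.slope_deg_per_ms == 0.0

    def test_phase_coupled_pair_modulates_rsc_map(self):
        """Shared-rate modulation by pupil phase shows up in the r_sc map
        at the imposed phase."""
        spec = synth.PairSpec(
            lambda_private=3.0,
            lambda_shared=1.0,
            phase_coupling=0.8,
            phase_lead_ms=0.0,
        )
        cfg = synth.SimConfig(
            n_trials=250,
            trial_len_ms=3000.0,
            beep_fraction=0.0,
            acc_pairs=[spec],
            lc_rate_hz=2.0,
            hippus=synth.HippusConfig(period_ms=600.0),
            seed=6,
        )
        session, _ = synth.simulate_session(cfg)
        pm = phase_triggered_rsc_map(
            session,
            ("ACC_0", "ACC_1"),
            offsets_ms=np.array([0.0]),
            window_ms=300.0,
            phase_bin_deg=30.0,
        )
        row = pm.values[0]
        phases = pm.phase_centers_deg
        # shared rate peaks where cos(phase) = 1 (phase 0/360)
        near_peak = (phases < 60) | (phases > 300)
        near_trough = (phases > 120) & (phases < 240)
        assert np.nanmean(row[near_peak]) > np.nanmean(row[near_trough])
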