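"""Synthetic generator: analytic identities and determinism."""

import numpy as np
import pytest

from lcacc import synth
from lcacc.pairwise import spike_count_correlation
from lcacc.session import extract_stable_fixation_epochs
from lcacc.spike_stats import make_count_table
from scipy import stats as sps


class TestCorrelatedCounts:
    def test_common_input_identity(self):
        """Pearson r converges to lam_shared/(lam_private+lam_shared)."""
        a, b = synth.simulate_correlated_counts(5000, 4.0, 1.0, 7)
        assert abs(spike_count_correlation(a, b) - 0.2) < 0.03

    def test_no_shared_component_uncorrelated(self):
        a, b = synth.simulate_correlated_counts(5000, 4.0, 0.0, 8)
        assert abs(spike_count_correlation(a, b)) < 0.05

    def test_pure_shared_component_identical(self):
        a, b = synth.simulate_correlated_counts(100, 0.0, 3.0, 9)
        assert np.array_equal(a, b)
        assert spike_count_correlation(a, b) == pytest.approx(1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_correlated_counts(10, -1.0, 1.0, 0)

    def test_seed_reproducibility(self):
        a1, b1 = synth.simulate_correlated_counts(100, 2.0, 1.0, 5)
        a2, b2 = synth.simulate_correlated_counts(100, 2.0, 1.0, 5)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)


class TestLcSpikes:
    def test_uncoupled_counts_are_poisson(self):
        """m=0, no beep: counts in 1.1 s windows have Fano ~ 1."""
        rng = np.random.default_rng(3)
        counts = np.array(
            [
                synth.simulate_lc_spikes(1100.0, 2.0, rng, phase_coupling=0.0).size
                for _ in range(10000)
            ]
        )
        fano = counts.var(ddof=1) / counts.mean()
        assert 0.95 < fano < 1.05
        assert counts.mean() == pytest.approx(2.2, rel=0.05)

    def test_burst_present_on_responsive_trials(self):
        """P(>=1 burst spike) = 1 - exp(-burst_rate*burst_dur)."""
        rng = np.random.default_rng(4)
        ev = synth.EvokedConfig()
        hits = 0
        n = 2000
        for _ in range(n):
            t = synth.simulate_lc_spikes(
                2000.0, 0.0, rng, beep_time_ms=500.0, responsive=True, evoked=ev
            )
            hits += np.any((t >= 500.0) & (t < 500.0 + ev.burst_dur_ms))
        p_analytic = 1 - np.exp(-ev.burst_rate_hz * ev.burst_dur_ms / 1000.0)
        assert hits / n == pytest.approx(p_analytic, abs=0.01)

    def test_pause_is_silent(self):
        rng = np.random.default_rng(5)
        ev = synth.EvokedConfig()
        for _ in range(200):
            t = synth.simulate_lc_spikes(
                3000.0, 5.0, rng, beep_time_ms=500.0, responsive=True, evoked=ev
            )
            pause = (t >= 500.0 + ev.burst_dur_ms) & (
                t < 500.0 + ev.burst_dur_ms + ev.pause_dur_ms
            )
            assert not pause.any()


class TestPupil:
    def test_noiseless_sinusoid(self):
        hip = synth.HippusConfig(period_ms=600.0, amplitude=1.0, noise_sd=0.0)
        v = synth.simulate_pupil(1200.0, 0.0, hip, 0)
        t = np.arange(0.0, 1200.0)
        assert np.allclose(v, np.sin(2 * np.pi * t / 600.0))

    def test_dilation_kernel_amplitude(self):
        """Post-beep max minus pre-beep mean equals the dilation amplitude."""
        hip = synth.HippusConfig(amplitude=0.0, noise_sd=0.0)
        v = synth.simulate_pupil(
            4000.0, 0.0, hip, 0, beep_time_ms=1500.0, dilation_amp=0.5
        )
        assert v[:1500].mean() == pytest.approx(0.0)
        assert v[1500:].max() == pytest.approx(0.5, abs=1e-6)


class TestSession:
    def test_deterministic_under_seed(self):
        cfg = synth.SimConfig(n_trials=30, seed=12)
        s1, _ = synth.simulate_session(cfg)
        s2, _ = synth.simulate_session(synth.SimConfig(n_trials=30, seed=12))
        assert s1.units == s2.units
        assert s1.pupil == s2.pupil
        assert s1.trials == s2.trials

    def test_beep_count_binomial(self):
        cfg = synth.SimConfig(n_trials=400, beep_fraction=0.25, seed=13)
        _, truth = synth.simulate_session(cfg)
        sd = np.sqrt(400 * 0.25 * 0.75)
        assert abs(len(truth.beep_trials) - 100) < 3 * sd

    def test_ground_truth_delta(self):
        gate = {"zero": (2.8, 1.2), "nonzero": (3.6, 0.4)}
        cfg = synth.SimConfig(
            n_trials=10, acc_pairs=[synth.PairSpec(lc_gate=gate)], seed=1
        )
        _, truth = synth.simulate_session(cfg)
        assert truth.delta_rsc(0) == pytest.approx(-0.2)

    def test_zero_inflation_gives_many_silent_trials(self):
        """More than a third of passive-fixation (no-beep) trials carry no
        LC spike in the reference window under the default conditions."""
        cfg = synth.SimConfig(n_trials=600, seed=21)
        _, truth = synth.simulate_session(cfg)
        beep = set(truth.beep_trials)
        counts = np.array(
            [c for t, c in truth.lc_epoch_counts.items() if t not in beep]
        )
        assert (counts == 0).mean() > 1 / 3
        nonzero_rate_hz = np.median(counts[counts > 0]) / 1.1
        assert 0.9 <= nonzero_rate_hz <= 3.6

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            synth.SimConfig(n_trials=10, trial_len_ms=1500.0).validate()

    def test_marginal_rate_preserved_across_conditions(self, gated_session):
        """When the gate trades shared for private rate at fixed total,
        single-unit counts are indistinguishable across conditions."""
        session, truth = gated_session
        eps = extract_stable_fixation_epochs(session)
        no_beep = {t.trial_id for t in session.trials if t.beep_time is None}
        eps = [e for e in eps if e.trial_id in no_beep]
        tab = make_count_table(
            session, eps, 1100.0, units=[session.unit("ACC_0"), session.unit("LC_0")]
        )
        lc = tab.unit_counts("LC_0")
        acc = tab.unit_counts("ACC_0")
        p = sps.mannwhitneyu(
            acc[lc == 0], acc[lc > 0], alternative="two-sided"
        ).pvalue
        assert p > 0.01

    def test_rsc_grows_with_bin_size(self):
        """Independent scattering of the shared count makes the measured
        correlation grow toward the block-level value with bin size."""
        cfg = synth.SimConfig(
            n_trials=3000,
            beep_fraction=0.0,
            acc_pairs=[synth.PairSpec(lambda_private=3.0, lambda_shared=1.0)],
            seed=14,
        )
        session, truth = synth.simulate_session(cfg)
        eps = extract_stable_fixation_epochs(session)
        rs = {}
        for bin_ms in (275.0, 550.0, 1100.0):
            tab = make_count_table(
                session, eps, bin_ms, units=session.units_by_region("ACC")
            )
            rs[bin_ms] = spike_count_correlation(
                tab.unit_counts("ACC_0"), tab.unit_counts("ACC_1")
            )
        assert rs[275.0] < rs[550.0] < rs[1100.0]
        # linear thinning law r(b) = (b / 1100) * 0.25
        assert rs[550.0] == pytest.approx(0.125, abs=0.05)
        assert rs[1100.0] == pytest.approx(0.25, abs=0.04)
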