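"""Beep-locked analyses: PSTH, quenching, detector, pre/post contrasts."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from lcacc import synth
from lcacc.evoked import (
    EvokedDetectorParams,
    classify_evoked_lc,
    detect_fake_beep,
    detect_lc_evoked_response,
    fano_timecourse,
    median_split,
    pre_post_rsc_difference,
    psth,
    pupil_response,
    pupil_response_table,
    timecourse_rsc,
)
from lcacc.inference import bootstrap_median_ci
from lcacc.session import PupilTrace, Session, TrialRecord, UnitRecord


class TestPsth:
    def test_homogeneous_rate_recovered(self):
        rng = np.random.default_rng(0)
        spikes = {
            i: np.sort(rng.uniform(0, 2000, rng.poisson(4.0))) for i in range(500)
        }
        out = psth(spikes, {i: 1000.0 for i in range(500)}, bin_ms=100.0)
        assert np.all(np.abs(out.rate - 2.0) <= 3 * np.maximum(out.sem, 1e-9) + 0.5)

    def test_single_spike_per_trial(self):
        spikes = {i: np.array([1100.0]) for i in range(50)}
        out = psth(
            spikes, {i: 1000.0 for i in range(50)}, bin_ms=200.0, t_range=(0, 400)
        )
        assert np.allclose(out.rate, [5.0, 0.0])

    def test_no_spikes(self):
        out = psth({0: np.array([])}, {0: 500.0}, bin_ms=100.0)
        assert np.all(out.rate == 0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            psth({}, {}, 100.0)


class TestFanoTimecourse:
    def test_gain_quenching(self):
        """Across-trial gain (sd 0.4, lam 5/window) gives Fano 1.8 before
        the freeze and 1.0 after."""
        trains = synth.gain_modulated_spike_trains(
            5000, 25.0, 0.4, 0.0, (-1000, 1000), 1
        )
        ft = fano_timecourse(
            {i: t for i, t in enumerate(trains)},
            {i: 0.0 for i in range(5000)},
            window_ms=200.0,
            step_ms=200.0,
        )
        pre = ft[ft.t_center_ms <= -100].fano.mean()
        post = ft[ft.t_center_ms >= 100].fano.mean()
        assert pre == pytest.approx(1.8, rel=0.10)
        assert post == pytest.approx(1.0, rel=0.10)

    def test_pure_poisson_flat(self):
        trains = synth.gain_modulated_spike_trains(
            3000, 25.0, 0.0, 0.0, (-1000, 1000), 2
        )
        ft = fano_timecourse(
            {i: t for i, t in enumerate(trains)},
            {i: 0.0 for i in range(3000)},
        )
        assert np.nanmax(np.abs(ft.fano - 1.0)) < 0.15

    def test_deterministic_spikes_zero(self):
        spikes = {i: np.arange(-900.0, 1000.0, 100.0) for i in range(20)}
        ft = fano_timecourse(spikes, {i: 0.0 for i in range(20)})
        assert np.nanmax(ft.fano) == 0


class TestDetector:
    def test_constructed_burst_pause_responsive(self):
        spikes = np.array([1050.0, 1120.0])  # burst, then silence
        responsive, burst, pause = detect_lc_evoked_response(spikes, 1000.0)
        assert responsive and burst == 2 and pause == 0

    def test_no_spikes_not_responsive(self):
        responsive, _, _ = detect_lc_evoked_response(np.array([]), 1000.0)
        assert not responsive

    def test_pause_spike_vetoes(self):
        spikes = np.array([1050.0, 1120.0, 1500.0])
        responsive, _, pause = detect_lc_evoked_response(spikes, 1000.0)
        assert pause == 1 and not responsive

    def test_window_beyond_trial_rejected(self):
        with pytest.raises(ValueError):
            detect_lc_evoked_response(np.array([]), 1900.0, trial_end_ms=2000.0)

    def test_false_alarm_rate_matches_poisson_closed_form(self):
        """P(responsive) = P(Pois(0.6) >= 2) * P(Pois(1.0) = 0) for a
        burst-free 2 sp/s Poisson train."""
        rng = np.random.default_rng(3)
        n = 5000
        hits = 0
        for _ in range(n):
            spikes = np.sort(rng.uniform(0, 2000, rng.poisson(4.0)))
            hits += detect_lc_evoked_response(spikes, 500.0)[0]
        analytic = (1 - math.exp(-0.6) * 1.6) * math.exp(-1.0)
        sd = math.sqrt(analytic * (1 - analytic) / n)
        assert abs(hits / n - analytic) < 3 * sd


class TestFakeBeep:
    def test_inserted_bursts_detected(self):
        """Trials given the burst-pause kernel at a known time are flagged
        by the fake-beep detector with hit rate >= 0.95."""
        rng = np.random.default_rng(4)
        hits = 0
        n = 200
        for _ in range(n):
            virtual_rng = np.random.default_rng(7)
            probe = detect_fake_beep(np.array([]), 200.0, 4000.0, virtual_rng)[0]
            spikes = synth.simulate_lc_spikes(
                4000.0, 2.0, rng, beep_time_ms=probe, responsive=True
            )
            _, responsive, _, _ = detect_fake_beep(
                spikes, 200.0, 4000.0, np.random.default_rng(7)
            )
            hits += responsive
        assert hits / n >= 0.95

    def test_virtual_times_deterministic(self):
        spikes = np.arange(0.0, 4000.0, 400.0)
        t1 = detect_fake_beep(spikes, 200.0, 4000.0, seed=9)[0]
        t2 = detect_fake_beep(spikes, 200.0, 4000.0, seed=9)[0]
        assert t1 == t2
        assert 1200.0 <= t1 <= 1700.0

    def test_too_short_trial_rejected(self):
        with pytest.raises(ValueError):
            detect_fake_beep(np.array([]), 200.0, 1500.0, seed=0)


@pytest.fixture(scope="module")
def prepost_session():
    gate = {
        "pre": (3.5, 0.5),
        "post_responsive": (2.5, 1.5),
        "post_nonresponsive": (3.5, 0.5),
    }
    cfg = synth.SimConfig(
        n_trials=400,
        beep_fraction=0.5,
        acc_pairs=[synth.PairSpec(evoked_gate=gate) for _ in range(40)],
        seed=55,
    )
    return synth.simulate_session(cfg)


class TestPrePostRsc:
    def test_step_recovery_and_null_groups(self, prepost_session):
        session, truth = prepost_session
        tm = session.trial_map()
        responsive = set(truth.responsive_trials)
        events = {t: tm[t].beep_time for t in truth.beep_trials}
        groups = {
            "responsive": sorted(responsive),
            "nonresponsive": sorted(set(truth.beep_trials) - responsive),
        }
        per_pair, contrast = pre_post_rsc_difference(
            session, truth.pair_units, events, groups, np.array([1000.0])
        )
        d_resp = per_pair.loc[
            per_pair.group == "responsive", "delta_rsc"
        ].dropna().to_numpy()
        d_non = per_pair.loc[
            per_pair.group == "nonresponsive", "delta_rsc"
        ].dropna().to_numpy()
        assert bootstrap_median_ci(d_resp, seed=0).covers(0.25)
        assert bootstrap_median_ci(d_non, seed=0).covers(0.0)
        assert contrast.ranksum_p.iloc[0] < 0.01

    def test_fake_beep_contrast_null(self, prepost_session):
        session, truth = prepost_session
        cls = classify_evoked_lc(session, "LC_0", seed=11)
        fakes = cls[~cls.is_beep]
        events = {int(r.trial_id): r.event_time_ms for r in fakes.itertuples()}
        groups = {
            "responsive": fakes[fakes.responsive].trial_id.tolist(),
            "nonresponsive": fakes[~fakes.responsive].trial_id.tolist(),
        }
        _, contrast = pre_post_rsc_difference(
            session, truth.pair_units, events, groups, np.array([1000.0])
        )
        assert contrast.ranksum_p.iloc[0] > 0.05


class TestPupilResponse:
    def test_constructed_kernel(self):
        values = np.concatenate([np.zeros(1000), np.linspace(0, 0.5, 500),
                                 np.full(1500, 0.25)])
        baseline, amp = pupil_response(values, 1.0, 1000.0)
        assert baseline == pytest.approx(0.0)
        assert amp == pytest.approx(0.5)

    def test_flat_trace(self):
        baseline, amp = pupil_response(np.full(4000, 3.0), 1.0, 1500.0)
        assert baseline == pytest.approx(3.0) and amp == pytest.approx(0.0)

    def test_insufficient_trace_rejected(self):
        with pytest.raises(ValueError):
            pupil_response(np.zeros(100), 1.0, 50.0)

    def test_burst_size_couples_to_dilation(self, prepost_session):
        session, truth = prepost_session
        tm = session.trial_map()
        events = {t: tm[t].beep_time for t in truth.beep_trials}
        table = pupil_response_table(session, events)
        cls = classify_evoked_lc(session, "LC_0", seed=12)
        merged = table.merge(
            cls[["trial_id", "burst_count"]], on="trial_id"
        )
        rho, p = sps.spearmanr(merged.burst_count, merged.evoked_amp)
        assert rho > 0 and p < 0.01

    def test_median_split_balanced(self):
        labels = median_split(np.random.default_rng(0).normal(size=101))
        assert abs(labels.sum() - (~labels).sum()) <= 1


class TestTimecourse:
    def test_responsive_group_rises_faster(self, prepost_session):
        """The event-locked shared-rate step drives a steeper early r_sc
        slope in the responsive group."""
        session, truth = prepost_session
        tm = session.trial_map()
        responsive = set(truth.responsive_trials)
        align = {t: tm[t].beep_time for t in truth.beep_trials}
        groups = {
            "responsive": sorted(responsive),
            "nonresponsive": sorted(set(truth.beep_trials) - responsive),
        }
        series, bin_tests, slopes = timecourse_rsc(
            session,
            truth.pair_units,
            align,
            groups,
            t_range=(-1000.0, 1000.0),
            slope_epoch_ms=(-200.0, 300.0),
        )
        comparison = slopes[slopes.group == "nonresponsive_vs_responsive"]
        assert not comparison.empty
        assert comparison.ranksum_p.iloc[0] < 0.05
        med = slopes[slopes.pair_a != ""].groupby("group").slope_per_ms.median()
        assert med["responsive"] > med["nonresponsive"]

    def test_stationary_generator_false_positive_rate(self):
        """Uniform correlation structure across the trial: per-bin tests vs
        baseline flag at most a modest false-positive fraction."""
        flat_gate = {
            "pre": (3.0, 1.0),
            "post_responsive": (3.0, 1.0),
            "post_nonresponsive": (3.0, 1.0),
        }
        cfg = synth.SimConfig(
            n_trials=200,
            beep_fraction=0.0,
            acc_pairs=[synth.PairSpec(evoked_gate=flat_gate) for _ in range(20)],
            seed=77,
        )
        session, truth = synth.simulate_session(cfg)
        # random per-trial alignment so windows sample all phases of the
        # generator's internal block structure equally in every bin
        rng = np.random.default_rng(78)
        align = {
            t.trial_id: t.stable_fix_on + rng.uniform(500.0, 1500.0)
            for t in session.trials
        }
        groups = {"all": [t.trial_id for t in session.trials]}
        _, bin_tests, _ = timecourse_rsc(
            session,
            truth.pair_units,
            align,
            groups,
            t_range=(-500.0, 1100.0),
            baseline_range_ms=(-500.0, 0.0),
        )
        post = bin_tests[bin_tests.t_center_ms >= 0].dropna(subset=["p_vs_baseline"])
        assert (post.p_vs_baseline < 0.05).mean() <= 0.25

    def test_elevated_prefix_declines(self):
        """A pair whose shared rate is high early in the trial and lower
        later shows the corresponding r_sc decline when aligned to the
        transition."""
        rng = np.random.default_rng(8)
        n_trials = 300
        trials = [
            TrialRecord(trial_id=i, fix_on=0.0, stable_fix_on=200.0, trial_end=3000.0)
            for i in range(n_trials)
        ]
        ua = UnitRecord(unit_id="ACC_0", region="ACC")
        ub = UnitRecord(unit_id="ACC_1", region="ACC")
        for i in range(n_trials):
            a1, b1 = synth._correlated_block(2.0, 2.0, 0.0, 1000.0, rng)
            a2, b2 = synth._correlated_block(3.5, 0.5, 1000.0, 2000.0, rng)
            ua.spikes[i] = np.sort(np.concatenate([a1, a2]))
            ub.spikes[i] = np.sort(np.concatenate([b1, b2]))
        session = Session(
            session_id="prefix", units=[ua, ub], trials=trials, pupil=PupilTrace()
        ).validate()
        align = {i: 1000.0 for i in range(n_trials)}
        series, _, _ = timecourse_rsc(
            session,
            [("ACC_0", "ACC_1")],
            align,
            {"all": list(range(n_trials))},
            t_range=(-1000.0, 1500.0),
        )
        early = series[series.t_center_ms <= -250].r.mean()
        late = series[series.t_center_ms >= 500].r.mean()
        assert early > late
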