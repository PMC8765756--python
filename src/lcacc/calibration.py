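"""Calibration suite: parameter-recovery experiments with analytic oracles.

Each function runs one canonical experiment on synthetic data whose target
value is known in closed form — the common-input correlation identity, the
conditioned-correlation difference, the shuffle null, Poisson and
gain-quenched Fano factors, pupil-phase slope/delay recovery, evoked-LC
detector calibration, pre/post correlation contrasts, and the exactness /
null uniformity of the nonparametric tests — and returns the measured
numbers together with the analytic targets.  They are used both by the test
suite and by the reproduction script.

All randomness is derived from a single integer seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from . import synth
from .evoked import (
    EvokedDetectorParams,
    classify_evoked_lc,
    detect_lc_evoked_response,
    fano_timecourse,
    pre_post_rsc_difference,
)
from .inference import bootstrap_median_ci, ranksum_test, signrank_test
from .pairwise import conditioned_rsc, shuffled_null, spike_count_correlation
from .pupil_phase import fit_phase_slope, phase_triggered_rate_map
from .session import extract_stable_fixation_epochs
from .spike_stats import make_count_table, partition_trials_by_partner

__all__ = [
    "common_input_identity",
    "conditioned_delta_recovery",
    "evoked_detector_calibration",
    "fano_calibration",
    "phase_delay_recovery",
    "prepost_contrast_recovery",
    "shuffle_null_calibration",
    "test_exactness_and_uniformity",
]


def _child_seed(seed: int, k: int) -> int:
    return int((seed * 1000003 + k) % 2**31)


def common_input_identity(
    seed: int,
    n_pairs: int = 100,
    n_trials: int = 5000,
    lam_private: float = 4.0,
    lam_shared: float = 1.0,
) -> dict[str, float]:
    """Median empirical correlation of common-input pairs vs the analytic
    identity r = lam_shared / (lam_private + lam_shared)."""
    rng = np.random.default_rng(_child_seed(seed, 1))
    rs = []
    for _ in range(n_pairs):
        a, b = synth.simulate_correlated_counts(n_trials, lam_private, lam_shared, rng)
        rs.append(spike_count_correlation(a, b))
    return {
        "median_r": float(np.median(rs)),
        "target_r": synth.PairSpec.rsc(lam_private, lam_shared),
        "n_pairs": n_pairs,
        "n_trials": n_trials,
    }


def _gated_session(
    seed: int, n_pairs: int, n_trials: int
) -> tuple[synth.SimConfig, object, object]:
    gate = {"zero": (2.8, 1.2), "nonzero": (3.6, 0.4)}
    cfg = synth.SimConfig(
        n_trials=n_trials,
        acc_pairs=[synth.PairSpec(lc_gate=gate) for _ in range(n_pairs)],
        seed=_child_seed(seed, 2),
    )
    return (cfg, *synth.simulate_session(cfg))


def _conditioned_diffs(session, truth, shuffle_trials_seed: int | None = None):
    epochs = extract_stable_fixation_epochs(session)
    no_beep = {t.trial_id for t in session.trials if t.beep_time is None}
    epochs = [e for e in epochs if e.trial_id in no_beep]
    lc_tab = make_count_table(
        session, epochs, 1100.0, units=session.units_by_region("LC")
    )
    labels = partition_trials_by_partner(
        lc_tab.unit_counts("LC_0"), lc_tab.trial_ids
    )
    acc_tab = make_count_table(
        session, epochs, 1100.0, units=session.units_by_region("ACC")
    )
    if shuffle_trials_seed is not None:
        from .pairwise import shuffle_count_table

        acc_tab = shuffle_count_table(acc_tab, shuffle_trials_seed)
    _, diffs = conditioned_rsc(
        [acc_tab], truth.pair_units, labels, conditions=("all", "zero", "nonzero")
    )
    return labels, acc_tab, diffs


def conditioned_delta_recovery(
    seed: int, n_pairs: int = 100, n_trials: int = 400
) -> dict[str, float]:
    """Recover the analytic conditioned-correlation difference.

    The shared rate is gated on realized LC spiking (1.2 vs 0.4 with the
    total rate fixed at 4), so the pipeline's median (nonzero - zero) delta
    should recover -0.2 while mean counts stay condition-independent.
    """
    _, session, truth = _gated_session(seed, n_pairs, n_trials)
    _, _, diffs = _conditioned_diffs(session, truth)
    delta = diffs.delta_rsc.dropna().to_numpy()
    ci = bootstrap_median_ci(delta, seed=_child_seed(seed, 3))
    target = truth.delta_rsc(0)

    # marginal-rate preservation at large n: one pair, rank-sum across trials
    _, big_session, big_truth = _gated_session(seed + 7919, 1, 5000)
    labels, acc_tab, _ = _conditioned_diffs(big_session, big_truth)
    zero_ids = set(labels.trials_in("zero"))
    mask = np.isin(acc_tab.trial_ids, list(zero_ids))
    counts = acc_tab.unit_counts("ACC_0")
    rate_p = ranksum_test(counts[mask], counts[~mask]).p_value

    return {
        "median_delta": float(np.median(delta)),
        "ci_lower": ci.lower,
        "ci_upper": ci.upper,
        "covers_target": float(ci.covers(target)),
        "target_delta": target,
        "rate_ranksum_p": rate_p,
        "n_pairs": n_pairs,
        "n_trials": n_trials,
    }


def shuffle_null_calibration(
    seed: int,
    n_trials: int = 1000,
    n_shuffles: int = 1000,
    n_pairs: int = 50,
    n_session_trials: int = 400,
) -> dict[str, float]:
    """Trial shuffling destroys pairing: null mean ~0, and the conditioned
    analysis re-run on trial-shuffled count vectors yields a delta whose
    CI covers 0."""
    rng = np.random.default_rng(_child_seed(seed, 4))
    a, b = synth.simulate_correlated_counts(n_trials, 4.0, 1.0, rng)
    null = shuffled_null(a, b, n_shuffles, rng)
    _, session, truth = _gated_session(seed + 104729, n_pairs, n_session_trials)
    _, _, diffs = _conditioned_diffs(
        session, truth, shuffle_trials_seed=_child_seed(seed, 5)
    )
    delta = diffs.delta_rsc.dropna().to_numpy()
    ci = bootstrap_median_ci(delta, seed=_child_seed(seed, 6))
    return {
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "expected_sd": 1.0 / math.sqrt(n_trials - 1),
        "shuffled_delta_median": float(np.median(delta)),
        "shuffled_delta_ci_lower": ci.lower,
        "shuffled_delta_ci_upper": ci.upper,
        "shuffled_delta_covers_zero": float(ci.covers(0.0)),
        "n_shuffles": n_shuffles,
        "n_trials": n_trials,
    }


def fano_calibration(
    seed: int,
    n_poisson: int = 10000,
    n_gain: int = 5000,
    lam_per_window: float = 5.0,
    gain_sd: float = 0.4,
) -> dict[str, float]:
    """Fano factor oracles: 1 for the Poisson spike generator; quenching
    from 1 + lam*sd^2 to 1 when the across-trial gain freezes."""
    rng = np.random.default_rng(_child_seed(seed, 7))
    counts = np.empty(n_poisson)
    for i in range(n_poisson):
        t = synth.simulate_lc_spikes(1100.0, 2.0, rng, phase_coupling=0.0)
        counts[i] = t.size
    fano_poisson = counts.var(ddof=1) / counts.mean()

    window = 200.0
    rate_hz = lam_per_window / (window / 1000.0)
    trains = synth.gain_modulated_spike_trains(
        n_gain, rate_hz, gain_sd, 0.0, (-1000.0, 1000.0), rng
    )
    ft = fano_timecourse(
        {i: t for i, t in enumerate(trains)},
        {i: 0.0 for i in range(n_gain)},
        window_ms=window,
        step_ms=200.0,
    )
    pre = float(ft[ft.t_center_ms <= -window / 2].fano.mean())
    post = float(ft[ft.t_center_ms >= window / 2].fano.mean())
    return {
        "fano_poisson": float(fano_poisson),
        "fano_pre_gain": pre,
        "fano_post_freeze": post,
        "target_pre": 1.0 + lam_per_window * gain_sd**2,
        "target_post": 1.0,
        "n_poisson": n_poisson,
        "n_gain": n_gain,
    }


def phase_delay_recovery(
    seed: int,
    n_seeds: int = 20,
    period_ms: float = 600.0,
    lead_ms: float = 270.0,
    n_trials: int = 300,
) -> dict[str, float]:
    """Fit phase-precession lines to phase-triggered LC rate maps across
    seeded simulations; slope should recover -360/T and the zero-phase
    time the imposed LC-to-pupil lead."""
    slopes, zero_times = [], []
    for k in range(n_seeds):
        cfg = synth.SimConfig(
            n_trials=n_trials,
            trial_len_ms=3000.0,
            beep_fraction=0.0,
            acc_pairs=[],
            lc_rate_hz=2.0,
            lc_zero_inflation=0.0,
            lc_phase_coupling=1.0,
            lc_pupil_lead_ms=lead_ms,
            hippus=synth.HippusConfig(period_ms=period_ms),
            seed=_child_seed(seed, 100 + k),
        )
        session, _ = synth.simulate_session(cfg)
        pm = phase_triggered_rate_map(
            session, "LC_0", offsets_ms=np.arange(-1000.0, 1001.0, 100.0)
        )
        fit = fit_phase_slope(pm, mode="peaks")
        slopes.append(fit.slope_deg_per_ms)
        zero_times.append(fit.zero_phase_time_ms)
    return {
        "median_slope": float(np.median(slopes)),
        "median_zero_phase_time": float(np.median(zero_times)),
        "target_slope": -360.0 / period_ms,
        "target_zero_phase_time": lead_ms,
        "n_seeds": n_seeds,
        "n_trials": n_trials,
    }


def evoked_detector_calibration(
    seed: int,
    n_null: int = 10000,
    n_burst: int = 1000,
    base_rate_hz: float = 2.0,
) -> dict[str, float]:
    """Detector false-alarm rate on burst-free Poisson trials vs the
    Poisson closed form, and hit rate on trials with the burst-pause kernel."""
    rng = np.random.default_rng(_child_seed(seed, 8))
    params = EvokedDetectorParams()
    lam_burst = base_rate_hz * params.burst_window_ms / 1000.0
    lam_pause = base_rate_hz * params.pause_window_ms / 1000.0
    analytic = (
        1.0 - math.exp(-lam_burst) * (1.0 + lam_burst)
    ) * math.exp(-lam_pause)

    false_alarms = 0
    for _ in range(n_null):
        n = rng.poisson(base_rate_hz * 2.0)
        spikes = np.sort(rng.uniform(0.0, 2000.0, n))
        responsive, _, _ = detect_lc_evoked_response(spikes, 500.0, params)
        false_alarms += responsive

    hits = 0
    for _ in range(n_burst):
        spikes = synth.simulate_lc_spikes(
            2000.0,
            base_rate_hz,
            rng,
            beep_time_ms=500.0,
            responsive=True,
        )
        responsive, _, _ = detect_lc_evoked_response(spikes, 500.0, params)
        hits += responsive

    return {
        "false_alarm_rate": false_alarms / n_null,
        "analytic_rate": analytic,
        "binomial_sd": math.sqrt(analytic * (1 - analytic) / n_null),
        "hit_rate": hits / n_burst,
        "n_null": n_null,
        "n_burst": n_burst,
    }


def prepost_contrast_recovery(
    seed: int, n_pairs: int = 60, n_trials: int = 400
) -> dict[str, float]:
    """Event-locked shared-rate step (0.5 -> 1.5 of a total 4) on responsive
    trials only.

    The recovery of the analytic +0.25 delta uses the generator's true
    responsive/non-responsive groups (the target is only implied for the
    exact groups the step was imposed on); the detector-classified groups
    provide the between-group contrast, and the same detector applied at
    virtual events on no-beep trials provides the fake-beep null contrast.
    """
    gate = {
        "pre": (3.5, 0.5),
        "post_responsive": (2.5, 1.5),
        "post_nonresponsive": (3.5, 0.5),
    }
    cfg = synth.SimConfig(
        n_trials=n_trials,
        beep_fraction=0.5,
        acc_pairs=[synth.PairSpec(evoked_gate=gate) for _ in range(n_pairs)],
        seed=_child_seed(seed, 9),
    )
    session, truth = synth.simulate_session(cfg)
    cls = classify_evoked_lc(session, "LC_0", seed=_child_seed(seed, 10))
    target = synth.PairSpec.rsc(2.5, 1.5) - synth.PairSpec.rsc(3.5, 0.5)
    out: dict[str, float] = {"target_delta": target, "n_pairs": n_pairs}

    beeps = cls[cls.is_beep]
    beep_events = {int(r.trial_id): r.event_time_ms for r in beeps.itertuples()}
    responsive_true = set(truth.responsive_trials)
    groupings = {
        "beep": {
            "responsive": [t for t in beep_events if t in responsive_true],
            "nonresponsive": [t for t in beep_events if t not in responsive_true],
        },
        "detected": {
            "responsive": beeps[beeps.responsive].trial_id.tolist(),
            "nonresponsive": beeps[~beeps.responsive].trial_id.tolist(),
        },
    }
    for kind, groups in groupings.items():
        per_pair, contrast = pre_post_rsc_difference(
            session, truth.pair_units, beep_events, groups, np.array([1000.0])
        )
        for grp in ("responsive", "nonresponsive"):
            d = per_pair.loc[per_pair.group == grp, "delta_rsc"].dropna().to_numpy()
            if d.size >= 2:
                ci = bootstrap_median_ci(d, seed=_child_seed(seed, 11))
                out[f"{kind}_{grp}_delta"] = float(np.median(d))
                out[f"{kind}_{grp}_ci_lower"] = ci.lower
                out[f"{kind}_{grp}_ci_upper"] = ci.upper
        if not contrast.empty:
            out[f"{kind}_contrast"] = float(contrast.contrast.iloc[0])
            out[f"{kind}_contrast_p"] = float(contrast.ranksum_p.iloc[0])

    fakes = cls[~cls.is_beep]
    fake_events = {int(r.trial_id): r.event_time_ms for r in fakes.itertuples()}
    fake_groups = {
        "responsive": fakes[fakes.responsive].trial_id.tolist(),
        "nonresponsive": fakes[~fakes.responsive].trial_id.tolist(),
    }
    per_pair, contrast = pre_post_rsc_difference(
        session, truth.pair_units, fake_events, fake_groups, np.array([1000.0])
    )
    deltas = per_pair.groupby("group").delta_rsc.median()
    if not contrast.empty:
        out["fake_contrast"] = float(contrast.contrast.iloc[0])
        out["fake_contrast_p"] = float(contrast.ranksum_p.iloc[0])
        for grp in ("responsive", "nonresponsive"):
            if grp in deltas:
                out[f"fake_{grp}_delta"] = float(deltas[grp])
    return out


def test_exactness_and_uniformity(
    seed: int, n_replicates: int = 300
) -> dict[str, float]:
    """Exact small-sample p-values plus null p-value uniformity (KS against
    the uniform distribution) for all four nonparametric tests."""
    p_signrank = signrank_test(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])).p_value
    p_ranksum = ranksum_test(np.array([1, 2, 3]), np.array([4, 5, 6])).p_value

    rng = np.random.default_rng(_child_seed(seed, 12))
    from .inference import anova_oneway, ks_test

    pools = {"signrank": [], "ranksum": [], "ks": [], "anova": []}
    # co-prime KS sample sizes keep the D statistic's support fine enough
    # for its discrete p-value to look uniform at this replicate count
    for _ in range(n_replicates):
        pools["signrank"].append(signrank_test(rng.normal(size=50)).p_value)
        pools["ranksum"].append(
            ranksum_test(rng.normal(size=30), rng.normal(size=30)).p_value
        )
        pools["ks"].append(
            ks_test(rng.normal(size=100), rng.normal(size=103)).p_value
        )
        pools["anova"].append(
            anova_oneway(
                rng.normal(size=10), rng.normal(size=10), rng.normal(size=10)
            ).p_value
        )
    uniformity = {
        name: float(sps.kstest(np.asarray(ps), "uniform").pvalue)
        for name, ps in pools.items()
    }
    return {
        "signrank_exact_p_six_positive": p_signrank,
        "ranksum_exact_p_shifted_triples": p_ranksum,
        "min_uniformity_ks_p": min(uniformity.values()),
        **{f"uniformity_{k}": v for k, v in uniformity.items()},
        "n_replicates": n_replicates,
    }
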