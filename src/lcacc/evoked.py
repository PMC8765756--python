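"""Beep-locked analyses: PSTHs, Fano quenching, evoked-LC classification,
fake-beep control, pre/post correlation differences, pupil responses, and
event-aligned r_sc time courses.

The evoked-LC detector operationalizes the characteristic burst-then-pause
response as: at least ``burst_min`` spikes in the burst window immediately
after the event AND at most ``pause_max`` spikes in the pause window that
follows.  The same detector applied at a virtual event time on no-beep
trials ("fake beeps") provides the control classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pairwise import rsc
from .session import Session

__all__ = [
    "EvokedDetectorParams",
    "Psth",
    "classify_evoked_lc",
    "detect_fake_beep",
    "detect_lc_evoked_response",
    "fano_timecourse",
    "median_split",
    "pre_post_rsc_difference",
    "psth",
    "pupil_response",
    "pupil_response_table",
    "timecourse_rsc",
]


def _window_counts(
    spikes: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    s = np.asarray(spikes, dtype=float)
    return np.searchsorted(s, ends) - np.searchsorted(s, starts)


@dataclass
class Psth:
    """Trial-averaged event-aligned firing rate (sp/s) with SEM per bin."""

    edges_ms: np.ndarray  # bin edges relative to event
    rate: np.ndarray
    sem: np.ndarray
    n_trials: int

    @property
    def centers_ms(self) -> np.ndarray:
        return (self.edges_ms[:-1] + self.edges_ms[1:]) / 2.0


def psth(
    spikes_by_trial: dict[int, np.ndarray],
    event_times: dict[int, float],
    bin_ms: float = 50.0,
    t_range: tuple[float, float] = (-1000.0, 1000.0),
) -> Psth:
    """Peri-event time histogram across trials with an event."""
    if not event_times:
        raise ValueError("need at least one event")
    edges = np.arange(t_range[0], t_range[1] + bin_ms / 2, bin_ms)
    per_trial = []
    for trial_id, event in event_times.items():
        rel = np.asarray(spikes_by_trial.get(trial_id, ()), dtype=float) - event
        counts, _ = np.histogram(rel, bins=edges)
        per_trial.append(counts / (bin_ms / 1000.0))
    rates = np.vstack(per_trial)
    n = rates.shape[0]
    sem = rates.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(rates.shape[1])
    return Psth(edges_ms=edges, rate=rates.mean(axis=0), sem=sem, n_trials=n)


def fano_timecourse(
    spikes_by_trial: dict[int, np.ndarray],
    event_times: dict[int, float],
    window_ms: float = 200.0,
    step_ms: float = 50.0,
    t_range: tuple[float, float] = (-1000.0, 1000.0),
) -> pd.DataFrame:
    """Fano factor in sliding event-aligned windows across trials.

    Returns one row per window center with mean, variance, and Fano (NaN
    where the window's mean count is zero).
    """
    if len(event_times) < 2:
        raise ValueError("need at least 2 trials")
    centers = np.arange(
        t_range[0] + window_ms / 2.0, t_range[1] - window_ms / 2.0 + 1e-9, step_ms
    )
    starts_rel = centers - window_ms / 2.0
    counts = np.vstack(
        [
            _window_counts(
                np.asarray(spikes_by_trial.get(tid, ()), dtype=float),
                ev + starts_rel,
                ev + starts_rel + window_ms,
            )
            for tid, ev in event_times.items()
        ]
    )
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    fano = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    return pd.DataFrame(
        {
            "t_center_ms": centers,
            "mean_count": mean,
            "variance": var,
            "fano": fano,
            "n_trials": counts.shape[0],
        }
    )


@dataclass
class EvokedDetectorParams:
    """Burst-then-pause criterion for the transient evoked LC response."""

    burst_window_ms: float = 300.0
    pause_window_ms: float = 500.0
    burst_min: int = 2
    pause_max: int = 0


def detect_lc_evoked_response(
    spikes: np.ndarray,
    event_time_ms: float,
    params: EvokedDetectorParams | None = None,
    trial_end_ms: float | None = None,
) -> tuple[bool, int, int]:
    """Classify one trial: responsive iff burst count >= ``burst_min`` in
    ``[event, event + W1)`` and pause count <= ``pause_max`` in
    ``[event + W1, event + W1 + W2)``.

    Returns ``(responsive, burst_count, pause_count)``.
    """
    p = params or EvokedDetectorParams()
    window_end = event_time_ms + p.burst_window_ms + p.pause_window_ms
    if trial_end_ms is not None and window_end > trial_end_ms:
        raise ValueError(
            f"detector windows end at {window_end} ms, beyond trial end {trial_end_ms}"
        )
    s = np.asarray(spikes, dtype=float)
    burst = int(
        np.count_nonzero(
            (s >= event_time_ms) & (s < event_time_ms + p.burst_window_ms)
        )
    )
    pause = int(
        np.count_nonzero(
            (s >= event_time_ms + p.burst_window_ms) & (s < window_end)
        )
    )
    return burst >= p.burst_min and pause <= p.pause_max, burst, pause


def detect_fake_beep(
    spikes: np.ndarray,
    stable_fix_on_ms: float,
    trial_end_ms: float,
    seed: int | np.random.Generator,
    params: EvokedDetectorParams | None = None,
    delay_range_ms: tuple[float, float] = (1000.0, 1500.0),
) -> tuple[float, bool, int, int]:
    """Apply the evoked detector at a virtual event time on a no-beep trial.

    The virtual time is drawn uniformly from the real beep schedule
    (``delay_range_ms`` after stable fixation), seeded for reproducibility.
    Returns ``(virtual_time, responsive, burst_count, pause_count)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params or EvokedDetectorParams()
    virtual = stable_fix_on_ms + rng.uniform(*delay_range_ms)
    if virtual + p.burst_window_ms + p.pause_window_ms > trial_end_ms:
        raise ValueError("trial too short for a virtual event")
    responsive, burst, pause = detect_lc_evoked_response(spikes, virtual, p)
    return virtual, responsive, burst, pause


def classify_evoked_lc(
    session: Session,
    lc_unit_id: str,
    seed: int | np.random.Generator = 0,
    params: EvokedDetectorParams | None = None,
    fake_delay_range_ms: tuple[float, float] = (1000.0, 1500.0),
) -> pd.DataFrame:
    """Per-trial evoked-LC classification for a whole session.

    Beep trials are classified at the real beep time; no-beep trials at a
    seeded virtual ("fake beep") time.  Returns one row per trial with the
    event time used, the beep flag, and the detector outputs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    unit = session.unit(lc_unit_id)
    rows = []
    for trial in session.trials:
        spikes = unit.spike_times(trial.trial_id)
        if trial.beep_time is not None:
            event = trial.beep_time
            responsive, burst, pause = detect_lc_evoked_response(
                spikes, event, params, trial.trial_end
            )
            is_beep = True
        else:
            event, responsive, burst, pause = detect_fake_beep(
                spikes,
                trial.stable_fix_on,
                trial.trial_end,
                rng,
                params,
                fake_delay_range_ms,
            )
            is_beep = False
        rows.append(
            {
                "trial_id": trial.trial_id,
                "is_beep": is_beep,
                "event_time_ms": event,
                "responsive": responsive,
                "burst_count": burst,
                "pause_count": pause,
            }
        )
    return pd.DataFrame(rows)


def pre_post_rsc_difference(
    session: Session,
    pairs: list[tuple[str, str]],
    event_times: dict[int, float],
    groups: dict[str, list[int]],
    bin_sizes_ms: np.ndarray,
    window_ms: float = 1000.0,
    min_trials: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-minus-pre r_sc per pair, bin size, and trial group.

    r_sc is computed in the ``window_ms`` windows immediately before and
    after each event, with counting bins anchored at each window's start.
    Returns ``(per_pair, contrast)``: the per-pair table of pre/post r and
    their difference, and — when exactly two groups are given — the per-bin
    between-group contrast (difference of group medians with a rank-sum p).
    """
    units = {uid: session.unit(uid) for pair in pairs for uid in pair}
    rows = []
    for group, trial_ids in groups.items():
        tids = [t for t in trial_ids if t in event_times]
        for bin_ms in np.asarray(bin_sizes_ms, dtype=float):
            b = min(bin_ms, window_ms)
            for pair in pairs:
                counts = {"pre": [[], []], "post": [[], []]}
                for tid in tids:
                    ev = event_times[tid]
                    for k, (uid) in enumerate(pair):
                        s = units[uid].spike_times(tid)
                        counts["pre"][k].append(
                            int(
                                _window_counts(
                                    s,
                                    np.array([ev - window_ms]),
                                    np.array([ev - window_ms + b]),
                                )[0]
                            )
                        )
                        counts["post"][k].append(
                            int(
                                _window_counts(
                                    s, np.array([ev]), np.array([ev + b])
                                )[0]
                            )
                        )
                r_pre, n_pre, _ = rsc(
                    np.array(counts["pre"][0]),
                    np.array(counts["pre"][1]),
                    min_trials,
                )
                r_post, n_post, _ = rsc(
                    np.array(counts["post"][0]),
                    np.array(counts["post"][1]),
                    min_trials,
                )
                rows.append(
                    {
                        "group": group,
                        "bin_size_ms": bin_ms,
                        "pair_a": pair[0],
                        "pair_b": pair[1],
                        "r_pre": r_pre,
                        "r_post": r_post,
                        "delta_rsc": r_post - r_pre,
                        "n_trials": len(tids),
                    }
                )
    per_pair = pd.DataFrame(rows)

    contrast_rows = []
    names = list(groups)
    if len(names) == 2 and not per_pair.empty:
        for bin_ms, sub in per_pair.groupby("bin_size_ms"):
            d = {
                g: sub.loc[sub.group == g, "delta_rsc"].dropna().to_numpy()
                for g in names
            }
            if min(len(d[names[0]]), len(d[names[1]])) >= 3:
                stat, p = sps.mannwhitneyu(
                    d[names[0]], d[names[1]], alternative="two-sided"
                )
            else:
                stat, p = np.nan, np.nan
            contrast_rows.append(
                {
                    "bin_size_ms": bin_ms,
                    "group_a": names[0],
                    "group_b": names[1],
                    "median_delta_a": float(np.median(d[names[0]]))
                    if len(d[names[0]])
                    else np.nan,
                    "median_delta_b": float(np.median(d[names[1]]))
                    if len(d[names[1]])
                    else np.nan,
                    "contrast": (
                        float(np.median(d[names[0]]) - np.median(d[names[1]]))
                        if len(d[names[0]]) and len(d[names[1]])
                        else np.nan
                    ),
                    "ranksum_p": p,
                }
            )
    return per_pair, pd.DataFrame(contrast_rows)


def pupil_response(
    values: np.ndarray,
    dt_ms: float,
    event_time_ms: float,
    t0_ms: float = 0.0,
    baseline_ms: float = 1000.0,
    search_ms: float = 2000.0,
) -> tuple[float, float]:
    """Baseline (mean over the 1 s pre-event) and evoked amplitude
    (post-event maximum minus baseline) of one trial's pupil trace."""
    t = t0_ms + np.arange(len(values)) * dt_ms
    if len(values) == 0 or t[0] > event_time_ms - baseline_ms or t[-1] < (
        event_time_ms + search_ms - dt_ms
    ):
        raise ValueError("insufficient trace around event")
    pre = (t >= event_time_ms - baseline_ms) & (t < event_time_ms)
    post = (t > event_time_ms) & (t <= event_time_ms + search_ms)
    v = np.asarray(values, dtype=float)
    baseline = float(v[pre].mean())
    evoked_amp = float(v[post].max() - baseline)
    return baseline, evoked_amp


def pupil_response_table(
    session: Session, event_times: dict[int, float], search_ms: float = 2000.0
) -> pd.DataFrame:
    """Per-trial pupil baseline and evoked amplitude with median-split labels."""
    rows = []
    for tid, ev in event_times.items():
        baseline, amp = pupil_response(
            session.pupil.trial_values(tid),
            session.pupil.dt_ms,
            ev,
            t0_ms=session.pupil.t0,
            search_ms=search_ms,
        )
        rows.append({"trial_id": tid, "baseline": baseline, "evoked_amp": amp})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["baseline_high"] = median_split(df.baseline.to_numpy())
        df["evoked_high"] = median_split(df.evoked_amp.to_numpy())
    return df


def median_split(values: np.ndarray) -> np.ndarray:
    """Boolean high/low labels balanced to within one trial (rank split)."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    labels = np.zeros(v.size, dtype=bool)
    labels[order[v.size // 2 :]] = True
    return labels


def timecourse_rsc(
    session: Session,
    pairs: list[tuple[str, str]],
    align_times: dict[int, float],
    groups: dict[str, list[int]],
    window_ms: float = 500.0,
    step_ms: float = 100.0,
    t_range: tuple[float, float] = (-1000.0, 2000.0),
    baseline_range_ms: tuple[float, float] = (-1000.0, 0.0),
    slope_epoch_ms: tuple[float, float] = (100.0, 600.0),
    min_trials: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Event-aligned r_sc time course per trial group.

    Returns ``(series, bin_tests, slopes)``:

    * ``series``: r_sc per pair per sliding window center per group;
    * ``bin_tests``: per group and window, rank-sum of the across-pair r_sc
      values against the group's pre-event baseline windows;
    * ``slopes``: per pair and group, the least-squares slope of r_sc over
      window centers inside ``slope_epoch_ms`` (the early post-event rise),
      plus a between-group rank-sum comparison row per group pair.
    """
    centers = np.arange(
        t_range[0] + window_ms / 2.0, t_range[1] - window_ms / 2.0 + 1e-9, step_ms
    )
    units = {uid: session.unit(uid) for pair in pairs for uid in pair}
    series_rows = []
    for group, trial_ids in groups.items():
        tids = [t for t in trial_ids if t in align_times]
        evs = np.array([align_times[t] for t in tids])
        for pair in pairs:
            counts_a = np.vstack(
                [
                    _window_counts(
                        units[pair[0]].spike_times(tid),
                        ev + centers - window_ms / 2.0,
                        ev + centers + window_ms / 2.0,
                    )
                    for tid, ev in zip(tids, evs)
                ]
            )
            counts_b = np.vstack(
                [
                    _window_counts(
                        units[pair[1]].spike_times(tid),
                        ev + centers - window_ms / 2.0,
                        ev + centers + window_ms / 2.0,
                    )
                    for tid, ev in zip(tids, evs)
                ]
            )
            for k, c in enumerate(centers):
                r, n_used, _ = rsc(counts_a[:, k], counts_b[:, k], min_trials)
                series_rows.append(
                    {
                        "group": group,
                        "pair_a": pair[0],
                        "pair_b": pair[1],
                        "t_center_ms": c,
                        "r": r,
                        "n_trials_used": n_used,
                    }
                )
    series = pd.DataFrame(series_rows)

    test_rows = []
    for group, sub in series.groupby("group"):
        base = sub[
            (sub.t_center_ms >= baseline_range_ms[0])
            & (sub.t_center_ms < baseline_range_ms[1])
        ].r.dropna()
        for c, bin_sub in sub.groupby("t_center_ms"):
            vals = bin_sub.r.dropna()
            if len(vals) >= 3 and len(base) >= 3:
                _, p = sps.mannwhitneyu(vals, base, alternative="two-sided")
            else:
                p = np.nan
            test_rows.append(
                {
                    "group": group,
                    "t_center_ms": c,
                    "median_r": vals.median() if len(vals) else np.nan,
                    "p_vs_baseline": p,
                }
            )
    bin_tests = pd.DataFrame(test_rows)

    slope_rows = []
    in_epoch = (series.t_center_ms >= slope_epoch_ms[0]) & (
        series.t_center_ms < slope_epoch_ms[1]
    )
    for (group, pa, pb), sub in series[in_epoch].groupby(
        ["group", "pair_a", "pair_b"]
    ):
        sub = sub.dropna(subset=["r"])
        if len(sub) >= 3:
            fit = sps.linregress(sub.t_center_ms, sub.r)
            slope_rows.append(
                {
                    "group": group,
                    "pair_a": pa,
                    "pair_b": pb,
                    "slope_per_ms": fit.slope,
                }
            )
    slopes = pd.DataFrame(slope_rows)
    if not slopes.empty:
        names = sorted(groups)
        for i, ga in enumerate(names):
            for gb in names[i + 1 :]:
                a = slopes.loc[slopes.group == ga, "slope_per_ms"].to_numpy()
                b = slopes.loc[slopes.group == gb, "slope_per_ms"].to_numpy()
                if min(a.size, b.size) >= 3:
                    _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                    slopes.loc[len(slopes)] = {
                        "group": f"{ga}_vs_{gb}",
                        "pair_a": "",
                        "pair_b": "",
                        "slope_per_ms": float(np.median(a) - np.median(b)),
                    }
                    slopes.loc[len(slopes) - 1, "ranksum_p"] = p
    return series, bin_tests, slopes
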