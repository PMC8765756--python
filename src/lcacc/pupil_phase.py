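"""Hippus cycle detection, pupil-phase assignment, and phase-triggered maps.

Each hippus cycle runs between successive local minima of the (smoothed)
pupil trace and is anchored by four landmarks: maximum rate of dilation
(0 deg), maximum size (90 deg), maximum rate of constriction (180 deg), and
minimum size (270 deg).  Phase is linear in time between consecutive
landmarks and undefined outside complete cycles.

Phase-triggered maps hold, for each (time offset, phase bin) cell, the mean
z-scored spike rate of a unit or the spike-count correlation of a pair,
computed in a fixed-width window centered ``offset`` ms from each occurrence
of that pupil phase.  A line fitted to the per-offset extrema of such a map
measures how the signal's modulation precesses with phase; its slope is
-360/T deg/ms for a modulation locked to a hippus of period T, and its
0-degree crossing gives the signal-to-pupil delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.signal import find_peaks

from .pairwise import spike_count_correlation
from .session import PupilTrace, Session

__all__ = [
    "HippusCycle",
    "PhaseMap",
    "PhaseSlopeFit",
    "assign_phase",
    "detect_hippus_cycles",
    "fit_phase_slope",
    "phase_occurrence_times",
    "phase_triggered_rate_map",
    "phase_triggered_rsc_map",
]

LANDMARK_PHASES_DEG = np.array([-90.0, 0.0, 90.0, 180.0, 270.0])
DEFAULT_OFFSETS_MS = np.arange(-1000.0, 1001.0, 100.0)


@dataclass
class HippusCycle:
    """Landmark times (ms) bounding one pupil cycle, strictly increasing."""

    t_min_prev: float
    t_max_dil_rate: float
    t_max: float
    t_max_con_rate: float
    t_min_next: float

    @property
    def landmarks(self) -> np.ndarray:
        return np.array(
            [
                self.t_min_prev,
                self.t_max_dil_rate,
                self.t_max,
                self.t_max_con_rate,
                self.t_min_next,
            ]
        )

    @property
    def period_ms(self) -> float:
        return self.t_min_next - self.t_min_prev


def _smooth(values: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return values.astype(float)
    kernel = np.ones(width_samples) / width_samples
    return np.convolve(values, kernel, mode="same")


def detect_hippus_cycles(
    values: np.ndarray,
    dt_ms: float,
    t0_ms: float = 0.0,
    smoothing_ms: float = 50.0,
    min_prominence: float = 0.2,
) -> list[HippusCycle]:
    """Detect complete hippus cycles in one trial's pupil trace.

    Cycles are delimited by successive local minima of the moving-average
    smoothed trace with at least ``min_prominence`` prominence (in pupil
    units); within each cycle the maximum and the extrema of the smoothed
    derivative give the remaining landmarks.  Incomplete boundary cycles are
    dropped; a flat or unmodulated trace yields no cycles.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return []
    smoothed = _smooth(v, max(int(round(smoothing_ms / dt_ms)), 1))
    minima, _ = find_peaks(-smoothed, prominence=min_prominence)
    if minima.size < 2:
        return []
    deriv = np.gradient(smoothed, dt_ms)
    cycles = []
    for i0, i1 in zip(minima, minima[1:]):
        seg = smoothed[i0 : i1 + 1]
        imax = i0 + int(np.argmax(seg))
        if imax <= i0 or imax >= i1:
            continue
        idil = i0 + int(np.argmax(deriv[i0 : imax + 1]))
        icon = imax + int(np.argmin(deriv[imax : i1 + 1]))
        idx = np.array([i0, idil, imax, icon, i1])
        if np.any(np.diff(idx) <= 0):
            continue
        t = t0_ms + idx * dt_ms
        cycles.append(HippusCycle(*t))
    return cycles


def assign_phase(
    n_samples: int,
    cycles: list[HippusCycle],
    dt_ms: float,
    t0_ms: float = 0.0,
) -> np.ndarray:
    """Per-sample pupil phase in degrees [0, 360), NaN outside complete cycles.

    Landmarks map to -90/0/90/180/270 degrees (the minimum opening a cycle is
    the 270-degree landmark of the previous one); phase is interpolated
    linearly in time between consecutive landmarks.
    """
    t = t0_ms + np.arange(n_samples) * dt_ms
    phase = np.full(n_samples, np.nan)
    for cyc in cycles:
        inside = (t >= cyc.t_min_prev) & (t < cyc.t_min_next)
        phase[inside] = np.interp(t[inside], cyc.landmarks, LANDMARK_PHASES_DEG)
    return np.mod(phase, 360.0)


def phase_occurrence_times(
    cycles: list[HippusCycle], phases_deg: np.ndarray
) -> np.ndarray:
    """Times at which each requested phase occurs, one per cycle.

    Returns an array of shape (n_cycles, n_phases).  Phases are folded into
    the cycle's native [-90, 270) span before inverse interpolation.
    """
    p = np.mod(np.asarray(phases_deg, dtype=float), 360.0)
    # 270 itself is the cycle-closing minimum; only fold strictly beyond it
    p = np.where(p > 270.0, p - 360.0, p)
    out = np.empty((len(cycles), p.size))
    for i, cyc in enumerate(cycles):
        out[i] = np.interp(p, LANDMARK_PHASES_DEG, cyc.landmarks)
    return out


@dataclass
class PhaseMap:
    """(time offset x phase bin) matrix of a phase-triggered quantity."""

    offsets_ms: np.ndarray
    phase_centers_deg: np.ndarray
    values: np.ndarray  # (n_offsets, n_phases); NaN flags below-min_n cells
    n: np.ndarray  # occurrences per cell
    quantity: str  # "zscored_rate" or "rsc"
    window_ms: float = 500.0
    extra: dict = field(default_factory=dict)


def _collect_window_counts(
    spikes_by_trial: dict[int, np.ndarray],
    pupil: PupilTrace,
    trial_ends: dict[int, float],
    offsets_ms: np.ndarray,
    phase_centers: np.ndarray,
    window_ms: float,
    smoothing_ms: float,
    min_prominence: float,
) -> tuple[list[list[np.ndarray]], np.ndarray]:
    """Per (offset, phase) cell, gather spike counts over all valid
    occurrences (windows fully inside the trial)."""
    n_off, n_ph = offsets_ms.size, phase_centers.size
    cells: list[list[np.ndarray]] = [
        [np.empty(0)] * n_ph for _ in range(n_off)
    ]
    buckets: list[list[list[np.ndarray]]] = [
        [[] for _ in range(n_ph)] for _ in range(n_off)
    ]
    half = window_ms / 2.0
    for trial_id, spikes in spikes_by_trial.items():
        trace = pupil.trial_values(trial_id)
        if trace.size == 0:
            continue
        cycles = detect_hippus_cycles(
            trace,
            pupil.dt_ms,
            t0_ms=pupil.t0,
            smoothing_ms=smoothing_ms,
            min_prominence=min_prominence,
        )
        if not cycles:
            continue
        occ = phase_occurrence_times(cycles, phase_centers)  # (n_cyc, n_ph)
        end = trial_ends[trial_id]
        spikes = np.asarray(spikes, dtype=float)
        for i_off, off in enumerate(offsets_ms):
            starts = occ + off - half  # (n_cyc, n_ph)
            valid = (starts >= 0.0) & (starts + window_ms <= end)
            counts = np.searchsorted(spikes, starts + window_ms) - np.searchsorted(
                spikes, starts
            )
            for i_ph in range(n_ph):
                good = valid[:, i_ph]
                if good.any():
                    buckets[i_off][i_ph].append(counts[good, i_ph])
    for i_off in range(n_off):
        for i_ph in range(n_ph):
            if buckets[i_off][i_ph]:
                cells[i_off][i_ph] = np.concatenate(buckets[i_off][i_ph])
    n = np.array(
        [[cells[i][j].size for j in range(n_ph)] for i in range(n_off)]
    )
    return cells, n


def phase_triggered_rate_map(
    session: Session,
    unit_id: str,
    offsets_ms: np.ndarray = DEFAULT_OFFSETS_MS,
    window_ms: float = 500.0,
    phase_bin_deg: float = 10.0,
    smoothing_ms: float = 50.0,
    min_prominence: float = 0.2,
    min_n: int = 10,
    zscore: bool = True,
) -> PhaseMap:
    """Mean spike rate of one unit in windows aligned to each pupil phase.

    Cell (t, p) is the unit's mean rate in a ``window_ms``-wide bin centered
    ``t`` ms from occurrences of pupil phase ``p``; the map is z-scored per
    unit across defined cells.  Cells with fewer than ``min_n`` occurrences
    are NaN.
    """
    offsets_ms = np.asarray(offsets_ms, dtype=float)
    centers = np.arange(phase_bin_deg / 2.0, 360.0, phase_bin_deg)
    unit = session.unit(unit_id)
    trial_ends = {t.trial_id: t.trial_end for t in session.trials}
    cells, n = _collect_window_counts(
        unit.spikes,
        session.pupil,
        trial_ends,
        offsets_ms,
        centers,
        window_ms,
        smoothing_ms,
        min_prominence,
    )
    rate = np.full(n.shape, np.nan)
    for i in range(n.shape[0]):
        for j in range(n.shape[1]):
            if n[i, j] >= min_n:
                rate[i, j] = cells[i][j].mean() / (window_ms / 1000.0)
    if zscore:
        finite = np.isfinite(rate)
        if finite.sum() >= 2 and np.nanstd(rate) > 0:
            rate = (rate - np.nanmean(rate)) / np.nanstd(rate)
    return PhaseMap(
        offsets_ms=offsets_ms,
        phase_centers_deg=centers,
        values=rate,
        n=n,
        quantity="zscored_rate" if zscore else "rate",
        window_ms=window_ms,
    )


def phase_triggered_rsc_map(
    session: Session,
    pair: tuple[str, str],
    offsets_ms: np.ndarray = DEFAULT_OFFSETS_MS,
    window_ms: float = 500.0,
    phase_bin_deg: float = 10.0,
    smoothing_ms: float = 50.0,
    min_prominence: float = 0.2,
    min_n: int = 10,
) -> PhaseMap:
    """Spike-count correlation of a pair across occurrences of each phase."""
    offsets_ms = np.asarray(offsets_ms, dtype=float)
    centers = np.arange(phase_bin_deg / 2.0, 360.0, phase_bin_deg)
    trial_ends = {t.trial_id: t.trial_end for t in session.trials}
    cells = []
    for unit_id in pair:
        unit = session.unit(unit_id)
        c, n = _collect_window_counts(
            unit.spikes,
            session.pupil,
            trial_ends,
            offsets_ms,
            centers,
            window_ms,
            smoothing_ms,
            min_prominence,
        )
        cells.append(c)
    r = np.full(n.shape, np.nan)
    for i in range(n.shape[0]):
        for j in range(n.shape[1]):
            a, b = cells[0][i][j], cells[1][i][j]
            if min(a.size, b.size) >= min_n and a.size == b.size:
                r[i, j] = spike_count_correlation(a, b)
    return PhaseMap(
        offsets_ms=offsets_ms,
        phase_centers_deg=centers,
        values=r,
        n=n,
        quantity="rsc",
        window_ms=window_ms,
    )


@dataclass
class PhaseSlopeFit:
    """Line fitted to the per-offset extremum phases of a phase map.

    ``zero_phase_time_ms`` is the time by which the signal's modulation
    leads the 0-degree (maximum-dilation-rate) landmark: minus the fitted
    line's 0-degree crossing, folded into one precession period.
    """

    slope_deg_per_ms: float
    intercept_deg: float
    zero_phase_time_ms: float
    p_value: float
    reliable: bool
    n_offsets: int


def fit_phase_slope(
    phase_map: PhaseMap,
    mode: str = "peaks",
    p_threshold: float = 0.05,
) -> PhaseSlopeFit:
    """Least-squares line through the circularly unwrapped extremum phases.

    ``mode="peaks"`` tracks the phase of the maximum per offset (spike-rate
    maps); ``mode="minima"`` tracks the minimum (correlation maps).  Fits
    with slope-vs-zero p >= ``p_threshold`` are flagged unreliable.
    """
    if mode not in ("peaks", "minima"):
        raise ValueError("mode must be 'peaks' or 'minima'")
    offsets, extremum = [], []
    for i, off in enumerate(phase_map.offsets_ms):
        row = phase_map.values[i]
        if not np.isfinite(row).any():
            continue
        j = np.nanargmax(row) if mode == "peaks" else np.nanargmin(row)
        offsets.append(off)
        extremum.append(phase_map.phase_centers_deg[j])
    if len(offsets) < 3:
        return PhaseSlopeFit(0.0, 0.0, float("nan"), 1.0, False, len(offsets))
    offsets = np.asarray(offsets)
    unwrapped = np.asarray(extremum, dtype=float)
    for k in range(1, unwrapped.size):
        unwrapped[k] += 360.0 * np.round(
            (unwrapped[k - 1] - unwrapped[k]) / 360.0
        )
    if np.allclose(unwrapped, unwrapped[0]):
        # constant extremum phase: degenerate, no precession measurable
        return PhaseSlopeFit(
            0.0, float(unwrapped[0]), float("nan"), 1.0, False, offsets.size
        )
    fit = sps.linregress(offsets, unwrapped)
    slope, intercept, p = fit.slope, fit.intercept, fit.pvalue
    if slope == 0 or not np.isfinite(slope):
        return PhaseSlopeFit(0.0, float(intercept), float("nan"), 1.0, False, offsets.size)
    period = 360.0 / abs(slope)
    t_cross = -intercept / slope  # fitted line's 0-degree crossing
    zero_phase_time = float(np.mod(-t_cross, period))
    return PhaseSlopeFit(
        slope_deg_per_ms=float(slope),
        intercept_deg=float(intercept),
        zero_phase_time_ms=zero_phase_time,
        p_value=float(p),
        reliable=bool(p < p_threshold),
        n_offsets=int(offsets.size),
    )
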