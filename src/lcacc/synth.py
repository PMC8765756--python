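"""Synthetic session generator with analytic ground truth.

The generator emulates the statistical structure that the analysis pipeline
assumes in real LC/ACC recordings:

* a weakly firing LC unit (~2 sp/s, zero-inflated so that more than a third
  of trials carry no spike) whose rate is modulated by the hippus and which
  leads the pupil by a fixed delay;
* ACC pairs whose spike-count correlation is produced by a common-input
  Poisson construction — each unit's count in a "correlation block" is
  ``N_i = B_i + C`` with private ``B_i ~ Poisson(lam_private)`` and shared
  ``C ~ Poisson(lam_shared)`` — so that the block-level Pearson correlation
  is exactly ``lam_shared / (lam_private + lam_shared)``;
* quasi-periodic pupil fluctuations (hippus) plus beep-evoked dilations;
* beep-evoked LC burst-pause responses on a configurable fraction of beep
  trials, with dilation size coupled to burst size.

Each unit of a pair scatters the *same* shared count at *independent*
uniform times within the block.  Counting in a sub-window of length ``b``
then thins both counts independently, which makes the measured correlation
grow linearly with bin size toward the block-level value — the bin-size
dependence the analyses probe — while keeping every marginal count Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .session import PupilTrace, Session, TrialRecord, UnitRecord

__all__ = [
    "EvokedConfig",
    "GroundTruth",
    "HippusConfig",
    "PairSpec",
    "SimConfig",
    "gain_modulated_counts",
    "gain_modulated_spike_trains",
    "simulate_correlated_counts",
    "simulate_lc_spikes",
    "simulate_pupil",
    "simulate_session",
]

REFERENCE_WINDOW_MS = 1100.0


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class HippusConfig:
    """Quasi-periodic pupil fluctuation: ``A*sin(2*pi*t/T + phi0)`` plus
    smoothed Gaussian noise.  ``phi0`` is randomized per trial."""

    period_ms: float = 600.0
    amplitude: float = 1.0
    noise_sd: float = 0.05
    noise_smooth_ms: float = 50.0


@dataclass
class EvokedConfig:
    """Beep-evoked LC burst-pause response and coupled pupil dilation.

    The burst adds ``burst_rate_hz`` to the LC rate for ``burst_dur_ms``
    after the beep, then the rate is clamped to zero for ``pause_dur_ms``
    (hard pause).  The pupil dilation ramps up over ``dilation_latency_ms``
    and decays exponentially; its amplitude scales with the realized burst
    spike count so that larger LC responses come with larger dilations.
    """

    burst_rate_hz: float = 40.0
    burst_dur_ms: float = 200.0
    pause_dur_ms: float = 600.0
    responsive_fraction: float = 0.5
    pupil_dilation_amp: float = 0.5
    dilation_latency_ms: float = 500.0
    dilation_decay_ms: float = 1000.0

    @property
    def expected_burst_count(self) -> float:
        return self.burst_rate_hz * self.burst_dur_ms / 1000.0


@dataclass
class PairSpec:
    """Common-input Poisson specification for one ACC pair.

    ``lambda_private`` / ``lambda_shared`` are expected counts per reference
    window (1.1 s).  Optional gates replace them depending on the trial's
    condition:

    * ``lc_gate``: ``{"zero": (lb, lc), "nonzero": (lb, lc)}`` applied to the
      stable-fixation block on no-beep trials, keyed by whether the LC unit
      spiked in the reference window;
    * ``evoked_gate``: ``{"pre": .., "post_responsive": .., "post_nonresponsive": ..}``
      applied to the 1 s windows before/after the beep on beep trials
      (expected counts per 1 s window);
    * ``phase_coupling`` > 0 switches the pair to short tiled blocks over the
      whole trial with the shared rate modulated by pupil phase
      (``lam_shared * (1 + g*cos(phase(t + phase_lead_ms)))``), for
      phase-triggered correlation analyses.
    """

    lambda_private: float = 3.0
    lambda_shared: float = 1.0
    lc_gate: dict[str, tuple[float, float]] | None = None
    evoked_gate: dict[str, tuple[float, float]] | None = None
    phase_coupling: float = 0.0
    phase_lead_ms: float = 0.0

    def validate(self) -> None:
        pairs = [(self.lambda_private, self.lambda_shared)]
        for gate in (self.lc_gate, self.evoked_gate):
            if gate:
                pairs.extend(gate.values())
        for lb, lc in pairs:
            if lb < 0 or lc < 0:
                raise ValueError(f"negative rate in PairSpec: ({lb}, {lc})")
        if not 0 <= self.phase_coupling <= 1:
            raise ValueError("phase_coupling must be in [0, 1]")

    @staticmethod
    def rsc(lam_private: float, lam_shared: float) -> float:
        """Analytic block-level correlation of the common-input construction."""
        total = lam_private + lam_shared
        return lam_shared / total if total > 0 else float("nan")


@dataclass
class SimConfig:
    """Study conditions for one synthetic session.

    Defaults follow the recording conditions the pipeline targets: ~25% beep
    trials, a beep 1-1.5 s after stable fixation, an LC unit near 2 sp/s with
    zero spikes on over a third of trials, hippus period 600 ms with the LC
    leading the pupil by 270 ms.  Trials are fixed at 4 s so every trial
    admits both the stable-fixation window and the pre/post beep windows.
    """

    n_trials: int = 400
    trial_len_ms: float = 4000.0
    beep_fraction: float = 0.25
    acc_pairs: list[PairSpec] = field(default_factory=lambda: [PairSpec()])
    lc_rate_hz: float = 2.0
    lc_zero_inflation: float = 0.3
    lc_phase_coupling: float = 0.5
    lc_pupil_lead_ms: float = 270.0
    hippus: HippusConfig = field(default_factory=HippusConfig)
    evoked: EvokedConfig = field(default_factory=EvokedConfig)
    fix_on_ms: float = 0.0
    stable_fix_on_ms: float = 200.0
    epoch_offset_ms: float = 1000.0
    epoch_duration_ms: float = REFERENCE_WINDOW_MS
    beep_delay_range_ms: tuple[float, float] = (1000.0, 1500.0)
    pupil_sample_rate_hz: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.beep_fraction <= 1:
            raise ValueError("beep_fraction must be in [0, 1]")
        if self.hippus.period_ms <= 0:
            raise ValueError("hippus period must be positive")
        if self.lc_rate_hz < 0:
            raise ValueError("lc_rate_hz must be >= 0")
        epoch_end = self.stable_fix_on_ms + self.epoch_offset_ms + self.epoch_duration_ms
        if epoch_end > self.trial_len_ms:
            raise ValueError("stable-fixation window exceeds trial length")
        beep_latest = self.stable_fix_on_ms + self.beep_delay_range_ms[1]
        if self.beep_fraction > 0 and beep_latest + 1000.0 > self.trial_len_ms:
            raise ValueError("post-beep window exceeds trial length")
        burst_end = self.evoked.burst_dur_ms + self.evoked.pause_dur_ms
        if self.beep_fraction > 0 and beep_latest + burst_end > self.trial_len_ms:
            raise ValueError("burst/pause window exceeds trial length")
        for p in self.acc_pairs:
            p.validate()

    @property
    def epoch_start_ms(self) -> float:
        return self.stable_fix_on_ms + self.epoch_offset_ms


@dataclass
class GroundTruth:
    """Analytically implied targets for every stage of the pipeline."""

    config: SimConfig
    target_rsc: list[dict[str, float]]  # one dict per pair, keyed by condition
    hippus_period_ms: float
    lc_lead_ms: float
    expected_fano: float  # per condition; Poisson construction => 1
    beep_trials: list[int]
    responsive_trials: list[int]
    silent_lc_trials: list[int]
    lc_epoch_counts: dict[int, int]
    pair_units: list[tuple[str, str]]

    def delta_rsc(self, pair_index: int = 0) -> float:
        """Analytic (nonzero - zero) conditioned-correlation difference."""
        t = self.target_rsc[pair_index]
        return t["nonzero"] - t["zero"]


# ---------------------------------------------------------------------------
# primitive generators


def simulate_correlated_counts(
    n_trials: int,
    lambda_private: float,
    lambda_shared: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired counts ``N_i = B_i + C`` from the common-input model.

    The implied Pearson correlation is ``lambda_shared / (lambda_private +
    lambda_shared)`` when both marginals share ``lambda_private``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if lambda_private < 0 or lambda_shared < 0:
        raise ValueError("rates must be non-negative")
    rng = _rng(seed)
    shared = rng.poisson(lambda_shared, n_trials)
    n1 = rng.poisson(lambda_private, n_trials) + shared
    n2 = rng.poisson(lambda_private, n_trials) + shared
    return n1, n2


def _scatter(count: int, t0: float, dur: float, rng: np.random.Generator) -> np.ndarray:
    return np.sort(rng.uniform(t0, t0 + dur, count)) if count else np.empty(0)


def _correlated_block(
    lam_private: float,
    lam_shared: float,
    t0: float,
    dur: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times for one correlation block of one pair.

    The shared count is drawn once but scattered independently per unit, so
    sub-window counts are independently thinned (see module docstring).
    """
    shared = rng.poisson(lam_shared)
    a = _scatter(rng.poisson(lam_private) + shared, t0, dur, rng)
    b = _scatter(rng.poisson(lam_private) + shared, t0, dur, rng)
    return a, b


def gain_modulated_counts(
    n_trials: int,
    lam: float,
    gain_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Doubly stochastic counts: ``Poisson(lam * G)`` with trial gain
    ``G ~ N(1, gain_sd)`` clipped at 0.

    For small clipping mass the Fano factor is ``1 + lam * gain_sd**2``.
    """
    rng = _rng(seed)
    gains = np.clip(rng.normal(1.0, gain_sd, n_trials), 0.0, None)
    return rng.poisson(lam * gains)


def gain_modulated_spike_trains(
    n_trials: int,
    rate_hz: float,
    gain_sd: float,
    freeze_time_ms: float,
    t_range_ms: tuple[float, float],
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """Spike trains whose rate gain fluctuates across trials before
    ``freeze_time_ms`` and is frozen to 1 afterwards.

    Emulates stimulus-driven quenching of trial-to-trial variability: Fano
    ``1 + (rate*window)*gain_sd**2`` before the event, 1 after it.
    """
    rng = _rng(seed)
    t0, t1 = t_range_ms
    trains = []
    for _ in range(n_trials):
        gain = max(rng.normal(1.0, gain_sd), 0.0)
        pieces = []
        for a, b, g in ((t0, freeze_time_ms, gain), (freeze_time_ms, t1, 1.0)):
            if b <= a:
                continue
            n = rng.poisson(rate_hz * g * (b - a) / 1000.0)
            pieces.append(rng.uniform(a, b, n))
        trains.append(np.sort(np.concatenate(pieces)) if pieces else np.empty(0))
    return trains


def simulate_pupil(
    trial_len_ms: float,
    phi0: float,
    hippus: HippusConfig,
    seed: int | np.random.Generator,
    beep_time_ms: float | None = None,
    dilation_amp: float = 0.0,
    dilation_latency_ms: float = 500.0,
    dilation_decay_ms: float = 1000.0,
    sample_rate_hz: float = 1000.0,
) -> np.ndarray:
    """One trial's pupil trace: sinusoidal hippus + smoothed Gaussian noise
    + an optional beep-evoked dilation (linear ramp, exponential decay)."""
    rng = _rng(seed)
    dt = 1000.0 / sample_rate_hz
    t = np.arange(0.0, trial_len_ms, dt)
    values = hippus.amplitude * np.sin(2 * np.pi * t / hippus.period_ms + phi0)
    if hippus.noise_sd > 0:
        noise = rng.normal(0.0, hippus.noise_sd, t.size)
        width = max(int(round(hippus.noise_smooth_ms / dt)), 1)
        kernel = np.ones(width) / width
        values = values + np.convolve(noise, kernel, mode="same")
    if beep_time_ms is not None and dilation_amp != 0.0:
        rel = t - beep_time_ms
        kernel_vals = np.zeros_like(rel)
        ramp = (rel >= 0) & (rel < dilation_latency_ms)
        kernel_vals[ramp] = rel[ramp] / dilation_latency_ms
        decay = rel >= dilation_latency_ms
        kernel_vals[decay] = np.exp(
            -(rel[decay] - dilation_latency_ms) / dilation_decay_ms
        )
        values = values + dilation_amp * kernel_vals
    return values


def simulate_lc_spikes(
    trial_len_ms: float,
    base_rate_hz: float,
    seed: int | np.random.Generator,
    phase_coupling: float = 0.0,
    period_ms: float = 600.0,
    lead_ms: float = 0.0,
    phi0: float = 0.0,
    beep_time_ms: float | None = None,
    responsive: bool = False,
    evoked: EvokedConfig | None = None,
    silent: bool = False,
) -> np.ndarray:
    """Inhomogeneous-Poisson LC spike times for one trial (thinning).

    Baseline rate ``base*(1 + m*cos(2*pi*(t + lead)/T + phi0))`` so the LC
    modulation peaks ``lead_ms`` before the pupil's maximum-dilation-rate
    landmark (pupil = ``sin(2*pi*t/T + phi0)``).  On responsive beep trials
    an additive burst is followed by a hard pause; ``silent`` trials carry
    no baseline spikes (zero-inflation) but still express the evoked burst.
    """
    rng = _rng(seed)
    if not 0 <= phase_coupling <= 1:
        raise ValueError("phase_coupling must be in [0, 1]")
    evoked = evoked or EvokedConfig()
    burst = beep_time_ms is not None and responsive
    rate_max = base_rate_hz * (1 + phase_coupling) + (
        evoked.burst_rate_hz if burst else 0.0
    )
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * trial_len_ms / 1000.0)
    t = rng.uniform(0.0, trial_len_ms, n)
    u = rng.uniform(0.0, rate_max, n)

    if silent:
        rate = np.zeros_like(t)
    else:
        rate = base_rate_hz * (
            1 + phase_coupling * np.cos(2 * np.pi * (t + lead_ms) / period_ms + phi0)
        )
    if beep_time_ms is not None and responsive:
        rel = t - beep_time_ms
        in_burst = (rel >= 0) & (rel < evoked.burst_dur_ms)
        in_pause = (rel >= evoked.burst_dur_ms) & (
            rel < evoked.burst_dur_ms + evoked.pause_dur_ms
        )
        rate = rate + np.where(in_burst, evoked.burst_rate_hz, 0.0)
        rate[in_pause] = 0.0
    return np.sort(t[u < rate])


# ---------------------------------------------------------------------------
# full session


def _pair_blocks(
    spec: PairSpec,
    trial: TrialRecord,
    lc_nonzero: bool,
    responsive: bool,
    cfg: SimConfig,
) -> list[tuple[float, float, float, float]]:
    """Correlation blocks ``(t0, dur, lam_private, lam_shared)`` for one
    pair on one trial.  Filler stretches are rate-matched but uncorrelated."""
    base_total = spec.lambda_private + spec.lambda_shared
    filler_rate = base_total / REFERENCE_WINDOW_MS  # counts per ms

    def filler(a: float, b: float) -> tuple[float, float, float, float] | None:
        if b - a <= 0:
            return None
        return (a, b - a, filler_rate * (b - a), 0.0)

    blocks: list[tuple[float, float, float, float] | None] = []
    if trial.beep_time is not None and spec.evoked_gate:
        pre0 = trial.beep_time - 1000.0
        key = "post_responsive" if responsive else "post_nonresponsive"
        lb_pre, lc_pre = spec.evoked_gate["pre"]
        lb_post, lc_post = spec.evoked_gate[key]
        blocks.append(filler(0.0, pre0))
        blocks.append((pre0, 1000.0, lb_pre, lc_pre))
        blocks.append((trial.beep_time, 1000.0, lb_post, lc_post))
        blocks.append(filler(trial.beep_time + 1000.0, trial.trial_end))
    elif spec.evoked_gate:
        # no-beep trial of an event-gated pair: tile the whole trial with
        # baseline ("pre") correlation blocks so that pre/post windows around
        # any virtual (fake-beep) event time are statistically exchangeable
        lb_pre, lc_pre = spec.evoked_gate["pre"]
        t = 0.0
        while t < trial.trial_end:
            dur = min(1000.0, trial.trial_end - t)
            scale = dur / 1000.0
            blocks.append((t, dur, lb_pre * scale, lc_pre * scale))
            t += dur
    else:
        if spec.lc_gate:
            lb, lc = spec.lc_gate["nonzero" if lc_nonzero else "zero"]
        else:
            lb, lc = spec.lambda_private, spec.lambda_shared
        e0 = cfg.epoch_start_ms
        e1 = e0 + cfg.epoch_duration_ms
        blocks.append(filler(0.0, e0))
        blocks.append((e0, cfg.epoch_duration_ms, lb, lc))
        blocks.append(filler(e1, trial.trial_end))
    return [b for b in blocks if b is not None]


def _phase_coupled_blocks(
    spec: PairSpec,
    trial: TrialRecord,
    phi0: float,
    cfg: SimConfig,
    block_ms: float = 200.0,
) -> list[tuple[float, float, float, float]]:
    """Tile the trial with short blocks whose shared rate follows pupil phase."""
    T = cfg.hippus.period_ms
    lb_ms = spec.lambda_private / REFERENCE_WINDOW_MS
    lc_ms = spec.lambda_shared / REFERENCE_WINDOW_MS
    edges = np.arange(0.0, trial.trial_end, block_ms)
    blocks = []
    for t0 in edges:
        dur = min(block_ms, trial.trial_end - t0)
        mid = t0 + dur / 2
        mod = 1 + spec.phase_coupling * math.cos(
            2 * np.pi * (mid + spec.phase_lead_ms) / T + phi0
        )
        blocks.append((t0, dur, lb_ms * dur, lc_ms * dur * mod))
    return blocks


def simulate_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Assemble a full synthetic session and its implied ground truth.

    Deterministic for a fixed ``config.seed``.  The LC unit is simulated
    first; each pair's stable-fixation block is then gated on the *realized*
    LC spike count in the reference window, so the conditioned-correlation
    targets hold exactly by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    trials: list[TrialRecord] = []
    beep_flags = rng.random(cfg.n_trials) < cfg.beep_fraction
    beep_delays = rng.uniform(*cfg.beep_delay_range_ms, cfg.n_trials)
    for i in range(cfg.n_trials):
        beep = (
            cfg.stable_fix_on_ms + beep_delays[i] if beep_flags[i] else None
        )
        trials.append(
            TrialRecord(
                trial_id=i,
                fix_on=cfg.fix_on_ms,
                stable_fix_on=cfg.stable_fix_on_ms,
                trial_end=cfg.trial_len_ms,
                beep_time=beep,
            )
        )

    phi0 = rng.uniform(0.0, 2 * np.pi, cfg.n_trials)
    silent = rng.random(cfg.n_trials) < cfg.lc_zero_inflation
    responsive = beep_flags & (
        rng.random(cfg.n_trials) < cfg.evoked.responsive_fraction
    )

    lc = UnitRecord(unit_id="LC_0", region="LC")
    burst_counts = np.zeros(cfg.n_trials)
    for i, trial in enumerate(trials):
        times = simulate_lc_spikes(
            cfg.trial_len_ms,
            cfg.lc_rate_hz,
            rng,
            phase_coupling=cfg.lc_phase_coupling,
            period_ms=cfg.hippus.period_ms,
            lead_ms=cfg.lc_pupil_lead_ms,
            phi0=phi0[i],
            beep_time_ms=trial.beep_time,
            responsive=bool(responsive[i]),
            evoked=cfg.evoked,
            silent=bool(silent[i]),
        )
        lc.spikes[i] = times
        if trial.beep_time is not None:
            burst_counts[i] = np.count_nonzero(
                (times >= trial.beep_time)
                & (times < trial.beep_time + cfg.evoked.burst_dur_ms)
            )

    pupil = PupilTrace(sample_rate=cfg.pupil_sample_rate_hz, t0=0.0)
    expected_burst = max(cfg.evoked.expected_burst_count, 1.0)
    for i, trial in enumerate(trials):
        amp = 0.0
        if trial.beep_time is not None:
            amp = cfg.evoked.pupil_dilation_amp * burst_counts[i] / expected_burst
        pupil.values[i] = simulate_pupil(
            cfg.trial_len_ms,
            phi0[i],
            cfg.hippus,
            rng,
            beep_time_ms=trial.beep_time,
            dilation_amp=amp,
            dilation_latency_ms=cfg.evoked.dilation_latency_ms,
            dilation_decay_ms=cfg.evoked.dilation_decay_ms,
            sample_rate_hz=cfg.pupil_sample_rate_hz,
        )

    e0, e1 = cfg.epoch_start_ms, cfg.epoch_start_ms + cfg.epoch_duration_ms
    lc_epoch_counts = {
        i: int(np.count_nonzero((lc.spikes[i] >= e0) & (lc.spikes[i] < e1)))
        for i in range(cfg.n_trials)
    }

    units = [lc]
    pair_units: list[tuple[str, str]] = []
    for p_idx, spec in enumerate(cfg.acc_pairs):
        ua = UnitRecord(unit_id=f"ACC_{2 * p_idx}", region="ACC")
        ub = UnitRecord(unit_id=f"ACC_{2 * p_idx + 1}", region="ACC")
        for i, trial in enumerate(trials):
            if spec.phase_coupling > 0:
                blocks = _phase_coupled_blocks(spec, trial, phi0[i], cfg)
            else:
                blocks = _pair_blocks(
                    spec, trial, lc_epoch_counts[i] > 0, bool(responsive[i]), cfg
                )
            parts_a, parts_b = [], []
            for t0, dur, lb, lsh in blocks:
                a, b = _correlated_block(lb, lsh, t0, dur, rng)
                parts_a.append(a)
                parts_b.append(b)
            ua.spikes[i] = np.sort(np.concatenate(parts_a))
            ub.spikes[i] = np.sort(np.concatenate(parts_b))
        units.extend([ua, ub])
        pair_units.append((ua.unit_id, ub.unit_id))

    session = Session(
        session_id=f"synthetic-{cfg.seed}",
        units=units,
        trials=trials,
        pupil=pupil,
        meta={
            "generator": "lcacc.synth",
            "seed": cfg.seed,
            "n_trials": cfg.n_trials,
        },
    ).validate()

    target_rsc = []
    for spec in cfg.acc_pairs:
        targets = {"all": PairSpec.rsc(spec.lambda_private, spec.lambda_shared)}
        if spec.lc_gate:
            for key, (lb, lsh) in spec.lc_gate.items():
                targets[key] = PairSpec.rsc(lb, lsh)
        else:
            targets["zero"] = targets["nonzero"] = targets["all"]
        if spec.evoked_gate:
            for key, (lb, lsh) in spec.evoked_gate.items():
                targets[key] = PairSpec.rsc(lb, lsh)
        target_rsc.append(targets)

    truth = GroundTruth(
        config=replace(cfg),
        target_rsc=target_rsc,
        hippus_period_ms=cfg.hippus.period_ms,
        lc_lead_ms=cfg.lc_pupil_lead_ms,
        expected_fano=1.0,
        beep_trials=[i for i in range(cfg.n_trials) if beep_flags[i]],
        responsive_trials=[i for i in range(cfg.n_trials) if responsive[i]],
        silent_lc_trials=[i for i in range(cfg.n_trials) if silent[i]],
        lc_epoch_counts=lc_epoch_counts,
        pair_units=pair_units,
    )
    return session, truth
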