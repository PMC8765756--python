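"""Session data model, on-disk format, and stable-fixation epoch extraction.

A :class:`Session` bundles everything recorded in one sitting: spike times of
units labelled by region (LC or ACC), per-trial event times, and a continuously
sampled pupil-diameter trace.  All times are in milliseconds relative to trial
start; pupil diameter is in arbitrary units (it is never calibrated).

The on-disk format is a directory holding a JSON manifest plus three CSV
tables (trials, spikes, pupil) so that sessions are inspectable with any
text tool and round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "PupilTrace",
    "Session",
    "SessionFormatError",
    "SessionValidationError",
    "TrialRecord",
    "UnitRecord",
    "extract_stable_fixation_epochs",
    "read_session",
    "write_session",
]

REGIONS = ("LC", "ACC")


class SessionValidationError(ValueError):
    """A session violates a structural invariant (names the trial/unit)."""


class SessionFormatError(ValueError):
    """On-disk session directory is malformed or incomplete."""


@dataclass
class TrialRecord:
    """Event times for one fixation trial, in ms relative to trial start.

    ``beep_time`` is present only on trials where a startle sound was played;
    ``gaze_ok`` is the upstream gaze quality-control summary (fixation held
    within the required window for the whole stable-fixation period).
    """

    trial_id: int
    fix_on: float
    stable_fix_on: float
    trial_end: float
    beep_time: float | None = None
    gaze_ok: bool = True

    def validate(self) -> None:
        if not (self.fix_on < self.stable_fix_on < self.trial_end):
            raise SessionValidationError(
                f"trial {self.trial_id}: require fix_on < stable_fix_on < trial_end, "
                f"got {self.fix_on}, {self.stable_fix_on}, {self.trial_end}"
            )
        if self.beep_time is not None and not (
            self.stable_fix_on < self.beep_time < self.trial_end
        ):
            raise SessionValidationError(
                f"trial {self.trial_id}: beep_time {self.beep_time} outside "
                f"({self.stable_fix_on}, {self.trial_end})"
            )


@dataclass
class UnitRecord:
    """One sorted unit: region label plus per-trial spike-time arrays."""

    unit_id: str
    region: str
    spikes: dict[int, np.ndarray] = field(default_factory=dict)

    def spike_times(self, trial_id: int) -> np.ndarray:
        return self.spikes.get(trial_id, np.empty(0))

    def validate(self, trials: dict[int, TrialRecord]) -> None:
        if self.region not in REGIONS:
            raise SessionValidationError(
                f"unit {self.unit_id}: region {self.region!r} not in {REGIONS}"
            )
        for trial_id, times in self.spikes.items():
            if trial_id not in trials:
                raise SessionValidationError(
                    f"unit {self.unit_id}: spikes reference unknown trial {trial_id}"
                )
            t = np.asarray(times, dtype=float)
            if t.size and np.any(np.diff(t) < 0):
                raise SessionValidationError(
                    f"unit {self.unit_id}, trial {trial_id}: spike times not sorted"
                )
            end = trials[trial_id].trial_end
            if t.size and (t[0] < 0 or t[-1] > end):
                bad = t[(t < 0) | (t > end)][0]
                raise SessionValidationError(
                    f"unit {self.unit_id}, trial {trial_id}: spike at {bad} ms "
                    f"outside [0, {end}]"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnitRecord):
            return NotImplemented
        if (self.unit_id, self.region) != (other.unit_id, other.region):
            return False
        a = {k: v for k, v in self.spikes.items() if len(v)}
        b = {k: v for k, v in other.spikes.items() if len(v)}
        return a.keys() == b.keys() and all(
            np.array_equal(a[k], b[k]) for k in a
        )


@dataclass
class PupilTrace:
    """Uniformly sampled pupil diameter, one array per trial.

    ``t0`` is the time of the first sample relative to trial start.
    """

    sample_rate: float = 1000.0
    t0: float = 0.0
    values: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def trial_values(self, trial_id: int) -> np.ndarray:
        return self.values.get(trial_id, np.empty(0))

    def sample_times(self, trial_id: int) -> np.ndarray:
        n = len(self.values.get(trial_id, ()))
        return self.t0 + np.arange(n) * self.dt_ms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PupilTrace):
            return NotImplemented
        if (self.sample_rate, self.t0) != (other.sample_rate, other.t0):
            return False
        return self.values.keys() == other.values.keys() and all(
            np.array_equal(self.values[k], other.values[k]) for k in self.values
        )


@dataclass
class Epoch:
    """A counting window inside one trial (start and duration in ms)."""

    trial_id: int
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class Session:
    session_id: str
    units: list[UnitRecord] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)
    pupil: PupilTrace = field(default_factory=PupilTrace)
    meta: dict = field(default_factory=dict)

    def validate(self) -> "Session":
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise SessionValidationError("duplicate trial ids")
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise SessionValidationError("trial ids not strictly increasing")
        for t in self.trials:
            t.validate()
        trial_map = self.trial_map()
        seen: set[str] = set()
        for u in self.units:
            if u.unit_id in seen:
                raise SessionValidationError(f"duplicate unit id {u.unit_id}")
            seen.add(u.unit_id)
            u.validate(trial_map)
        for trial_id in self.pupil.values:
            if trial_id not in trial_map:
                raise SessionValidationError(
                    f"pupil trace references unknown trial {trial_id}"
                )
        return self

    def trial_map(self) -> dict[int, TrialRecord]:
        return {t.trial_id: t for t in self.trials}

    def units_by_region(self, region: str) -> list[UnitRecord]:
        return [u for u in self.units if u.region == region]

    def unit(self, unit_id: str) -> UnitRecord:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def extract_stable_fixation_epochs(
    session: Session, offset_ms: float = 1000.0, duration_ms: float = 1100.0
) -> list[Epoch]:
    """Stable-fixation counting windows: ``duration_ms`` starting ``offset_ms``
    after stable fixation was attained.

    Trials whose gaze QC failed, or that end before the window does, are
    excluded.  Defaults implement the 1.1 s window beginning 1 s after
    attaining fixation.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    epochs = []
    for t in session.trials:
        start = t.stable_fix_on + offset_ms
        if t.gaze_ok and start + duration_ms <= t.trial_end:
            epochs.append(Epoch(t.trial_id, start, duration_ms))
    return epochs


# ---------------------------------------------------------------------------
# On-disk format: manifest.json + trials.csv + spikes.csv + pupil.csv

_MANIFEST = "manifest.json"
_TABLES = ("trials.csv", "spikes.csv", "pupil.csv")


def write_session(session: Session, path: str | Path) -> Path:
    """Write a validated session to ``path`` (a directory, created if needed).

    Output is deterministic: equal sessions produce byte-identical files.
    """
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format": "lcacc-session-v1",
        "session_id": session.session_id,
        "meta": session.meta,
        "units": [
            {"unit_id": u.unit_id, "region": u.region} for u in session.units
        ],
        "pupil": {
            "sample_rate": session.pupil.sample_rate,
            "t0": session.pupil.t0,
        },
    }
    (path / _MANIFEST).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )

    trials = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in session.trials],
            "fix_on": [t.fix_on for t in session.trials],
            "stable_fix_on": [t.stable_fix_on for t in session.trials],
            "beep_time": [t.beep_time for t in session.trials],
            "trial_end": [t.trial_end for t in session.trials],
            "gaze_ok": [t.gaze_ok for t in session.trials],
        }
    )
    trials.to_csv(path / "trials.csv", index=False)

    rows_t, rows_u, rows_s = [], [], []
    for u in session.units:
        for trial_id in sorted(u.spikes):
            times = u.spikes[trial_id]
            rows_t.extend([trial_id] * len(times))
            rows_u.extend([u.unit_id] * len(times))
            rows_s.extend(float(x) for x in times)
    pd.DataFrame(
        {"trial_id": rows_t, "unit_id": rows_u, "time_ms": rows_s}
    ).to_csv(path / "spikes.csv", index=False)

    rows = []
    for trial_id in sorted(session.pupil.values):
        vals = session.pupil.values[trial_id]
        rows.append(
            pd.DataFrame(
                {
                    "trial_id": trial_id,
                    "sample_index": np.arange(len(vals)),
                    "value": vals,
                }
            )
        )
    pupil = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["trial_id", "sample_index", "value"])
    )
    pupil.to_csv(path / "pupil.csv", index=False)
    return path


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`SessionFormatError` for missing/malformed files and
    :class:`SessionValidationError` when the parsed session violates an
    invariant.
    """
    path = Path(path)
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise SessionFormatError(f"missing {_MANIFEST} in {path}")
    for name in _TABLES:
        if not (path / name).exists():
            raise SessionFormatError(f"missing table {name} in {path}")
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"malformed manifest: {exc}") from exc
    for key in ("session_id", "units", "pupil"):
        if key not in manifest:
            raise SessionFormatError(f"manifest missing key {key!r}")

    trials_df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    trials = [
        TrialRecord(
            trial_id=int(r.trial_id),
            fix_on=float(r.fix_on),
            stable_fix_on=float(r.stable_fix_on),
            trial_end=float(r.trial_end),
            beep_time=None if pd.isna(r.beep_time) else float(r.beep_time),
            gaze_ok=bool(r.gaze_ok),
        )
        for r in trials_df.itertuples()
    ]

    spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    units = []
    for entry in manifest["units"]:
        u = UnitRecord(unit_id=str(entry["unit_id"]), region=str(entry["region"]))
        sub = spikes_df[spikes_df.unit_id == entry["unit_id"]]
        for trial_id, grp in sub.groupby("trial_id"):
            u.spikes[int(trial_id)] = grp.time_ms.to_numpy(dtype=float)
        units.append(u)

    pupil_df = pd.read_csv(path / "pupil.csv", float_precision="round_trip")
    pupil = PupilTrace(
        sample_rate=float(manifest["pupil"]["sample_rate"]),
        t0=float(manifest["pupil"].get("t0", 0.0)),
    )
    for trial_id, grp in pupil_df.groupby("trial_id"):
        grp = grp.sort_values("sample_index")
        pupil.values[int(trial_id)] = grp.value.to_numpy(dtype=float)

    session = Session(
        session_id=str(manifest["session_id"]),
        units=units,
        trials=trials,
        pupil=pupil,
        meta=dict(manifest.get("meta", {})),
    )
    return session.validate()
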