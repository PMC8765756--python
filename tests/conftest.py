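import numpy as np
import pytest

from lcacc import synth
from lcacc.session import PupilTrace, Session, TrialRecord, UnitRecord


def small_session() -> Session:
    """Hand-built two-trial session touching every record type."""
    u_lc = UnitRecord(
        unit_id="LC_0",
        region="LC",
        spikes={0: np.array([100.0, 400.0]), 1: np.array([250.0])},
    )
    u_acc = UnitRecord(
        unit_id="ACC_0", region="ACC", spikes={0: np.array([50.0, 60.0, 900.0])}
    )
    trials = [
        TrialRecord(trial_id=0, fix_on=0.0, stable_fix_on=200.0, trial_end=4000.0),
        TrialRecord(
            trial_id=1,
            fix_on=0.0,
            stable_fix_on=150.0,
            trial_end=3500.0,
            beep_time=1500.0,
            gaze_ok=False,
        ),
    ]
    pupil = PupilTrace(
        sample_rate=500.0,
        t0=0.0,
        values={0: np.linspace(0, 1, 20), 1: np.zeros(10)},
    )
    return Session(
        session_id="séance-1",  # unicode id on purpose
        units=[u_lc, u_acc],
        trials=trials,
        pupil=pupil,
        meta={"monkey": "synthetic"},
    ).validate()


@pytest.fixture
def tiny_session() -> Session:
    return small_session()


@pytest.fixture(scope="session")
def gated_session():
    """Synthetic session whose shared ACC rate is gated by LC spiking."""
    gate = {"zero": (2.8, 1.2), "nonzero": (3.6, 0.4)}
    cfg = synth.SimConfig(
        n_trials=400,
        acc_pairs=[synth.PairSpec(lc_gate=gate) for _ in range(40)],
        seed=101,
    )
    session, truth = synth.simulate_session(cfg)
    return session, truth
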