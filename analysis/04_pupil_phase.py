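#!/usr/bin/env python
"""Pupil-phase-triggered LC spiking and ACC correlation maps.

Simulates sessions in which the LC rate follows the hippus with a 270 ms
lead (and, for the correlation map, an ACC pair whose shared rate is
phase-coupled), detects hippus cycles, assigns the four-landmark phase,
builds phase-triggered maps, and fits precession lines to their extrema.
For a 600 ms hippus the analytic slope is -360/600 = -0.6 deg/ms and the
fitted line's zero-phase time recovers the imposed lead.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from lcacc import synth
from lcacc.pupil_phase import (
    fit_phase_slope,
    phase_triggered_rate_map,
    phase_triggered_rsc_map,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0
PERIOD_MS = 600.0
LEAD_MS = 270.0


def main() -> None:
    cfg = synth.SimConfig(
        n_trials=300,
        trial_len_ms=3000.0,
        beep_fraction=0.0,
        acc_pairs=[
            synth.PairSpec(
                lambda_private=3.0,
                lambda_shared=1.0,
                phase_coupling=0.8,
                phase_lead_ms=LEAD_MS,
            )
        ],
        lc_rate_hz=2.0,
        lc_zero_inflation=0.0,
        lc_phase_coupling=1.0,
        lc_pupil_lead_ms=LEAD_MS,
        hippus=synth.HippusConfig(period_ms=PERIOD_MS),
        seed=SEED,
    )
    session, _ = synth.simulate_session(cfg)

    rate_map = phase_triggered_rate_map(session, "LC_0")
    rate_fit = fit_phase_slope(rate_map, mode="peaks")
    rsc_map = phase_triggered_rsc_map(
        session, ("ACC_0", "ACC_1"), window_ms=300.0, phase_bin_deg=30.0
    )

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        rate_map.values,
        index=pd.Index(rate_map.offsets_ms, name="offset_ms"),
        columns=rate_map.phase_centers_deg,
    ).to_csv(RESULTS / "phase_map_lc_rate.csv")
    pd.DataFrame(
        rsc_map.values,
        index=pd.Index(rsc_map.offsets_ms, name="offset_ms"),
        columns=rsc_map.phase_centers_deg,
    ).to_csv(RESULTS / "phase_map_acc_rsc.csv")
    pd.DataFrame(
        [
            {
                "signal": "lc_rate",
                "slope_deg_per_ms": rate_fit.slope_deg_per_ms,
                "zero_phase_time_ms": rate_fit.zero_phase_time_ms,
                "p_value": rate_fit.p_value,
                "reliable": rate_fit.reliable,
            }
        ]
    ).to_csv(RESULTS / "phase_fits.csv", index=False)

    print(f"hippus period {PERIOD_MS:.0f} ms, imposed LC lead {LEAD_MS:.0f} ms")
    print(f"  LC rate map: fitted slope {rate_fit.slope_deg_per_ms:+.3f} deg/ms "
          f"(analytic {-360 / PERIOD_MS:+.2f}), zero-phase time "
          f"{rate_fit.zero_phase_time_ms:.0f} ms, slope-vs-0 p = "
          f"{rate_fit.p_value:.2e}")
    row = rsc_map.values[np.where(rsc_map.offsets_ms == 0.0)[0][0]]
    peak = rsc_map.phase_centers_deg[np.nanargmax(row)]
    print(f"  ACC r_sc map at offset 0: max r {np.nanmax(row):.3f} at phase "
          f"{peak:.0f} deg, min r {np.nanmin(row):.3f} (shared-rate "
          "modulation expressed in the correlation map)")


if __name__ == "__main__":
    main()
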