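#!/usr/bin/env python
"""Single-unit ACC statistics conditioned on simultaneous LC spiking.

Counts ACC spikes in five equally spaced windows (200 ms to 1 s) anchored
at the stable-fixation epoch, partitions trials by the LC unit's spike
count (0/1/2/3/4+ and the zero vs nonzero split), and tabulates per-unit
mean, variance, and Fano factor per condition with sign-rank tests on the
(nonzero - zero) differences.  Because the generator trades shared for
private rate at a fixed total, the expected differences are zero — the
rate-independence property of the conditioned-correlation effect.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import importlib

import pandas as pd

from lcacc.inference import signrank_test
from lcacc.session import extract_stable_fixation_epochs
from lcacc.spike_stats import (
    conditioned_stat_difference,
    difference_relations,
    linear_spaced_bin_sizes,
    make_count_table,
    partition_trials_by_partner,
)

simulate = importlib.import_module("01_simulate")
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    from lcacc import synth

    session, truth = synth.simulate_session(simulate.build_config())
    epochs = extract_stable_fixation_epochs(session)
    no_beep = {t.trial_id for t in session.trials if t.beep_time is None}
    epochs = [e for e in epochs if e.trial_id in no_beep]

    lc_tab = make_count_table(
        session, epochs, 1100.0, units=session.units_by_region("LC")
    )
    labels = partition_trials_by_partner(
        lc_tab.unit_counts("LC_0"), lc_tab.trial_ids
    )
    acc_units = session.units_by_region("ACC")
    tables = [
        make_count_table(session, epochs, b, units=acc_units)
        for b in linear_spaced_bin_sizes()
    ]
    stats = conditioned_stat_difference(tables, labels)
    relations = difference_relations(stats)

    RESULTS.mkdir(exist_ok=True)
    stats.to_csv(RESULTS / "conditioned_stats.csv", index=False)
    relations.to_csv(RESULTS / "conditioned_stat_relations.csv", index=False)

    print(f"conditioned single-unit statistics: {len(acc_units)} ACC units, "
          f"{len(epochs)} no-beep epochs")
    rows = []
    for (bin_ms, stat), sub in stats.groupby(["bin_size_ms", "statistic"]):
        d = sub.difference.dropna()
        p = signrank_test(d.to_numpy()).p_value if len(d) >= 5 else float("nan")
        rows.append({"bin_size_ms": bin_ms, "statistic": stat,
                     "median_difference": d.median(), "signrank_p": p})
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "conditioned_stats_summary.csv", index=False)
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    n_sig = (summary.signrank_p < 0.05).sum()
    print(f"\nfinding: {n_sig}/{len(summary)} bin x statistic combinations "
          "show a reliable LC-linked difference (expected ~none: the "
          "generator preserves single-unit rates across conditions)")


if __name__ == "__main__":
    main()
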