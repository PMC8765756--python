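"""Binned spike counts and conditioned single-unit statistics.

Spikes are counted in a single half-open window ``[start, start + bin)``
per trial, anchored at the stable-fixation epoch start.  Trials are
partitioned by the *partner* region's spike count in the reference window
(0 / 1 / 2 / 3 / 4+ plus the derived zero vs nonzero split), and per-unit
mean, variance, and Fano factor are compared across those conditions.

The partner groups are spike counts in the 1.1 s reference window: the
zero group is literally "no spikes", so the 0/1/2/3/4+ labels are counts,
not rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import Epoch, Session, UnitRecord

__all__ = [
    "CountTable",
    "LcGroupLabel",
    "conditioned_stat_difference",
    "count_spikes",
    "count_stats",
    "linear_spaced_bin_sizes",
    "log_spaced_bin_sizes",
    "make_count_table",
    "partition_trials_by_partner",
]

GROUP_NAMES = ("0", "1", "2", "3", "4+")


def log_spaced_bin_sizes(
    min_ms: float = 100.0, max_ms: float = 1000.0, n: int = 10
) -> np.ndarray:
    """Geometric sequence of counting-window durations, endpoints exact."""
    if not 0 < min_ms < max_ms or n < 2:
        raise ValueError("require 0 < min_ms < max_ms and n >= 2")
    return np.geomspace(min_ms, max_ms, n)


def linear_spaced_bin_sizes(
    min_ms: float = 200.0, max_ms: float = 1000.0, n: int = 5
) -> np.ndarray:
    """Arithmetic sequence of counting-window durations, endpoints exact."""
    if not 0 < min_ms < max_ms or n < 2:
        raise ValueError("require 0 < min_ms < max_ms and n >= 2")
    return np.linspace(min_ms, max_ms, n)


def count_spikes(spikes: np.ndarray, epoch: Epoch, bin_size_ms: float) -> int:
    """Spike count in ``[epoch.start, epoch.start + bin_size)`` (half-open)."""
    if bin_size_ms > epoch.duration:
        raise ValueError(
            f"bin size {bin_size_ms} exceeds epoch duration {epoch.duration}"
        )
    t = np.asarray(spikes, dtype=float)
    return int(np.count_nonzero((t >= epoch.start) & (t < epoch.start + bin_size_ms)))


@dataclass
class CountTable:
    """Trials x units spike-count matrix for one bin size and alignment."""

    bin_size_ms: float
    alignment: str  # "stable_fix" or "beep"
    counts: pd.DataFrame  # index trial_id, columns unit_id, integer counts

    @property
    def trial_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def unit_ids(self) -> list[str]:
        return list(self.counts.columns)

    def unit_counts(self, unit_id: str) -> np.ndarray:
        return self.counts[unit_id].to_numpy()


def make_count_table(
    session: Session,
    epochs: list[Epoch],
    bin_size_ms: float,
    units: list[UnitRecord] | None = None,
    alignment: str = "stable_fix",
) -> CountTable:
    """Count each unit's spikes in one window per epoch."""
    units = session.units if units is None else units
    data = {}
    trial_ids = [e.trial_id for e in epochs]
    for u in units:
        data[u.unit_id] = [
            count_spikes(u.spike_times(e.trial_id), e, bin_size_ms) for e in epochs
        ]
    counts = pd.DataFrame(data, index=pd.Index(trial_ids, name="trial_id"))
    return CountTable(bin_size_ms=bin_size_ms, alignment=alignment, counts=counts)


def count_stats(counts: np.ndarray) -> tuple[float, float, float]:
    """Mean, sample variance (n-1), and Fano factor of a count vector.

    Fano is NaN (undefined) when the mean is 0.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 trials")
    mean = float(c.mean())
    var = float(c.var(ddof=1))
    fano = var / mean if mean > 0 else float("nan")
    return mean, var, fano


@dataclass
class LcGroupLabel:
    """Per-trial partner-region condition labels.

    ``group`` holds "0"/"1"/"2"/"3"/"4+" per trial; ``nonzero`` is the
    derived binary complement of the zero group.
    """

    trial_ids: np.ndarray
    group: np.ndarray  # str labels, parallel to trial_ids
    partner_counts: np.ndarray = field(repr=False, default=None)

    @property
    def nonzero(self) -> np.ndarray:
        return self.group != "0"

    def trials_in(self, condition: str) -> np.ndarray:
        """Trial ids for a named condition ("zero", "nonzero", or a group)."""
        if condition == "zero":
            mask = self.group == "0"
        elif condition == "nonzero":
            mask = self.nonzero
        elif condition == "all":
            mask = np.ones(len(self.group), dtype=bool)
        elif condition in GROUP_NAMES:
            mask = self.group == condition
        else:
            raise KeyError(condition)
        return self.trial_ids[mask]


def partition_trials_by_partner(
    partner_counts: np.ndarray, trial_ids: np.ndarray | None = None
) -> LcGroupLabel:
    """Label trials by the partner unit's count: 0, 1, 2, 3, or 4+."""
    counts = np.asarray(partner_counts)
    if trial_ids is None:
        trial_ids = np.arange(counts.size)
    group = np.where(
        counts >= 4, "4+", counts.astype(int).astype(str)
    )
    return LcGroupLabel(
        trial_ids=np.asarray(trial_ids), group=group, partner_counts=counts
    )


def conditioned_stat_difference(
    tables: list[CountTable],
    labels: LcGroupLabel,
    min_trials: int = 5,
) -> pd.DataFrame:
    """Per-unit mean/variance/Fano in the zero and nonzero conditions.

    One row per unit x bin size x statistic with the value in each condition
    and their difference (nonzero - zero).  Units whose conditions fall below
    ``min_trials`` are flagged missing rather than dropped.
    """
    zero_ids = set(labels.trials_in("zero"))
    nonzero_ids = set(labels.trials_in("nonzero"))
    rows = []
    for table in tables:
        tid = table.trial_ids
        mask_zero = np.array([t in zero_ids for t in tid])
        mask_nonzero = np.array([t in nonzero_ids for t in tid])
        enough = mask_zero.sum() >= min_trials and mask_nonzero.sum() >= min_trials
        for unit in table.unit_ids:
            counts = table.unit_counts(unit)
            if enough:
                stats_zero = count_stats(counts[mask_zero])
                stats_nonzero = count_stats(counts[mask_nonzero])
            else:
                stats_zero = stats_nonzero = (np.nan, np.nan, np.nan)
            for stat, vz, vn in zip(
                ("mean", "variance", "fano"), stats_zero, stats_nonzero
            ):
                rows.append(
                    {
                        "unit_id": unit,
                        "bin_size_ms": table.bin_size_ms,
                        "statistic": stat,
                        "value_zero": vz,
                        "value_nonzero": vn,
                        "difference": vn - vz,
                        "missing": not enough,
                    }
                )
    return pd.DataFrame(rows)


def difference_relations(conditioned: pd.DataFrame) -> pd.DataFrame:
    """Across-unit pairwise relations among the per-unit differences.

    Returns Spearman correlations between each pair of difference
    distributions (mean vs variance, mean vs fano, variance vs fano),
    per bin size.
    """
    from scipy import stats as sps

    rows = []
    for bin_size, sub in conditioned.groupby("bin_size_ms"):
        wide = sub.pivot(index="unit_id", columns="statistic", values="difference")
        wide = wide.dropna()
        for a, b in (("mean", "variance"), ("mean", "fano"), ("variance", "fano")):
            if len(wide) >= 3:
                rho, p = sps.spearmanr(wide[a], wide[b])
            else:
                rho, p = np.nan, np.nan
            rows.append(
                {
                    "bin_size_ms": bin_size,
                    "pair": f"d{a}_vs_d{b}",
                    "spearman_rho": rho,
                    "p_value": p,
                    "n_units": len(wide),
                }
            )
    return pd.DataFrame(rows)
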