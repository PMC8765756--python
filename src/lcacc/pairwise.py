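"""Pairwise spike-count correlations (r_sc) with preprocessing and controls.

For each pair, condition, and bin size: the two count vectors are z-scored,
trials on which either z-score exceeds 3 SD in magnitude are removed in a
single pass, and the Pearson correlation of the surviving counts is taken.
Controls: a trial-shuffle null (independent random trial selection per
neuron destroys the trial pairing) and a rank-based tercile partition of
the condition-independent r_sc values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spike_stats import CountTable, LcGroupLabel, count_stats

__all__ = [
    "RscRecord",
    "conditioned_rsc",
    "rsc",
    "remove_outlier_trials",
    "shuffled_null",
    "spike_count_correlation",
    "tercile_partition",
    "zscore_counts",
]

DEFAULT_MIN_TRIALS = 5
DEFAULT_OUTLIER_SD = 3.0


def zscore_counts(counts: np.ndarray) -> np.ndarray:
    """Z-score a count vector (sample SD); all-NaN when the SD is zero."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 trials")
    sd = c.std(ddof=1)
    if sd == 0:
        return np.full(c.size, np.nan)
    return (c - c.mean()) / sd


def remove_outlier_trials(
    z_a: np.ndarray, z_b: np.ndarray, threshold: float = DEFAULT_OUTLIER_SD
) -> np.ndarray:
    """Keep-mask after one-pass outlier removal.

    A trial is dropped iff either z-magnitude is *strictly* greater than
    ``threshold``, with z-scores computed once from the full condition.
    Constant vectors (z undefined) remove nothing.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape:
        raise ValueError("length mismatch")
    ok_a = np.where(np.isnan(z_a), True, np.abs(z_a) <= threshold)
    ok_b = np.where(np.isnan(z_b), True, np.abs(z_b) <= threshold)
    return ok_a & ok_b


def spike_count_correlation(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Pearson correlation of two count vectors; NaN if either is constant."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class RscRecord:
    pair_id: tuple[str, str]
    bin_size_ms: float
    condition: str
    r: float  # NaN flags an undefined / missing record
    n_trials_used: int
    n_outliers_removed: int


def rsc(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    min_trials: int = DEFAULT_MIN_TRIALS,
    outlier_threshold: float = DEFAULT_OUTLIER_SD,
) -> tuple[float, int, int]:
    """Full r_sc preprocessing chain: z-score, outlier removal, Pearson.

    Returns ``(r, n_used, n_removed)`` with ``r = NaN`` when fewer than
    ``min_trials`` trials survive or a vector is constant.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size < 2:
        return float("nan"), a.size, 0
    keep = remove_outlier_trials(zscore_counts(a), zscore_counts(b), outlier_threshold)
    n_removed = int((~keep).sum())
    a, b = a[keep], b[keep]
    if a.size < min_trials:
        return float("nan"), int(a.size), n_removed
    return spike_count_correlation(a, b), int(a.size), n_removed


def shuffled_null(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_shuffles: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Correlations from independently permuted trial orders of each vector."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = spike_count_correlation(rng.permutation(a), rng.permutation(b))
    return out


def shuffle_count_table(table: CountTable, seed: int | np.random.Generator) -> CountTable:
    """Independently permute each unit's counts across trials.

    Destroys the trial pairing between neurons (and any conditioning on
    simultaneously recorded activity) while preserving every marginal count
    distribution — the control used to verify that conditioned correlation
    differences are not artifacts of single-neuron statistics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = table.counts.copy()
    for col in shuffled.columns:
        shuffled[col] = rng.permutation(shuffled[col].to_numpy())
    return CountTable(
        bin_size_ms=table.bin_size_ms,
        alignment=table.alignment,
        counts=shuffled,
    )


def tercile_partition(values: np.ndarray) -> np.ndarray:
    """Rank-based split into terciles 1/2/3 (low/middle/high).

    Ties are broken by stable input order; sizes differ by at most one,
    with extras assigned to the lower terciles (n=7 -> sizes 3, 2, 2).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(v.size, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(v.size, dtype=int)
    start = 0
    for tercile, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = tercile
        start += size
    return labels


def conditioned_rsc(
    tables: list[CountTable],
    pairs: list[tuple[str, str]],
    labels: LcGroupLabel,
    conditions: tuple[str, ...] = ("all", "zero", "nonzero", "1", "2", "3", "4+"),
    min_trials: int = DEFAULT_MIN_TRIALS,
    outlier_threshold: float = DEFAULT_OUTLIER_SD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """r_sc per pair x bin size x partner-spiking condition, plus differences.

    Returns ``(records, diffs)``:

    * ``records``: one row per :class:`RscRecord` (condition "all" is the
      partner-independent r_sc used for terciles);
    * ``diffs``: per pair and bin size, the (nonzero - zero) difference in
      r_sc together with the matching differences in the pair's mean firing
      and Fano factor (averaged over the two units), and the tercile of the
      partner-independent r_sc.

    z-scoring and outlier removal happen within the trial set actually being
    correlated (per condition).
    """
    records = []
    diff_rows = []
    for table in tables:
        tid = table.trial_ids
        cond_masks = {
            cond: np.isin(tid, labels.trials_in(cond)) for cond in conditions
        }
        per_pair: dict[tuple[str, str], dict[str, float]] = {}
        for pair in pairs:
            a_all = table.unit_counts(pair[0])
            b_all = table.unit_counts(pair[1])
            values = {}
            for cond, mask in cond_masks.items():
                a, b = a_all[mask], b_all[mask]
                if a.size >= 2:
                    r, n_used, n_rm = rsc(a, b, min_trials, outlier_threshold)
                else:
                    r, n_used, n_rm = float("nan"), int(a.size), 0
                records.append(
                    RscRecord(pair, table.bin_size_ms, cond, r, n_used, n_rm)
                )
                values[cond] = r
            per_pair[pair] = values
            if {"zero", "nonzero"} <= set(conditions):
                stats = {}
                for cond in ("zero", "nonzero"):
                    mask = cond_masks[cond]
                    if mask.sum() >= max(min_trials, 2):
                        ma, _, fa = count_stats(a_all[mask])
                        mb, _, fb = count_stats(b_all[mask])
                        stats[cond] = ((ma + mb) / 2, (fa + fb) / 2)
                    else:
                        stats[cond] = (np.nan, np.nan)
                diff_rows.append(
                    {
                        "pair_a": pair[0],
                        "pair_b": pair[1],
                        "bin_size_ms": table.bin_size_ms,
                        "rsc_all": values.get("all", np.nan),
                        "rsc_zero": values.get("zero", np.nan),
                        "rsc_nonzero": values.get("nonzero", np.nan),
                        "delta_rsc": values.get("nonzero", np.nan)
                        - values.get("zero", np.nan),
                        "delta_rate": stats["nonzero"][0] - stats["zero"][0],
                        "delta_fano": stats["nonzero"][1] - stats["zero"][1],
                    }
                )

    records_df = pd.DataFrame(
        {
            "pair_a": [r.pair_id[0] for r in records],
            "pair_b": [r.pair_id[1] for r in records],
            "bin_size_ms": [r.bin_size_ms for r in records],
            "condition": [r.condition for r in records],
            "r": [r.r for r in records],
            "n_trials_used": [r.n_trials_used for r in records],
            "n_outliers_removed": [r.n_outliers_removed for r in records],
        }
    )
    diffs_df = pd.DataFrame(diff_rows)
    if not diffs_df.empty:
        # tercile of the partner-independent r_sc, per bin size
        terciles = np.full(len(diffs_df), -1)
        for _, idx in diffs_df.groupby("bin_size_ms").groups.items():
            vals = diffs_df.loc[idx, "rsc_all"].to_numpy()
            if np.isfinite(vals).all() and vals.size >= 3:
                terciles[diffs_df.index.get_indexer(idx)] = tercile_partition(vals)
        diffs_df["tercile"] = terciles
    return records_df, diffs_df


def shuffle_summary(null_r: np.ndarray) -> dict[str, float]:
    """Mean/SD of a shuffle-null correlation distribution."""
    finite = null_r[np.isfinite(null_r)]
    return {
        "mean": float(finite.mean()) if finite.size else float("nan"),
        "sd": float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
        "n": int(finite.size),
    }


def compare_difference_distributions(
    diffs_a: np.ndarray, diffs_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS comparison of two difference distributions.

    Used to ask whether, e.g., LC-linked ACC r_sc differences and
    ACC-linked LC r_sc differences come from the same distribution.
    """
    a = diffs_a[np.isfinite(diffs_a)]
    b = diffs_b[np.isfinite(diffs_b)]
    stat, p = sps.ks_2samp(a, b)
    return float(stat), float(p)
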