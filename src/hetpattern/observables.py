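"""Pattern statistics of simulated filaments.

The heterocyst pattern is summarized by the distribution of vegetative
intervals (runs of vegetative cells bounded by heterocysts on both sides),
the heterocyst percentage, contiguous-heterocyst cluster sizes, the number of
terminal heterocysts, and the mean HetR level over vegetative cells.

Replicate simulations are pooled into batches (default 15 batches of 10
runs); statistics are computed per batch and the across-batch mean and sample
standard deviation mimic experimental replicate error bars.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_core import FilamentState
from .simulate import Trajectory

__all__ = [
    "SummaryStats",
    "BatchResult",
    "vegetative_intervals",
    "heterocyst_percentage",
    "cluster_sizes",
    "terminal_heterocyst_count",
    "mean_hetr_vegetative",
    "ks_distance",
    "summarize_filaments",
    "batch_statistics",
]


def _het_array(filament) -> np.ndarray:
    if isinstance(filament, FilamentState):
        return filament.is_heterocyst
    return np.asarray(filament, dtype=bool)


def vegetative_intervals(filament) -> List[int]:
    """Lengths of vegetative runs flanked by heterocysts on both sides.

    Runs touching a filament end are excluded: experimental interval counts
    are between-heterocyst distances.  Accepts a FilamentState or a boolean
    heterocyst mask.
    """
    het = _het_array(filament)
    idx = np.flatnonzero(het)
    if idx.size < 2:
        return []
    gaps = np.diff(idx) - 1
    return [int(g) for g in gaps if g > 0]


def heterocyst_percentage(filament) -> float:
    """Heterocysts as a percentage of all cells."""
    het = _het_array(filament)
    if het.size == 0:
        raise ValueError("empty filament")
    return 100.0 * float(het.sum()) / het.size


def cluster_sizes(filament) -> Dict[int, int]:
    """Histogram {run length: count} of maximal contiguous heterocyst runs."""
    het = _het_array(filament)
    out: Counter = Counter()
    run = 0
    for h in het:
        if h:
            run += 1
        elif run:
            out[run] += 1
            run = 0
    if run:
        out[run] += 1
    return dict(out)


def terminal_heterocyst_count(filament) -> int:
    """Contiguous heterocysts at the two filament ends, summed.

    A fully heterocystous filament counts every cell exactly once.
    """
    het = _het_array(filament)
    n = het.size
    left = 0
    while left < n and het[left]:
        left += 1
    if left == n:
        return n
    right = 0
    while right < n and het[n - 1 - right]:
        right += 1
    return left + right


def mean_hetr_vegetative(filament: FilamentState) -> float:
    """Mean HetR concentration over vegetative cells (nan if none)."""
    veg = ~filament.is_heterocyst
    if not np.any(veg):
        return float("nan")
    return float(filament.conc[veg, 0].mean())


def ks_distance(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov–Smirnov distance sup |ECDF_A - ECDF_B|."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_distance requires two nonempty samples")
    return float(sps.ks_2samp(a, b, method="asymp").statistic)


@dataclass
class SummaryStats:
    """Pooled pattern statistics for one condition at one time."""

    interval_histogram: Dict[int, int] = field(default_factory=dict)
    m: float = float("nan")  # mean vegetative cells between heterocysts
    p: float = float("nan")  # heterocyst percentage
    cluster_histogram: Dict[int, int] = field(default_factory=dict)
    terminal_count: float = 0.0  # mean terminal heterocysts per filament
    mean_R_veg: float = float("nan")
    intervals: List[int] = field(default_factory=list)  # raw pooled sample

    def __post_init__(self) -> None:
        if self.interval_histogram and not self.intervals:
            self.intervals = [
                k for k, c in sorted(self.interval_histogram.items()) for _ in range(c)
            ]
        if self.intervals and np.isnan(self.m):
            self.m = float(np.mean(self.intervals))
        if not np.isnan(self.p) and not (0.0 <= self.p <= 100.0):
            raise ValueError("heterocyst percentage must lie in [0, 100]")


def summarize_filaments(filaments: Sequence[FilamentState]) -> SummaryStats:
    """Pool the pattern statistics of a group of filaments."""
    if not filaments:
        raise ValueError("empty group of filaments")
    intervals: List[int] = []
    clusters: Counter = Counter()
    n_cells = 0
    n_het = 0
    term = 0
    r_sum = 0.0
    r_n = 0
    for f in filaments:
        intervals.extend(vegetative_intervals(f))
        clusters.update(cluster_sizes(f))
        n_cells += f.n_cells
        n_het += f.n_heterocysts
        term += terminal_heterocyst_count(f)
        veg = ~f.is_heterocyst
        r_sum += float(f.conc[veg, 0].sum())
        r_n += int(veg.sum())
    hist = dict(Counter(intervals))
    return SummaryStats(
        interval_histogram=hist,
        m=float(np.mean(intervals)) if intervals else float("nan"),
        p=100.0 * n_het / n_cells,
        cluster_histogram=dict(clusters),
        terminal_count=term / len(filaments),
        mean_R_veg=r_sum / r_n if r_n else float("nan"),
        intervals=intervals,
    )


_SCALAR_STATS = ("m", "p", "terminal_count", "mean_R_veg")


@dataclass
class BatchResult:
    """Per-batch summaries plus across-batch mean and sample SD."""

    per_batch: List[SummaryStats]
    mean: Dict[str, float]
    sd: Dict[str, float]
    pooled: SummaryStats  # everything pooled across batches

    @property
    def n_batches(self) -> int:
        return len(self.per_batch)


def batch_statistics(
    batches: Sequence[Sequence[FilamentState]],
) -> BatchResult:
    """Aggregate filaments within each batch, then average across batches.

    The across-batch dispersion is the sample (n-1) standard deviation, the
    replicate-based convention of experimental error bars; with a single
    batch the SD is reported as 0.
    """
    if not batches or any(len(b) == 0 for b in batches):
        raise ValueError("every batch must be nonempty")
    per = [summarize_filaments(b) for b in batches]
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    for name in _SCALAR_STATS:
        vals = np.array([getattr(s, name) for s in per], dtype=float)
        ok = vals[~np.isnan(vals)]
        mean[name] = float(ok.mean()) if ok.size else float("nan")
        sd[name] = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    pooled = summarize_filaments([f for b in batches for f in b])
    return BatchResult(per_batch=per, mean=mean, sd=sd, pooled=pooled)


def trajectories_at_time(trajectories: Iterable[Trajectory], t: float) -> List[FilamentState]:
    """Snapshot each trajectory at (the snapshot closest to) time t."""
    return [tr.at_time(t) for tr in trajectories]


def summary_dataframe(
    result: BatchResult, condition: str, time_h: float
) -> pd.DataFrame:
    """Long-format summary table: condition, time_h, batch, statistic, value."""
    rows = []
    for i, s in enumerate(result.per_batch):
        for name in _SCALAR_STATS:
            rows.append((condition, time_h, i, name, getattr(s, name)))
    return pd.DataFrame(rows, columns=["condition", "time_h", "batch", "statistic", "value"])


def histogram_dataframe(
    stats: SummaryStats, condition: str, time_h: float, which: str = "interval"
) -> pd.DataFrame:
    """Histogram table (interval lengths or cluster sizes) for CSV export."""
    hist = stats.interval_histogram if which == "interval" else stats.cluster_histogram
    col = "interval_length" if which == "interval" else "cluster_size"
    rows = [(condition, time_h, k, c) for k, c in sorted(hist.items())]
    return pd.DataFrame(rows, columns=["condition", "time_h", col, "count"])
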