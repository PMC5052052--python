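"""Per-electrode burst detection by the max-interval method.

A burst is a rapid cluster of spikes on a single electrode.  The detector
is the fixed-parameter max-interval algorithm used throughout the
multiwell-MEA literature:

1. a burst *begins* at a spike whose following inter-spike interval (ISI)
   is <= ``max_begin_isi_s``;
2. the burst *extends* over subsequent spikes while ISIs stay
   <= ``max_end_isi_s``;
3. bursts whose separating gap (end of one to start of the next) is
   < ``min_ibi_s`` are merged;
4. bursts shorter than ``min_duration_s`` or with fewer than
   ``min_spikes`` spikes are discarded.

When two bursts merge, every spike between the merged start and end —
including any spikes in the bridged gap — belongs to the merged burst:
burst membership is interval membership.  Within one electrode the
returned bursts are non-overlapping and time-ordered, and no spike
belongs to two bursts.

Default parameters (begin 0.1 s, end 0.25 s, min IBI 0.8 s, min duration
0.05 s, min 5 spikes) follow the common parameterisation of this
algorithm family for cortical cultures; all five are configurable because
appropriate values are preparation-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["BurstParams", "Burst", "BurstSummary", "detect_bursts", "summarize_bursts", "bursts_to_table"]


@dataclass(frozen=True)
class BurstParams:
    max_begin_isi_s: float = 0.1
    max_end_isi_s: float = 0.25
    min_ibi_s: float = 0.8
    min_duration_s: float = 0.05
    min_spikes: int = 5

    def __post_init__(self) -> None:
        for name in ("max_begin_isi_s", "max_end_isi_s", "min_ibi_s", "min_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be >= 1")
        if self.max_end_isi_s < self.max_begin_isi_s:
            raise ValueError("max_end_isi_s must be >= max_begin_isi_s")


@dataclass(frozen=True)
class Burst:
    """One detected burst: spike indices [first, last] on its electrode."""

    electrode_id: str
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _candidate_bounds(t: np.ndarray, params: BurstParams) -> tuple[np.ndarray, np.ndarray]:
    """Spike-index bounds of pre-merge burst candidates (rules 1-2).

    Candidates are maximal runs of consecutive ISIs <= max_end_isi_s,
    trimmed at the front to the first spike whose following ISI is
    <= max_begin_isi_s; runs containing no such spike yield no burst.
    """
    isi = np.diff(t)
    ok_end = isi <= params.max_end_isi_s
    if not ok_end.any():
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    edges = np.diff(ok_end.astype(np.int8))
    run_starts = np.flatnonzero(edges == 1) + 1
    run_ends = np.flatnonzero(edges == -1)  # inclusive isi index
    if ok_end[0]:
        run_starts = np.concatenate(([0], run_starts))
    if ok_end[-1]:
        run_ends = np.concatenate((run_ends, [len(isi) - 1]))
    # first begin-qualifying ISI within each run
    begin_pos = np.flatnonzero(isi <= params.max_begin_isi_s)
    if begin_pos.size == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    first_in_run = np.searchsorted(begin_pos, run_starts, side="left")
    has_begin = (first_in_run < len(begin_pos)) & (
        begin_pos[np.minimum(first_in_run, len(begin_pos) - 1)] <= run_ends
    )
    starts = begin_pos[np.minimum(first_in_run, len(begin_pos) - 1)][has_begin]
    ends = run_ends[has_begin] + 1  # spike index of the run's last spike
    return starts, ends


def detect_bursts(
    spike_times: Sequence[float] | np.ndarray,
    params: BurstParams = BurstParams(),
    electrode_id: str = "",
) -> list[Burst]:
    """Detect bursts in one electrode's sorted spike-time train.

    Raises ``ValueError`` on unsorted input; an empty train yields an
    empty list.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted ascending")

    starts, ends = _candidate_bounds(t, params)
    if starts.size == 0:
        return []

    # rule 3: merge candidates separated by < min_ibi_s (chained)
    if starts.size > 1:
        gaps = t[starts[1:]] - t[ends[:-1]]
        new_group = np.concatenate(([True], gaps >= params.min_ibi_s))
        group = np.cumsum(new_group) - 1
        first = np.flatnonzero(new_group)
        last = np.concatenate((first[1:] - 1, [starts.size - 1]))
        starts = starts[first]
        ends = ends[last]

    # rule 4: size/duration filter (after merging)
    n_spikes = ends - starts + 1
    duration = t[ends] - t[starts]
    keep = (n_spikes >= params.min_spikes) & (duration >= params.min_duration_s)
    return [
        Burst(electrode_id=electrode_id, start_s=float(t[s]), end_s=float(t[e]),
              n_spikes=int(e - s + 1))
        for s, e in zip(starts[keep], ends[keep])
    ]


@dataclass
class BurstSummary:
    """Well-level burst statistics over the active electrodes of one day.

    ``burst_rate_per_min`` is normalised per active electrode; IBIs (gap
    from one burst's end to the next burst's start on the same electrode)
    are pooled across the well's active electrodes.  All fields are NaN
    when the well has no active electrodes (missing, not zero).
    """

    burst_rate_per_min: float
    mean_burst_duration_s: float
    inter_burst_intervals_s: list[float]
    pct_spikes_in_bursts: float
    spikes_per_burst: float

    @property
    def mean_ibi_s(self) -> float:
        if not self.inter_burst_intervals_s:
            return math.nan
        return float(np.mean(self.inter_burst_intervals_s))


def summarize_bursts(
    bursts_by_electrode: Mapping[str, Sequence[Burst]],
    spike_counts: Mapping[str, int],
    duration_s: float,
    active_set: frozenset[str] | set[str],
) -> BurstSummary:
    """Summarise per-electrode bursts into one well-day record.

    Only electrodes in ``active_set`` contribute; ``spike_counts`` gives
    each active electrode's total spike count (denominator for the
    percentage of spikes in bursts).
    """
    n_active = len(active_set)
    if n_active == 0:
        return BurstSummary(math.nan, math.nan, [], math.nan, math.nan)
    total_spikes = sum(spike_counts.get(e, 0) for e in active_set)
    all_bursts: list[Burst] = []
    ibis: list[float] = []
    for elec in sorted(active_set):
        bl = list(bursts_by_electrode.get(elec, ()))
        all_bursts.extend(bl)
        for prev, nxt in zip(bl, bl[1:]):
            ibis.append(nxt.start_s - prev.end_s)
    n_bursts = len(all_bursts)
    rate = n_bursts / n_active / (duration_s / 60.0)
    spikes_in = sum(b.n_spikes for b in all_bursts)
    if total_spikes == 0:
        pct = math.nan
    else:
        pct = 100.0 * spikes_in / total_spikes
    mean_dur = float(np.mean([b.duration_s for b in all_bursts])) if n_bursts else math.nan
    spb = spikes_in / n_bursts if n_bursts else math.nan
    return BurstSummary(
        burst_rate_per_min=rate,
        mean_burst_duration_s=mean_dur,
        inter_burst_intervals_s=ibis,
        pct_spikes_in_bursts=pct,
        spikes_per_burst=spb,
    )


def bursts_to_table(
    bursts_by_electrode: Mapping[str, Sequence[Burst]], div: int, well_id: str
) -> pd.DataFrame:
    """Flatten one well-day's bursts into the export table schema
    (div, well, electrode, start_s, end_s, n_spikes, duration_s) used for
    raster-style rendering."""
    rows = [
        (div, well_id, elec, b.start_s, b.end_s, b.n_spikes, b.duration_s)
        for elec in sorted(bursts_by_electrode)
        for b in bursts_by_electrode[elec]
    ]
    return pd.DataFrame(
        rows,
        columns=["div", "well_id", "electrode_id", "start_s", "end_s", "n_spikes", "duration_s"],
    )
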