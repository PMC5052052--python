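"""Well-level synchronous network-event detection.

A *network spike* is a short episode in which at least
``min_participants`` distinct electrodes of one well (default 16, i.e.
25% of a 64-electrode well) fire within the same time bin; consecutive
qualifying bins merge into one event.  A *network burst* is a maximal
interval during which at least ``min_participants`` electrodes are
simultaneously inside an electrode-level burst.  Events recruiting fewer
electrodes are filtered out.

Participation is counted by distinct electrodes, never by spike counts.
The network-spike bin width defaults to 25 ms, a typical population-spike
window for multiwell MEA work; it is exposed because appropriate values
are preparation-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bursts import Burst

__all__ = [
    "NetworkParams",
    "NetworkEvent",
    "NetworkSummary",
    "detect_network_spikes",
    "detect_network_bursts",
    "summarize_network_events",
    "events_to_table",
]


@dataclass(frozen=True)
class NetworkParams:
    """Parameters for network-event detection.

    ``min_participants`` defaults to 16 (25% of 64 electrodes); use
    :meth:`for_layout` to keep the 25% semantics on other layouts.
    ``nb_merge_gap_s`` is the gap below which adjacent network bursts
    merge; the default 0 disables merging.
    """

    min_participants: int = 16
    ns_bin_s: float = 0.025
    nb_merge_gap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.min_participants < 1:
            raise ValueError("min_participants must be >= 1")
        if self.ns_bin_s <= 0:
            raise ValueError("ns_bin_s must be positive")
        if self.nb_merge_gap_s < 0:
            raise ValueError("nb_merge_gap_s must be non-negative")

    @classmethod
    def for_layout(cls, electrodes_per_well: int, **kwargs) -> "NetworkParams":
        return cls(
            min_participants=math.ceil(0.25 * electrodes_per_well), **kwargs
        )


@dataclass(frozen=True)
class NetworkEvent:
    kind: str  # "network-spike" | "network-burst"
    start_s: float
    end_s: float
    participants: frozenset[str]
    n_spikes_in_event: int

    @property
    def n_participants(self) -> int:
        return len(self.participants)


def detect_network_spikes(
    spike_times: Sequence[float] | np.ndarray,
    electrode_ids: Sequence[str] | np.ndarray,
    active_set: frozenset[str] | set[str],
    params: NetworkParams = NetworkParams(),
) -> list[NetworkEvent]:
    """Detect network spikes in one well's spike train.

    The time axis is partitioned into half-open bins
    ``[k*ns_bin_s, (k+1)*ns_bin_s)``; a bin with spikes from at least
    ``min_participants`` distinct active electrodes is a candidate, and
    runs of consecutive qualifying bins merge into one event whose
    participants are the union over its bins.  Event bounds are the outer
    bin edges of the merged run.
    """
    t = np.asarray(spike_times, dtype=float)
    e = pd.Series(electrode_ids)
    if t.size != len(e):
        raise ValueError("spike_times and electrode_ids must have equal length")
    if t.size == 0:
        return []
    keep = e.isin(active_set).to_numpy()
    t, e = t[keep], e[keep].reset_index(drop=True)
    if t.size == 0:
        return []
    bins = np.floor(t / params.ns_bin_s).astype(np.int64)
    df = pd.DataFrame({"bin": bins, "elec": e.to_numpy(dtype=object), "t": t})
    per_bin = df.groupby("bin")["elec"].nunique()
    qual = per_bin[per_bin >= params.min_participants].index.to_numpy()
    if qual.size == 0:
        return []
    # merge runs of consecutive qualifying bins
    new_run = np.concatenate(([True], np.diff(qual) > 1))
    run_id = np.cumsum(new_run) - 1
    events: list[NetworkEvent] = []
    qual_set = df["bin"].isin(qual)
    sub = df[qual_set]
    bin_to_run = dict(zip(qual, run_id))
    sub_runs = sub["bin"].map(bin_to_run)
    for rid, rsub in sub.groupby(sub_runs):
        b0 = qual[run_id == rid].min()
        b1 = qual[run_id == rid].max()
        events.append(
            NetworkEvent(
                kind="network-spike",
                start_s=float(b0 * params.ns_bin_s),
                end_s=float((b1 + 1) * params.ns_bin_s),
                participants=frozenset(rsub["elec"]),
                n_spikes_in_event=int(len(rsub)),
            )
        )
    events.sort(key=lambda ev: ev.start_s)
    return events


def detect_network_bursts(
    bursts_by_electrode: Mapping[str, Sequence[Burst]],
    active_set: frozenset[str] | set[str],
    params: NetworkParams = NetworkParams(),
) -> list[NetworkEvent]:
    """Detect network bursts from per-electrode burst intervals.

    A boundary sweep over burst start/end times finds maximal intervals
    during which >= ``min_participants`` electrodes are simultaneously
    inside a burst (burst intervals are closed, so a burst ending exactly
    when another starts still overlaps at that instant).  Intervals whose
    separating gap is < ``nb_merge_gap_s`` merge.  The spike count of an
    event is the total over participating bursts that overlap it.
    """
    intervals = [
        (b.start_s, b.end_s, elec, b.n_spikes)
        for elec in sorted(active_set)
        for b in bursts_by_electrode.get(elec, ())
    ]
    if not intervals:
        return []
    # boundary sweep; at equal times starts are processed before ends
    marks = []
    for s, e0, _, _ in intervals:
        marks.append((s, 0, 1))
        marks.append((e0, 1, -1))
    marks.sort()
    bounds: list[tuple[float, float]] = []
    depth = 0
    cur_start: float | None = None
    for time, _, delta in marks:
        depth += delta
        if cur_start is None and depth >= params.min_participants:
            cur_start = time
        elif cur_start is not None and depth < params.min_participants:
            bounds.append((cur_start, time))
            cur_start = None
    if cur_start is not None:  # cannot happen with balanced marks, kept defensive
        bounds.append((cur_start, marks[-1][0]))
    if not bounds:
        return []
    # optional merge of nearby intervals
    if params.nb_merge_gap_s > 0:
        merged = [list(bounds[0])]
        for s, e0 in bounds[1:]:
            if s - merged[-1][1] < params.nb_merge_gap_s:
                merged[-1][1] = max(merged[-1][1], e0)
            else:
                merged.append([s, e0])
        bounds = [(s, e0) for s, e0 in merged]
    events = []
    for s, e0 in bounds:
        parts = set()
        n_spk = 0
        for bs, be, elec, n in intervals:
            if bs <= e0 and be >= s:
                parts.add(elec)
                n_spk += n
        events.append(
            NetworkEvent(
                kind="network-burst",
                start_s=float(s),
                end_s=float(e0),
                participants=frozenset(parts),
                n_spikes_in_event=int(n_spk),
            )
        )
    return events


@dataclass
class NetworkSummary:
    """Well-day network-event statistics.

    ``pct_spikes_in_network_events`` is the percentage of active-electrode
    spikes falling inside any event's [start_s, end_s]; NaN when the well
    recorded no spikes on active electrodes.
    """

    n_network_spikes: int
    network_burst_rate_per_s: float
    pct_spikes_in_network_events: float


def summarize_network_events(
    events: Sequence[NetworkEvent],
    spike_times_active: Sequence[float] | np.ndarray,
    duration_s: float,
) -> NetworkSummary:
    """Summarise one well-day's network events.

    ``spike_times_active`` are the spike times on active electrodes; they
    are needed (rather than a bare count) to test each spike against the
    event intervals for the percentage feature.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    t = np.asarray(spike_times_active, dtype=float)
    n_spikes = sum(1 for ev in events if ev.kind == "network-spike")
    nb = [ev for ev in events if ev.kind == "network-burst"]
    rate_nb = len(nb) / duration_s
    if t.size == 0:
        pct = math.nan
    elif not events:
        pct = 0.0
    else:
        inside = np.zeros(t.size, dtype=bool)
        for ev in events:
            inside |= (t >= ev.start_s) & (t <= ev.end_s)
        pct = 100.0 * inside.sum() / t.size
    return NetworkSummary(
        n_network_spikes=n_spikes,
        network_burst_rate_per_s=rate_nb,
        pct_spikes_in_network_events=pct,
    )


def events_to_table(
    events: Sequence[NetworkEvent], div: int, well_id: str
) -> pd.DataFrame:
    """Flatten events into the export schema
    (div, well, kind, start_s, end_s, n_participants)."""
    rows = [
        (div, well_id, ev.kind, ev.start_s, ev.end_s, ev.n_participants)
        for ev in sorted(events, key=lambda ev: (ev.start_s, ev.kind))
    ]
    return pd.DataFrame(
        rows, columns=["div", "well_id", "kind", "start_s", "end_s", "n_participants"]
    )
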