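"""Per-well per-day activity feature table.

One row per (included well, DIV) with the activity features the group
statistics consume: number of active electrodes, mean firing rate (MFR)
normalised to the number of active electrodes, burst rate and duration,
mean inter-burst interval, network spike count and network-burst rate,
and the percentages of spikes in bursts and in network events.

Days on which an included well has zero active electrodes keep their row
but carry missing values (NaN), never zeros: an inactive day is absence
of evidence, not evidence of silence at rate zero.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .bursts import BurstParams, detect_bursts, summarize_bursts, bursts_to_table
from .io import GroupAssignment, Recording
from .network import (
    NetworkParams,
    detect_network_bursts,
    detect_network_spikes,
    summarize_network_events,
    events_to_table,
)
from .qc import ActivityMask

__all__ = [
    "FEATURE_COLUMNS",
    "ACTIVITY_FEATURES",
    "compute_well_features",
    "compute_feature_table",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_COLUMNS = [
    "div",
    "well_id",
    "condition",
    "n_active_electrodes",
    "mfr_hz",
    "burst_rate_per_min",
    "mean_burst_duration_s",
    "mean_ibi_s",
    "n_network_spikes",
    "network_burst_rate_per_s",
    "pct_spikes_in_bursts",
    "pct_spikes_in_network_events",
]

#: Feature columns carrying activity measurements (everything except keys).
ACTIVITY_FEATURES = FEATURE_COLUMNS[3:]


def compute_well_features(
    recording: Recording,
    mask: ActivityMask,
    assignment: GroupAssignment | None = None,
    burst_params: BurstParams = BurstParams(),
    network_params: NetworkParams | None = None,
    *,
    collect_events: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Compute the feature rows for one recording day.

    Only wells in ``mask.included_wells`` appear, and every computation
    is restricted to that day's active electrode set.  With
    ``collect_events=True`` the per-electrode burst table and the
    network-event table for the day are returned as well (the raster
    export inputs).
    """
    div = recording.div
    if div not in mask.active:
        raise ValueError(f"mask has no entry for div {div}")
    net_params = network_params or NetworkParams.for_layout(
        recording.layout.electrodes_per_well
    )
    rows = []
    burst_tables = []
    event_tables = []
    # one pass over the event frame instead of a scan per well
    by_well = {
        str(w): sub for w, sub in recording.events.groupby("well_id", observed=True)
    }
    empty = recording.events.iloc[0:0]
    for well in recording.layout.well_ids:
        if well not in mask.included_wells:
            continue
        if assignment is not None and well not in assignment:
            continue
        cond = assignment.condition_of(well) if assignment is not None else ""
        active = mask.active_set(div, well)
        row: dict = {"div": div, "well_id": well, "condition": cond}
        row["n_active_electrodes"] = len(active)
        if len(active) == 0:
            for col in ACTIVITY_FEATURES[1:]:
                row[col] = math.nan
            rows.append(row)
            continue
        wev = by_well.get(well, empty)
        on_active = wev[wev["electrode_id"].isin(active)]
        total_spikes = len(on_active)
        row["mfr_hz"] = total_spikes / recording.duration_s / len(active)

        bursts_by_electrode = {}
        spike_counts = {}
        for elec, sub in on_active.groupby("electrode_id", sort=True, observed=True):
            t = sub["time_s"].to_numpy()
            spike_counts[str(elec)] = len(t)
            bursts_by_electrode[str(elec)] = detect_bursts(
                t, burst_params, electrode_id=str(elec)
            )
        bs = summarize_bursts(
            bursts_by_electrode, spike_counts, recording.duration_s, active
        )
        row["burst_rate_per_min"] = bs.burst_rate_per_min
        row["mean_burst_duration_s"] = bs.mean_burst_duration_s
        row["mean_ibi_s"] = bs.mean_ibi_s
        row["pct_spikes_in_bursts"] = bs.pct_spikes_in_bursts

        ns_events = detect_network_spikes(
            on_active["time_s"].to_numpy(),
            on_active["electrode_id"].to_numpy(),
            active,
            net_params,
        )
        nb_events = detect_network_bursts(bursts_by_electrode, active, net_params)
        summ = summarize_network_events(
            ns_events + nb_events, on_active["time_s"].to_numpy(), recording.duration_s
        )
        row["n_network_spikes"] = summ.n_network_spikes
        row["network_burst_rate_per_s"] = summ.network_burst_rate_per_s
        row["pct_spikes_in_network_events"] = summ.pct_spikes_in_network_events
        rows.append(row)
        if collect_events:
            burst_tables.append(bursts_to_table(bursts_by_electrode, div, well))
            event_tables.append(events_to_table(ns_events + nb_events, div, well))

    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if not collect_events:
        return table
    burst_tables = [t for t in burst_tables if len(t)]
    event_tables = [t for t in event_tables if len(t)]
    bt = (
        pd.concat(burst_tables, ignore_index=True)
        if burst_tables
        else bursts_to_table({}, div, "").iloc[0:0]
    )
    et = (
        pd.concat(event_tables, ignore_index=True)
        if event_tables
        else events_to_table([], div, "").iloc[0:0]
    )
    return table, bt, et


def compute_feature_table(
    recordings: Mapping[int, Recording],
    mask: ActivityMask,
    assignment: GroupAssignment | None = None,
    burst_params: BurstParams = BurstParams(),
    network_params: NetworkParams | None = None,
) -> pd.DataFrame:
    """Feature rows for every recording day, sorted by (div, well)."""
    parts = [
        compute_well_features(
            recordings[div], mask, assignment, burst_params, network_params
        )
        for div in sorted(recordings)
    ]
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=FEATURE_COLUMNS)
    return out.sort_values(["div", "well_id"], kind="mergesort").reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the feature table as CSV with the stable canonical column
    order; missing values are written as empty fields."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    table[FEATURE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table, checking the schema; missing values come back
    as NaN (never silently as 0)."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table at {path} missing columns: {missing}")
    df["well_id"] = df["well_id"].astype(str)
    df["condition"] = df["condition"].fillna("").astype(str)
    return df[FEATURE_COLUMNS]
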