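"""Spike-list ingestion and the core recording data model.

Multiwell MEA acquisition systems (e.g. the Axion Maestro) perform spike
detection on-device and export a *spike list*: one CSV row per detected
spike carrying a timestamp, a well/electrode identifier and, optionally,
the spike amplitude.  This module reads and writes that format, validates
it against a plate layout, and defines the in-memory containers the rest
of the pipeline consumes.

Column names vary between acquisition-software versions, so the reader is
driven by a :class:`SpikeListDialect` mapping logical fields to file
headers.  The default dialect expects ``Time (s)``, ``Electrode`` (a
combined ``A1_12``-style well_electrode token) and ``Amplitude(mV)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PlateLayout",
    "SpikeListDialect",
    "Recording",
    "GroupAssignment",
    "SpikeListFormatError",
    "SpikeListRowError",
    "read_spikelist",
    "write_spikelist",
    "read_group_assignment",
    "write_group_assignment",
]

#: Column order of the canonical in-memory event frame.
EVENT_COLUMNS = ["time_s", "well_id", "electrode_id", "amplitude_mV"]


class SpikeListFormatError(ValueError):
    """The file as a whole does not conform to the expected dialect."""


class SpikeListRowError(ValueError):
    """One or more rows are invalid (raised only in strict mode)."""


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of the recording plate.

    The default is a 12-well plate (rows A-C, columns 1-4) with 64
    electrodes per well on an 8x8 grid labelled ``"11"``..``"88"``
    (row digit then column digit).  Arbitrary well lists are allowed so
    that multi-plate experiments can be pooled into one layout.
    """

    well_ids: tuple[str, ...]
    electrode_ids: tuple[str, ...]

    @property
    def n_wells(self) -> int:
        return len(self.well_ids)

    @property
    def electrodes_per_well(self) -> int:
        return len(self.electrode_ids)

    @property
    def total_electrodes(self) -> int:
        return self.n_wells * self.electrodes_per_well

    def __post_init__(self) -> None:
        if len(set(self.well_ids)) != len(self.well_ids):
            raise ValueError("duplicate well ids in layout")
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValueError("duplicate electrode ids in layout")

    @classmethod
    def default_12well(cls) -> "PlateLayout":
        wells = tuple(f"{r}{c}" for r in "ABC" for c in range(1, 5))
        electrodes = tuple(f"{r}{c}" for r in range(1, 9) for c in range(1, 9))
        return cls(well_ids=wells, electrode_ids=electrodes)

    @classmethod
    def multi_plate(cls, n_wells: int) -> "PlateLayout":
        """Layout for ``n_wells`` wells spread over as many 12-well plates
        as needed; well ids are plate-prefixed, e.g. ``"P2-B3"``."""
        single = cls.default_12well()
        wells = []
        plate = 1
        while len(wells) < n_wells:
            for w in single.well_ids:
                wells.append(f"P{plate}-{w}")
                if len(wells) == n_wells:
                    break
            plate += 1
        return cls(well_ids=tuple(wells), electrode_ids=single.electrode_ids)


@dataclass(frozen=True)
class SpikeListDialect:
    """Mapping from logical spike-list fields to CSV headers.

    ``electrode_col`` holds a combined well/electrode token which is split
    on ``separator`` (``"A1_12"`` -> well ``A1``, electrode ``12``).
    """

    time_col: str = "Time (s)"
    electrode_col: str = "Electrode"
    amplitude_col: str = "Amplitude(mV)"
    separator: str = "_"

    def required_columns(self) -> tuple[str, ...]:
        return (self.time_col, self.electrode_col)


DEFAULT_DIALECT = SpikeListDialect()


@dataclass
class Recording:
    """All spikes detected on one plate during one recording session.

    Parameters
    ----------
    div
        Day in vitro of the recording (positive integer).
    duration_s
        Nominal recording length in seconds.  This is a configured
        constant (default 900 s = 15 min), never inferred from the last
        spike time: rate denominators must not shrink on quiet days.
    events
        DataFrame with columns ``time_s``, ``well_id``, ``electrode_id``,
        ``amplitude_mV``, sorted non-decreasing in ``time_s``.
    layout
        Plate geometry the events were validated against.
    n_rejected_rows
        Rows dropped during lenient parsing (0 for programmatic input).
    """

    div: int
    duration_s: float
    events: pd.DataFrame
    layout: PlateLayout
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        if self.div < 1:
            raise ValueError(f"div must be a positive integer, got {self.div}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events frame missing columns: {missing}")
        ev = self.events
        if len(ev) and not ev["time_s"].is_monotonic_increasing:
            ev = ev.sort_values("time_s", kind="mergesort").reset_index(drop=True)
            self.events = ev
        t = ev["time_s"].to_numpy()
        if len(t) and (t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("spike times must lie within [0, duration_s]")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def well(self, well_id: str) -> pd.DataFrame:
        """Events of one well (a view-like slice, time-sorted)."""
        if well_id not in self.layout.well_ids:
            raise KeyError(f"unknown well {well_id!r}")
        return self.events[self.events["well_id"] == well_id]

    def spike_counts(self) -> pd.DataFrame:
        """Spike counts per (well, electrode) over the full layout grid."""
        counts = (
            self.events.groupby(["well_id", "electrode_id"], sort=False, observed=True)
            .size()
            .rename("n_spikes")
            .reset_index()
        )
        return counts


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping from well id to experimental condition label."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    def condition_of(self, well_id: str) -> str:
        return self.mapping[well_id]

    def conditions(self) -> list[str]:
        """Distinct condition labels, sorted for determinism."""
        return sorted(set(self.mapping.values()))

    def wells(self, condition: str) -> list[str]:
        return sorted(w for w, c in self.mapping.items() if c == condition)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, well_id: str) -> bool:
        return well_id in self.mapping


def _split_tokens(
    tokens: pd.Series, dialect: SpikeListDialect
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Split combined well_electrode tokens; returns (well, electrode, ok)."""
    parts = tokens.astype(str).str.split(dialect.separator, n=1)
    ok = parts.str.len() == 2
    well = parts.str[0].where(ok, other="")
    elec = parts.str[1].where(ok, other="")
    return well, elec, ok


def read_spikelist(
    path: str | Path,
    div: int,
    *,
    dialect: SpikeListDialect = DEFAULT_DIALECT,
    layout: PlateLayout | None = None,
    duration_s: float = 900.0,
    strict: bool = False,
) -> Recording:
    """Read a spike-list CSV into a :class:`Recording`.

    Rows whose timestamp cannot be parsed or whose well/electrode is not
    in ``layout`` are rejected: in strict mode this raises
    :class:`SpikeListRowError` naming the offending line numbers; in
    lenient mode (the default, appropriate for real acquisition exports)
    the rows are dropped, counted in ``Recording.n_rejected_rows`` and a
    warning is emitted.
    """
    path = Path(path)
    layout = layout or PlateLayout.default_12well()
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    for col in dialect.required_columns():
        if col not in df.columns:
            raise SpikeListFormatError(
                f"{path.name}: required column {col!r} not found "
                f"(columns present: {list(df.columns)})"
            )
    if df.empty:
        warnings.warn(f"{path.name}: spike list contains no data rows")
        events = pd.DataFrame(columns=EVENT_COLUMNS).astype({"time_s": float})
        return Recording(div=div, duration_s=duration_s, events=events, layout=layout)

    def parse_float(series: pd.Series) -> pd.Series:
        # Python's float() is correctly rounded; pandas' fast parser is not
        def conv(x: str) -> float:
            try:
                return float(x)
            except ValueError:
                return math.nan

        return series.map(conv)

    # +2: header line plus 1-based numbering
    lineno = df.index.to_numpy() + 2
    times = parse_float(df[dialect.time_col])
    bad_time = times.isna().to_numpy()
    if strict and bad_time.any():
        raise SpikeListRowError(
            f"{path.name}: unparseable timestamp on line(s) "
            f"{lineno[bad_time][:10].tolist()}"
        )

    well, elec, split_ok = _split_tokens(df[dialect.electrode_col], dialect)
    known = (
        split_ok.to_numpy()
        & well.isin(layout.well_ids).to_numpy()
        & elec.isin(layout.electrode_ids).to_numpy()
    )
    if strict and not known.all():
        raise SpikeListRowError(
            f"{path.name}: well/electrode outside layout on line(s) "
            f"{lineno[~known][:10].tolist()}"
        )
    in_range = (~bad_time) & (times.to_numpy() >= 0) & (times.to_numpy() <= duration_s)
    if strict and not in_range[~bad_time].all():
        bad = lineno[(~in_range) & (~bad_time)]
        raise SpikeListRowError(
            f"{path.name}: spike time outside [0, {duration_s}] on line(s) "
            f"{bad[:10].tolist()}"
        )

    keep = (~bad_time) & known & in_range
    n_rejected = int((~keep).sum())
    if n_rejected:
        warnings.warn(f"{path.name}: dropped {n_rejected} invalid row(s)")

    amp = (
        parse_float(df[dialect.amplitude_col])
        if dialect.amplitude_col in df.columns
        else pd.Series(np.nan, index=df.index)
    )
    events = pd.DataFrame(
        {
            "time_s": times[keep].astype(float).to_numpy(),
            "well_id": well[keep].to_numpy(),
            "electrode_id": elec[keep].to_numpy(),
            "amplitude_mV": amp[keep].astype(float).to_numpy(),
        }
    )
    events = events.sort_values("time_s", kind="mergesort").reset_index(drop=True)
    return Recording(
        div=div,
        duration_s=duration_s,
        events=events,
        layout=layout,
        n_rejected_rows=n_rejected,
    )


def write_spikelist(
    recording: Recording,
    path: str | Path,
    *,
    dialect: SpikeListDialect = DEFAULT_DIALECT,
) -> Path:
    """Write a :class:`Recording` back to spike-list CSV.

    Round-trip guarantee: ``read_spikelist(write_spikelist(r))`` reproduces
    ``r``'s events exactly (time, well, electrode, amplitude).  Missing
    amplitudes are written as blank fields.
    """
    path = Path(path)
    ev = recording.events
    token = ev["well_id"].astype(str) + dialect.separator + ev["electrode_id"].astype(str)
    out = pd.DataFrame(
        {
            dialect.time_col: ev["time_s"].map(lambda t: np.format_float_positional(t, trim="0")),
            dialect.electrode_col: token,
            dialect.amplitude_col: ev["amplitude_mV"].map(
                lambda a: "" if pd.isna(a) else np.format_float_positional(a, trim="0")
            ),
        }
    )
    out.to_csv(path, index=False)
    return path


def read_group_assignment(
    path: str | Path, *, layout: PlateLayout | None = None
) -> GroupAssignment:
    """Read a two-column (well_id, condition) CSV into a GroupAssignment.

    Duplicate well rows with the same condition collapse to one entry;
    duplicates with conflicting conditions are an error naming the well.
    Wells absent from ``layout`` (when given) trigger a warning only.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    needed = {"well_id", "condition"}
    if not needed.issubset(df.columns):
        raise SpikeListFormatError(
            f"{path.name}: group table needs columns {sorted(needed)}, "
            f"found {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"{path.name}: group table is empty; no comparison possible")
    mapping: dict[str, str] = {}
    for well, cond in zip(df["well_id"], df["condition"]):
        if well in mapping and mapping[well] != cond:
            raise ValueError(
                f"{path.name}: well {well!r} assigned to conflicting conditions "
                f"{mapping[well]!r} and {cond!r}"
            )
        mapping[well] = cond
    if layout is not None:
        unknown = sorted(set(mapping) - set(layout.well_ids))
        if unknown:
            warnings.warn(f"{path.name}: wells not in layout: {unknown}")
    return GroupAssignment(mapping=mapping)


def write_group_assignment(assignment: GroupAssignment, path: str | Path) -> Path:
    path = Path(path)
    rows = sorted(assignment.mapping.items())
    pd.DataFrame(rows, columns=["well_id", "condition"]).to_csv(path, index=False)
    return path
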