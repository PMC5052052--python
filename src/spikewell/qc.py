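"""Activity-based electrode and well quality control.

Two rules, applied across the recording days of an experiment:

* an electrode counts as *active* on a given day if it recorded at least
  ``min_spikes_per_min`` spikes per minute (default 5/min, boundary
  inclusive);
* a well is *excluded* if on strictly more than ``max_inactive_day_fraction``
  of its recorded days (default 30%) fewer than ``min_active_electrodes``
  (default 16, i.e. 25% of 64) electrodes were active.

Electrode activity is re-assessed per day, so downstream per-day feature
normalisation (e.g. mean firing rate per active electrode) always uses
that day's active set.  The day-fraction denominator is the set of days
the well's plate was actually recorded, which keeps the rule robust to
missed recording days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import PlateLayout, Recording

__all__ = ["QCParams", "ActivityMask", "active_electrodes", "well_inclusion", "build_activity_mask"]


@dataclass(frozen=True)
class QCParams:
    min_spikes_per_min: float = 5.0
    min_active_electrodes: int = 16
    max_inactive_day_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.min_spikes_per_min <= 0:
            raise ValueError("min_spikes_per_min must be positive")
        if self.min_active_electrodes < 1:
            raise ValueError("min_active_electrodes must be >= 1")
        if not 0 <= self.max_inactive_day_fraction <= 1:
            raise ValueError("max_inactive_day_fraction must be in [0, 1]")


def active_electrodes(
    recording: Recording, min_spikes_per_min: float = 5.0
) -> dict[str, frozenset[str]]:
    """Per-well sets of active electrodes for one recording day.

    An electrode is active iff its spike count is >= the rate threshold
    times the recording length; equality counts as active ("at least").
    """
    if recording.duration_s <= 0:
        raise ValueError("recording duration must be positive")
    threshold = min_spikes_per_min * recording.duration_s / 60.0
    counts = recording.spike_counts()
    out: dict[str, frozenset[str]] = {w: frozenset() for w in recording.layout.well_ids}
    if len(counts):
        active = counts[counts["n_spikes"] >= threshold]
        for well, sub in active.groupby("well_id", sort=False, observed=True):
            out[str(well)] = frozenset(sub["electrode_id"])
    return out


def well_inclusion(
    per_div_active_counts: Mapping[int, int],
    min_active_electrodes: int = 16,
    max_inactive_day_fraction: float = 0.30,
) -> bool:
    """Apply the well-inclusion rule to one well's per-day active counts.

    The well is excluded iff the fraction of recorded days with fewer than
    ``min_active_electrodes`` active electrodes is *strictly* greater than
    ``max_inactive_day_fraction`` (">30% of the days" is exclusive: a well
    inactive on exactly 30% of days is retained).
    """
    if not per_div_active_counts:
        raise ValueError("no recorded days for well-inclusion decision")
    n_days = len(per_div_active_counts)
    n_inactive = sum(1 for c in per_div_active_counts.values() if c < min_active_electrodes)
    return (n_inactive / n_days) <= max_inactive_day_fraction


@dataclass
class ActivityMask:
    """Per-day electrode activity and well inclusion for one experiment.

    ``active`` maps div -> well -> frozenset of active electrode ids;
    ``included_wells`` holds wells passing the day-fraction rule;
    ``inactive_day_fraction`` records the audit quantity per well.
    """

    active: dict[int, dict[str, frozenset[str]]]
    included_wells: frozenset[str]
    inactive_day_fraction: dict[str, float]
    params: QCParams
    layout: PlateLayout

    def active_set(self, div: int, well_id: str) -> frozenset[str]:
        return self.active[div][well_id]

    def is_active(self, div: int, well_id: str, electrode_id: str) -> bool:
        return electrode_id in self.active[div][well_id]

    @property
    def divs(self) -> list[int]:
        return sorted(self.active)

    def electrode_table(self) -> pd.DataFrame:
        """Audit table: one row per (div, well, electrode) with active flag."""
        rows = []
        for div in self.divs:
            for well in self.layout.well_ids:
                act = self.active[div][well]
                for elec in self.layout.electrode_ids:
                    rows.append((div, well, elec, elec in act))
        return pd.DataFrame(rows, columns=["div", "well_id", "electrode_id", "active"])

    def well_table(self) -> pd.DataFrame:
        """Audit table: one row per well with inclusion flag and fraction."""
        rows = [
            (w, w in self.included_wells, self.inactive_day_fraction[w])
            for w in self.layout.well_ids
        ]
        return pd.DataFrame(rows, columns=["well_id", "included", "inactive_day_fraction"])

    @classmethod
    def from_tables(
        cls,
        electrode_table: pd.DataFrame,
        well_table: pd.DataFrame,
        params: QCParams,
        layout: PlateLayout,
    ) -> "ActivityMask":
        active: dict[int, dict[str, frozenset[str]]] = {}
        for div, sub in electrode_table.groupby("div"):
            per_well = {w: frozenset() for w in layout.well_ids}
            act = sub[sub["active"].astype(bool)]
            for well, wsub in act.groupby("well_id"):
                per_well[str(well)] = frozenset(wsub["electrode_id"].astype(str))
            active[int(div)] = per_well
        included = frozenset(
            well_table.loc[well_table["included"].astype(bool), "well_id"].astype(str)
        )
        frac = dict(
            zip(well_table["well_id"].astype(str), well_table["inactive_day_fraction"].astype(float))
        )
        return cls(
            active=active,
            included_wells=included,
            inactive_day_fraction=frac,
            params=params,
            layout=layout,
        )


def build_activity_mask(
    recordings: Mapping[int, Recording] | Iterable[Recording],
    params: QCParams = QCParams(),
) -> ActivityMask:
    """Combine the electrode and well rules over all recording days.

    All recordings must share one layout.  Downstream feature computation
    consumes only electrodes in the per-day active sets of included wells.
    """
    if not isinstance(recordings, Mapping):
        recordings = {r.div: r for r in recordings}
    if not recordings:
        raise ValueError("no recordings supplied")
    layouts = {id(r.layout): r.layout for r in recordings.values()}
    layout = next(iter(layouts.values()))
    if any(l.well_ids != layout.well_ids or l.electrode_ids != layout.electrode_ids
           for l in layouts.values()):
        raise ValueError("recordings do not share a common plate layout")

    active: dict[int, dict[str, frozenset[str]]] = {}
    for div, rec in recordings.items():
        active[int(div)] = active_electrodes(rec, params.min_spikes_per_min)

    included = set()
    frac: dict[str, float] = {}
    for well in layout.well_ids:
        counts = {div: len(active[div][well]) for div in active}
        n_inactive = sum(
            1 for c in counts.values() if c < params.min_active_electrodes
        )
        frac[well] = n_inactive / len(counts)
        if well_inclusion(
            counts, params.min_active_electrodes, params.max_inactive_day_fraction
        ):
            included.add(well)
    return ActivityMask(
        active=active,
        included_wells=frozenset(included),
        inactive_day_fraction=frac,
        params=params,
        layout=layout,
    )
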