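"""End-to-end orchestration: spike lists in, feature tables and group
statistics out.

The functions here are the library face of the pipeline (the CLI in
:mod:`spikewell.cli` is a thin wrapper around them):

* :func:`analyze` — QC mask, burst/network event tables, feature table;
* :func:`compare` — two-tier group statistics on a feature table;
* :func:`raster_window` — per-electrode spike ticks plus burst and
  network-event intervals clipped to a time window, for external
  raster rendering;
* :func:`run_all` — simulate-or-read, analyze, compare, and archive
  every output together with the resolved configuration.

All outputs are deterministic given inputs, configuration and seed, and
stage-by-stage counts are logged for auditability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .bursts import BurstParams
from .features import compute_well_features, write_feature_table
from .io import (
    GroupAssignment,
    PlateLayout,
    Recording,
    SpikeListDialect,
    read_group_assignment,
    read_spikelist,
)
from .network import NetworkParams
from .qc import ActivityMask, QCParams, build_activity_mask
from .stats import GroupComparison, compare_groups

logger = logging.getLogger("spikewell")

__all__ = [
    "AnalysisResult",
    "analyze",
    "load_experiment",
    "compare",
    "comparisons_to_frame",
    "raster_window",
    "run_all",
]


@dataclass
class AnalysisResult:
    """Everything the analysis stage produces for one experiment."""

    features: pd.DataFrame
    burst_table: pd.DataFrame
    network_table: pd.DataFrame
    mask: ActivityMask

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(self.features, out / "features.csv")
        self.burst_table.to_csv(out / "bursts.csv", index=False)
        self.network_table.to_csv(out / "network_events.csv", index=False)
        self.mask.electrode_table().to_csv(out / "qc_electrodes.csv", index=False)
        self.mask.well_table().to_csv(out / "qc_wells.csv", index=False)


def load_experiment(
    spikelists: Mapping[int, str | Path],
    group_table: str | Path,
    *,
    dialect: SpikeListDialect = SpikeListDialect(),
    layout: PlateLayout | None = None,
    duration_s: float = 900.0,
    strict: bool = False,
) -> tuple[dict[int, Recording], GroupAssignment]:
    """Read one spike list per DIV plus the group-assignment table."""
    group_path = Path(group_table)
    if not group_path.exists():
        raise FileNotFoundError(f"group table not found: {group_path}")
    for div, path in spikelists.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"spike list for DIV {div} not found: {path}")
    layout = layout or PlateLayout.default_12well()
    assignment = read_group_assignment(group_path, layout=layout)
    recordings = {}
    for div, path in sorted(spikelists.items()):
        rec = read_spikelist(
            path, div, dialect=dialect, layout=layout, duration_s=duration_s, strict=strict
        )
        logger.info(
            "DIV %d: read %d spikes (%d rows rejected) from %s",
            div, rec.n_events, rec.n_rejected_rows, path,
        )
        recordings[div] = rec
    return recordings, assignment


def analyze(
    recordings: Mapping[int, Recording],
    assignment: GroupAssignment | None = None,
    qc_params: QCParams = QCParams(),
    burst_params: BurstParams = BurstParams(),
    network_params: NetworkParams | None = None,
) -> AnalysisResult:
    """QC, burst/network detection and feature extraction for all days."""
    mask = build_activity_mask(recordings, qc_params)
    n_excl = len(mask.layout.well_ids) - len(mask.included_wells)
    logger.info(
        "QC: %d of %d wells included (%d excluded by the day-fraction rule)",
        len(mask.included_wells), len(mask.layout.well_ids), n_excl,
    )
    feat_parts, burst_parts, event_parts = [], [], []
    for div in sorted(recordings):
        feats, bursts, events = compute_well_features(
            recordings[div],
            mask,
            assignment,
            burst_params,
            network_params,
            collect_events=True,
        )
        logger.info(
            "DIV %d: %d wells, %d bursts, %d network events",
            div, len(feats), len(bursts), len(events),
        )
        feat_parts.append(feats)
        burst_parts.append(bursts)
        event_parts.append(events)
    features = (
        pd.concat(feat_parts, ignore_index=True)
        .sort_values(["div", "well_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    def _concat(parts: list[pd.DataFrame]) -> pd.DataFrame:
        non_empty = [p for p in parts if len(p)]
        return pd.concat(non_empty, ignore_index=True) if non_empty else parts[0]

    return AnalysisResult(
        features=features,
        burst_table=_concat(burst_parts),
        network_table=_concat(event_parts),
        mask=mask,
    )


def compare(
    features: pd.DataFrame,
    assignment: GroupAssignment,
    feature_names: Sequence[str] | None = None,
    window: tuple[int, int] = (8, 16),
    n_perm: int = 10_000,
    seed: int | None = None,
    reducer: str = "mean",
) -> list[GroupComparison]:
    """Two-tier statistics for every feature; see :mod:`spikewell.stats`."""
    results = compare_groups(
        features, assignment, feature_names, window, n_perm, seed, reducer
    )
    for r in results:
        logger.info(
            "%s: perm_p=%.4g (n_perm=%d), fisher_p=%.4g over DIV %d-%d",
            r.feature, r.perm_p, r.n_perm, r.fisher_p, r.window[0], r.window[1],
        )
    return results


def comparisons_to_frame(results: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparison records to one row per feature (per-day p-values
    serialised as JSON in the ``per_div_p`` column)."""
    rows = []
    for r in results:
        rec = r.to_record()
        rec["per_div_p"] = json.dumps(rec["per_div_p"])
        rec["skipped_divs"] = json.dumps(rec["skipped_divs"])
        rows.append(rec)
    return pd.DataFrame(rows)


def raster_window(
    recording: Recording,
    burst_table: pd.DataFrame,
    network_table: pd.DataFrame,
    well_id: str,
    window: tuple[float, float],
) -> dict[str, pd.DataFrame]:
    """Event-interval tables for raster rendering of one well.

    Returns spike ticks plus burst and network-event intervals restricted
    to ``window``; intervals straddling a boundary are clipped to it, not
    dropped.  An empty window yields empty tables.
    """
    t0, t1 = window
    if well_id not in recording.layout.well_ids:
        raise KeyError(f"unknown well {well_id!r}")
    wev = recording.well(well_id)
    spikes = wev[(wev["time_s"] >= t0) & (wev["time_s"] <= t1)]
    spikes = spikes[["time_s", "electrode_id"]].reset_index(drop=True)

    def clip(table: pd.DataFrame) -> pd.DataFrame:
        sub = table[(table["well_id"] == well_id) & (table["div"] == recording.div)]
        sub = sub[(sub["end_s"] >= t0) & (sub["start_s"] <= t1)].copy()
        sub["start_s"] = sub["start_s"].clip(lower=t0)
        sub["end_s"] = sub["end_s"].clip(upper=t1)
        return sub.reset_index(drop=True)

    return {
        "spikes": spikes,
        "bursts": clip(burst_table),
        "network_events": clip(network_table),
    }


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run (archived with outputs)."""

    spikelists: dict[int, str] = field(default_factory=dict)
    group_table: str = ""
    out_dir: str = "spikewell_out"
    duration_s: float = 900.0
    strict: bool = False
    dialect: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    bursts: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    window: tuple[int, int] = (8, 16)
    n_perm: int = 10_000
    seed: int | None = None
    reducer: str = "mean"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in raw and isinstance(raw["window"], str):
            lo, hi = raw["window"].split(":")
            raw["window"] = (int(lo), int(hi))
        if "spikelists" in raw:
            raw["spikelists"] = {int(k): str(v) for k, v in raw["spikelists"].items()}
        return cls(**raw)


def run_all(config: PipelineConfig) -> tuple[AnalysisResult, list[GroupComparison]]:
    """Load, analyze, compare; write every table plus the resolved config."""
    recordings, assignment = load_experiment(
        config.spikelists,
        config.group_table,
        dialect=SpikeListDialect(**config.dialect),
        duration_s=config.duration_s,
        strict=config.strict,
    )
    result = analyze(
        recordings,
        assignment,
        QCParams(**config.qc),
        BurstParams(**config.bursts),
        NetworkParams(**config.network) if config.network else None,
    )
    comparisons = compare(
        result.features,
        assignment,
        window=tuple(config.window),
        n_perm=config.n_perm,
        seed=config.seed,
        reducer=config.reducer,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.write(out)
    comparisons_to_frame(comparisons).to_csv(out / "group_stats.csv", index=False)
    (out / "group_stats.json").write_text(
        json.dumps([r.to_record() for r in comparisons], indent=2)
    )
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
    return result, comparisons
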