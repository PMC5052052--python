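"""Synthetic multiwell MEA experiments with known ground truth.

Each alive electrode's spike train is the union of three stationary
point processes over the recording interval:

* homogeneous Poisson *background* firing (``background_rate_hz``);
* an electrode-level *burst* process — burst onsets are Poisson
  (``burst_rate_per_min``), each onset emitting a cluster whose spike
  count is 1 + Poisson(``spikes_per_burst`` - 1) with exponential
  within-burst ISIs (``intra_burst_isi_s``);
* plate-level *network events* — onsets Poisson per well
  (``network_event_rate_per_min``); each event recruits every alive
  electrode independently with ``participation_prob``, and recruited
  electrodes emit a short dense cluster at the event time.

All rates are scaled by a per-condition effect multiplier, a per-DIV
maturation multiplier (sigmoidal rise to a plateau, mimicking network
development in culture), and a per-well lognormal random effect (mean 1,
coefficient of variation ``well_variability_cv``) shared across days —
wells, the experimental unit of the downstream statistics, genuinely
differ.  Treatment effects are multiplicative on background rate, burst
rate, burst duration, inter-burst interval, and network-event rate; the
inter-burst-interval multiplier acts by dividing the burst-onset rate.

Background firing is deliberately the dominant spike source under the
defaults (~94% of spikes), so an imposed background multiplier maps
nearly one-to-one onto the mean-firing-rate group ratio; parameter
recovery is then a direct end-to-end check of the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    GroupAssignment,
    PlateLayout,
    Recording,
    write_group_assignment,
    write_spikelist,
)

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "EXCITABILITY_EFFECTS",
    "simulate_well",
    "simulate_experiment",
    "recover_parameters",
]

#: Effect keys a condition may scale; absent keys default to 1.
EFFECT_KEYS = ("background_rate", "burst_rate", "burst_duration", "ibi", "network_event_rate")

#: Example treated-condition effect set producing an excitability
#: phenotype: more and longer bursts in quicker succession, higher firing
#: and network-event rates (direction only; magnitudes are illustrative).
EXCITABILITY_EFFECTS: dict[str, float] = {
    "background_rate": 1.5,
    "burst_rate": 1.5,
    "burst_duration": 1.3,
    "ibi": 0.7,
    "network_event_rate": 1.5,
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int | None = None
    n_control_wells: int = 17
    n_treatment_wells: int = 16
    control_label: str = "control"
    treatment_label: str = "sponge"
    divs: tuple[int, ...] = tuple(range(3, 20))
    duration_s: float = 900.0
    electrodes_per_well: int = 64
    p_electrode_active: float = 0.85
    background_rate_hz: float = 1.0
    burst_rate_per_min: float = 0.2
    spikes_per_burst: float = 8.0
    intra_burst_isi_s: float = 0.02
    network_event_rate_per_min: float = 0.2
    participation_prob: float = 0.75
    network_spikes_per_participant: int = 8
    network_intra_isi_s: float = 0.01
    network_jitter_s: float = 0.003
    well_variability_cv: float = 0.3
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    maturation_midpoint_div: float = 6.5
    maturation_scale_div: float = 1.5

    def __post_init__(self) -> None:
        for name in ("p_electrode_active", "participation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "background_rate_hz",
            "burst_rate_per_min",
            "network_event_rate_per_min",
            "well_variability_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        ctrl = self.effects.get(self.control_label, {})
        if any(abs(v - 1.0) > 1e-12 for v in ctrl.values()):
            raise ValueError("control-condition effect multipliers must all be 1")

    def effect(self, condition: str, key: str) -> float:
        return float(self.effects.get(condition, {}).get(key, 1.0))

    def maturation(self, div: int) -> float:
        """Sigmoidal activity rise with culture age, plateau near 1."""
        return 1.0 / (1.0 + math.exp(-(div - self.maturation_midpoint_div) / self.maturation_scale_div))

    def lognormal_sigma(self) -> float:
        return math.sqrt(math.log(1.0 + self.well_variability_cv**2))


def _segmented_cumsum(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each segment boundary."""
    if values.size == 0:
        return values
    cs = np.cumsum(values)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    offset = np.repeat(cs[starts] - values[starts], counts)
    return cs - offset


def _well_spike_arrays(
    config: SimulationConfig,
    condition: str,
    div: int,
    rng: np.random.Generator,
    alive: np.ndarray,
    well_effect: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times and electrode indices (into ``alive``) for one well-day."""
    T = config.duration_s
    scale = well_effect * config.maturation(div)
    n_alive = alive.size
    times_parts: list[np.ndarray] = []
    elec_parts: list[np.ndarray] = []
    if n_alive == 0:
        return np.empty(0), np.empty(0, dtype=np.intp)

    # background Poisson firing
    bg_rate = config.background_rate_hz * config.effect(condition, "background_rate") * scale
    if bg_rate > 0:
        counts = rng.poisson(bg_rate * T, n_alive)
        total = int(counts.sum())
        times_parts.append(rng.random(total) * T)
        elec_parts.append(np.repeat(np.arange(n_alive), counts))

    # electrode-level bursts
    burst_rate = (
        config.burst_rate_per_min
        / 60.0
        * config.effect(condition, "burst_rate")
        / config.effect(condition, "ibi")
        * scale
    )
    dur_mult = config.effect(condition, "burst_duration")
    if burst_rate > 0 and config.spikes_per_burst >= 1:
        onsets_per_elec = rng.poisson(burst_rate * T, n_alive)
        n_bursts = int(onsets_per_elec.sum())
        if n_bursts:
            onset_t = rng.random(n_bursts) * T
            burst_elec = np.repeat(np.arange(n_alive), onsets_per_elec)
            nspk = 1 + rng.poisson(max(config.spikes_per_burst - 1.0, 0.0), n_bursts)
            total = int(nspk.sum())
            deltas = rng.exponential(config.intra_burst_isi_s * dur_mult, total)
            starts = np.concatenate(([0], np.cumsum(nspk)[:-1]))
            deltas[starts] = 0.0  # first spike sits at the burst onset
            offs = _segmented_cumsum(deltas, nspk)
            times_parts.append(np.repeat(onset_t, nspk) + offs)
            elec_parts.append(np.repeat(burst_elec, nspk))

    # well-level synchronous network events
    net_rate = (
        config.network_event_rate_per_min
        / 60.0
        * config.effect(condition, "network_event_rate")
        * scale
    )
    if net_rate > 0 and config.network_spikes_per_participant >= 1:
        n_ev = int(rng.poisson(net_rate * T))
        if n_ev:
            ev_t = rng.random(n_ev) * T
            recruit = rng.random((n_ev, n_alive)) < config.participation_prob
            pair_ev, pair_el = np.nonzero(recruit)
            n_pairs = pair_ev.size
            if n_pairs:
                k = config.network_spikes_per_participant
                jitter = rng.exponential(config.network_jitter_s, n_pairs)
                deltas = rng.exponential(config.network_intra_isi_s, n_pairs * k)
                counts = np.full(n_pairs, k)
                starts = np.arange(0, n_pairs * k, k)
                deltas[starts] = 0.0
                offs = _segmented_cumsum(deltas, counts)
                times_parts.append(
                    np.repeat(ev_t[pair_ev] + jitter, k) + offs
                )
                elec_parts.append(np.repeat(pair_el, k))

    if not times_parts:
        return np.empty(0), np.empty(0, dtype=np.intp)
    t = np.concatenate(times_parts)
    e = np.concatenate(elec_parts)
    keep = t <= T
    t, e = t[keep], e[keep]
    order = np.argsort(t, kind="stable")
    return t[order], e[order]


def _events_frame(
    t: np.ndarray, elec_codes: np.ndarray, well_codes: np.ndarray, layout: PlateLayout
) -> pd.DataFrame:
    """Assemble the canonical event frame from integer category codes."""
    return pd.DataFrame(
        {
            "time_s": t,
            "well_id": pd.Categorical.from_codes(well_codes, categories=list(layout.well_ids)),
            "electrode_id": pd.Categorical.from_codes(
                elec_codes, categories=list(layout.electrode_ids)
            ),
            "amplitude_mV": np.full(t.size, np.nan),
        }
    )


def simulate_well(
    config: SimulationConfig,
    condition: str,
    div: int,
    rng: np.random.Generator,
    *,
    well_id: str = "A1",
    alive: np.ndarray | None = None,
    well_effect: float | None = None,
) -> Recording:
    """Simulate one well for one day and return it as a Recording.

    ``alive`` (electrode labels) and ``well_effect`` may be passed in so
    an experiment can hold them fixed across days; when omitted they are
    drawn from ``rng``.
    """
    electrodes = np.array(
        [f"{r}{c}" for r in range(1, 9) for c in range(1, 9)][: config.electrodes_per_well]
    )
    if config.electrodes_per_well > 64:
        electrodes = np.array([str(i) for i in range(config.electrodes_per_well)])
    if alive is None:
        alive = electrodes[rng.random(electrodes.size) < config.p_electrode_active]
    else:
        alive = np.asarray(alive)
    if well_effect is None:
        sigma = config.lognormal_sigma()
        well_effect = float(rng.lognormal(-0.5 * sigma**2, sigma))
    t, e_idx = _well_spike_arrays(config, condition, div, rng, alive, well_effect)
    layout = PlateLayout(well_ids=(well_id,), electrode_ids=tuple(electrodes))
    elec_index = {lab: i for i, lab in enumerate(layout.electrode_ids)}
    alive_codes = np.array([elec_index[lab] for lab in alive], dtype=np.intp)
    frame = _events_frame(
        t,
        alive_codes[e_idx] if t.size else np.empty(0, dtype=np.intp),
        np.zeros(t.size, dtype=np.intp),
        layout,
    )
    return Recording(div=div, duration_s=config.duration_s, events=frame, layout=layout)


@dataclass
class SimulatedExperiment:
    recordings: dict[int, Recording]
    assignment: GroupAssignment
    layout: PlateLayout
    config: SimulationConfig


def simulate_experiment(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedExperiment:
    """Simulate a full experiment: every well on every recording day.

    Wells are laid out over as many 12-well plates as needed (control
    wells first).  Alive-electrode sets and well random effects are drawn
    once per well and held fixed across days.  With ``out_dir`` given,
    one spike-list CSV per DIV, the group-assignment table and a manifest
    JSON (full config incl. seed) are written in the standard dialect.
    """
    n_wells = config.n_control_wells + config.n_treatment_wells
    layout = PlateLayout.multi_plate(n_wells)
    if config.electrodes_per_well != 64:
        electrodes = tuple(
            f"{r}{c}" for r in range(1, 9) for c in range(1, 9)
        )[: config.electrodes_per_well]
        layout = PlateLayout(well_ids=layout.well_ids, electrode_ids=electrodes)
    electrodes_arr = np.array(layout.electrode_ids)

    conditions = {
        w: (config.control_label if i < config.n_control_wells else config.treatment_label)
        for i, w in enumerate(layout.well_ids)
    }
    assignment = GroupAssignment(mapping=conditions)

    rng = np.random.default_rng(config.seed)
    sigma = config.lognormal_sigma()
    alive_idx = {
        w: np.flatnonzero(rng.random(electrodes_arr.size) < config.p_electrode_active)
        for w in layout.well_ids
    }
    alive_sets = {w: electrodes_arr[idx] for w, idx in alive_idx.items()}
    well_effects = {
        w: float(rng.lognormal(-0.5 * sigma**2, sigma)) for w in layout.well_ids
    }

    recordings: dict[int, Recording] = {}
    for div in config.divs:
        t_parts, e_parts, w_parts = [], [], []
        for wi, w in enumerate(layout.well_ids):
            t, e_idx = _well_spike_arrays(
                config, conditions[w], div, rng, alive_sets[w], well_effects[w]
            )
            t_parts.append(t)
            e_parts.append(
                alive_idx[w][e_idx] if t.size else np.empty(0, dtype=np.intp)
            )
            w_parts.append(np.full(t.size, wi, dtype=np.intp))
        t_all = np.concatenate(t_parts)
        order = np.argsort(t_all, kind="stable")
        frame = _events_frame(
            t_all[order],
            np.concatenate(e_parts)[order],
            np.concatenate(w_parts)[order],
            layout,
        )
        recordings[div] = Recording(
            div=div, duration_s=config.duration_s, events=frame, layout=layout
        )

    exp = SimulatedExperiment(
        recordings=recordings, assignment=assignment, layout=layout, config=config
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for div, rec in recordings.items():
            write_spikelist(rec, out / f"div{div:02d}_spikelist.csv")
        write_group_assignment(assignment, out / "groups.csv")
        manifest = dataclasses.asdict(config)
        manifest["effects"] = {k: dict(v) for k, v in config.effects.items()}
        manifest["divs"] = list(config.divs)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return exp


def recover_parameters(
    feature_table: pd.DataFrame,
    assignment: GroupAssignment,
    config: SimulationConfig,
    window: tuple[int, int] = (8, 16),
) -> pd.DataFrame:
    """Compare imposed effect multipliers to feature-ratio estimates.

    The estimate for each parameter is the ratio of treated to control
    group means of the matching feature's per-well window means:
    background rate -> mfr_hz, burst rate (net of the IBI multiplier) ->
    burst_rate_per_min, network-event rate -> n_network_spikes.
    """
    lo, hi = window
    sub = feature_table[(feature_table["div"] >= lo) & (feature_table["div"] <= hi)]
    t_label, c_label = config.treatment_label, config.control_label

    def group_mean(feature: str, condition: str) -> float:
        wells = [w for w in assignment.wells(condition) if w in set(sub["well_id"])]
        per_well = [
            np.nanmean(sub.loc[sub["well_id"] == w, feature].to_numpy(dtype=float))
            for w in wells
        ]
        return float(np.nanmean(per_well))

    eff = lambda key: config.effect(t_label, key)
    spec = [
        ("background_rate", "mfr_hz", eff("background_rate")),
        ("burst_rate", "burst_rate_per_min", eff("burst_rate") / eff("ibi")),
        ("network_event_rate", "n_network_spikes", eff("network_event_rate")),
    ]
    rows = []
    for name, feature, imposed in spec:
        denom = group_mean(feature, c_label)
        # a degenerate control mean (e.g. no events at all) has no ratio
        est = group_mean(feature, t_label) / denom if denom > 0 else float("nan")
        rows.append(
            {
                "parameter": name,
                "feature": feature,
                "imposed_ratio": imposed,
                "estimated_ratio": est,
                "relative_error": abs(est - imposed) / imposed,
            }
        )
    return pd.DataFrame(rows)
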