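"""Activity QC and the per-well feature table.

Simulates a small experiment, applies the two QC rules (electrode active
iff >= 5 spikes/min; well excluded iff < min_active electrodes on > 30%
of recorded days), and assembles the per-well per-day feature table the
statistics consume.
"""

from spikewell import (
    QCParams,
    SimulationConfig,
    build_activity_mask,
    compute_feature_table,
    simulate_experiment,
)

config = SimulationConfig(
    seed=42,
    n_control_wells=4,
    n_treatment_wells=4,
    divs=(8, 9, 10),
    duration_s=120.0,
    electrodes_per_well=8,
)
experiment = simulate_experiment(config)

# 8-electrode wells: scale the well rule to 25% of the layout (2 electrodes)
qc = QCParams(min_spikes_per_min=5.0, min_active_electrodes=2)
mask = build_activity_mask(experiment.recordings, qc)
print(f"included wells: {sorted(mask.included_wells)}")
print("per-well inactive-day fractions:")
for well, frac in sorted(mask.inactive_day_fraction.items()):
    print(f"  {well}: {frac:.2f}")

features = compute_feature_table(experiment.recordings, mask, experiment.assignment)
cols = ["div", "well_id", "condition", "n_active_electrodes", "mfr_hz",
        "burst_rate_per_min", "n_network_spikes"]
print(features[cols].head(8).to_string(index=False))
# mfr_hz is spikes / duration / n_active_electrodes; burst rate is per
# active electrode per minute; missing days would show as NaN, never 0.
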