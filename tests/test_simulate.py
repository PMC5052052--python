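"""Synthetic experiment generator: determinism, rates, recovery."""

import json

import numpy as np
import pytest

from spikewell.io import read_spikelist
from spikewell.network import NetworkParams, detect_network_spikes
from spikewell.qc import QCParams, build_activity_mask
from spikewell.features import compute_feature_table
from spikewell.simulate import (
    SimulationConfig,
    recover_parameters,
    simulate_experiment,
    simulate_well,
)

SMALL = dict(
    n_control_wells=3,
    n_treatment_wells=3,
    divs=(8, 9),
    duration_s=60.0,
    electrodes_per_well=8,
)


class TestSimulateWell:
    def test_all_rates_zero_gives_empty_recording(self):
        cfg = SimulationConfig(
            background_rate_hz=0.0, burst_rate_per_min=0.0, network_event_rate_per_min=0.0
        )
        rec = simulate_well(cfg, "control", 10, np.random.default_rng(0))
        assert rec.n_events == 0

    def test_background_count_matches_poisson_expectation(self):
        cfg = SimulationConfig(
            background_rate_hz=1.0,
            burst_rate_per_min=0.0,
            network_event_rate_per_min=0.0,
            p_electrode_active=1.0,
            well_variability_cv=0.0,
            maturation_midpoint_div=-100.0,  # plateau: multiplier ~1 at any div
        )
        rec = simulate_well(cfg, "control", 10, np.random.default_rng(1))
        expectation = 64 * 900
        assert abs(rec.n_events - expectation) < 4 * np.sqrt(expectation)

    def test_same_rng_state_reproduces_spike_list(self):
        cfg = SimulationConfig(**SMALL)
        r1 = simulate_well(cfg, "control", 8, np.random.default_rng(5))
        r2 = simulate_well(cfg, "control", 8, np.random.default_rng(5))
        assert r1.events.equals(r2.events)
        r3 = simulate_well(cfg, "control", 8, np.random.default_rng(6))
        assert not r1.events.equals(r3.events)

    def test_events_satisfy_recording_invariants(self):
        cfg = SimulationConfig(**SMALL)
        rec = simulate_well(cfg, "control", 8, np.random.default_rng(2))
        t = rec.events["time_s"].to_numpy()
        assert (np.diff(t) >= 0).all()
        assert t.size == 0 or (t[0] >= 0 and t[-1] <= rec.duration_s)
        assert set(rec.events["electrode_id"]) <= set(rec.layout.electrode_ids)

    def test_empirical_rate_converges_with_duration(self):
        base = dict(
            background_rate_hz=2.0, burst_rate_per_min=0.0,
            network_event_rate_per_min=0.0, p_electrode_active=1.0,
            well_variability_cv=0.0, maturation_midpoint_div=-100.0,
            electrodes_per_well=16,
        )
        rng = np.random.default_rng(3)
        mean_errs = []
        for dur in (20.0, 2000.0):
            cfg = SimulationConfig(duration_s=dur, **base)
            errs = [
                abs(simulate_well(cfg, "control", 10, rng).n_events / dur / 16 - 2.0)
                for _ in range(5)
            ]
            mean_errs.append(np.mean(errs))
        assert mean_errs[1] < mean_errs[0]


class TestSimulateExperiment:
    def test_writes_parseable_files_and_manifest(self, tmp_path):
        cfg = SimulationConfig(seed=0, **SMALL)
        exp = simulate_experiment(cfg, out_dir=tmp_path)
        files = sorted(tmp_path.glob("div*_spikelist.csv"))
        assert len(files) == 2
        rec = read_spikelist(
            files[0], div=8, layout=exp.layout, duration_s=cfg.duration_s
        )
        assert rec.n_events == exp.recordings[8].n_events
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 0
        assert (tmp_path / "groups.csv").exists()

    def test_seventeen_vs_sixteen_well_default_design(self):
        cfg = SimulationConfig(seed=1, divs=(10,), duration_s=5.0,
                               background_rate_hz=0.1, burst_rate_per_min=0.0,
                               network_event_rate_per_min=0.0)
        exp = simulate_experiment(cfg)
        assert len(exp.assignment.wells("control")) == 17
        assert len(exp.assignment.wells("sponge")) == 16
        assert len(exp.layout.well_ids) == 33

    def test_same_seed_byte_identical_spikelists(self, tmp_path):
        cfg = SimulationConfig(seed=7, **SMALL)
        simulate_experiment(cfg, out_dir=tmp_path / "a")
        simulate_experiment(cfg, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").glob("*.csv")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_control_effect_multipliers_must_be_one(self):
        with pytest.raises(ValueError, match="control"):
            SimulationConfig(effects={"control": {"background_rate": 2.0}})


class TestGeneratorDetectorConsistency:
    def test_seeded_network_events_are_detected(self):
        """With full recruitment of 64 electrodes, nearly every seeded
        synchronous event must be found by the network-spike detector."""
        cfg = SimulationConfig(
            background_rate_hz=0.2,
            burst_rate_per_min=0.0,
            network_event_rate_per_min=2.0,
            participation_prob=0.9,
            p_electrode_active=1.0,
            well_variability_cv=0.0,
            maturation_midpoint_div=-100.0,
        )
        rng = np.random.default_rng(4)
        detected, seeded = 0, 0
        for _ in range(5):
            rec = simulate_well(cfg, "control", 10, rng)
            events = detect_network_spikes(
                rec.events["time_s"].to_numpy(),
                rec.events["electrode_id"].to_numpy(),
                frozenset(rec.layout.electrode_ids),
                NetworkParams(),
            )
            detected += len(events)
            seeded += 30  # 2/min * 15 min expectation
        assert detected >= 0.95 * 0.8 * seeded  # Poisson slack on the seed count


class TestParameterRecovery:
    def run_recovery(self, effects, seed=0):
        cfg = SimulationConfig(
            seed=seed,
            n_control_wells=8,
            n_treatment_wells=8,
            divs=(10, 11, 12),
            duration_s=300.0,
            well_variability_cv=0.1,
            effects={"sponge": effects},
        )
        exp = simulate_experiment(cfg)
        mask = build_activity_mask(exp.recordings)
        feats = compute_feature_table(exp.recordings, mask, exp.assignment)
        return recover_parameters(feats, exp.assignment, cfg, window=(10, 12))

    def test_null_multipliers_recovered_near_one(self):
        rec = self.run_recovery({})
        assert (rec["imposed_ratio"] == 1.0).all()
        assert (rec["relative_error"] < 0.15).all()

    def test_background_multiplier_recovered(self):
        rec = self.run_recovery({"background_rate": 1.5}).set_index("parameter")
        est = rec.loc["background_rate", "estimated_ratio"]
        assert est == pytest.approx(1.5, rel=0.12)

    def test_recovery_error_shrinks_with_more_wells(self):
        def mean_error(n, n_reps=6):
            errs = []
            for rep in range(n_reps):
                cfg = SimulationConfig(
                    seed=100 * n + rep, n_control_wells=n, n_treatment_wells=n,
                    divs=(10,), duration_s=60.0, electrodes_per_well=16,
                    well_variability_cv=0.3,
                    effects={"sponge": {"background_rate": 1.5}},
                )
                exp = simulate_experiment(cfg)
                mask = build_activity_mask(exp.recordings, QCParams(min_active_electrodes=4))
                feats = compute_feature_table(exp.recordings, mask, exp.assignment)
                rec = recover_parameters(
                    feats, exp.assignment, cfg, window=(10, 10)
                ).set_index("parameter")
                errs.append(rec.loc["background_rate", "relative_error"])
            return float(np.mean(errs))

        # averaged over replicates the error must fall as wells are added
        assert mean_error(24) < mean_error(3)
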