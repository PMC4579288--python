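"""Generator contracts: determinism, balance, independence, persistence."""

import dataclasses

import numpy as np
import pytest

from phasecode.circstats import resultant_vector_length
from phasecode.spectral import morlet_decompose
from phasecode.synth import (
    GroundTruth,
    SimulationConfig,
    events_from_csv,
    events_to_csv,
    generate_null_session,
    generate_session,
    read_dataset,
    write_dataset,
)


class TestConfigValidation:
    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            SimulationConfig(coupling_concentration=-1.0)

    def test_window_shorter_than_one_period_rejected(self):
        with pytest.raises(ValueError, match="period"):
            SimulationConfig(epoch_window_ms=(-200.0, 500.0), modulator_freq=1.0)

    def test_wrong_phase_count_rejected(self):
        with pytest.raises(ValueError, match="4 entries"):
            SimulationConfig(category_preferred_phases=(0.0, 90.0, 180.0))

    def test_config_json_round_trip(self):
        cfg = SimulationConfig(seed=42, coupling_depth=0.5)
        assert SimulationConfig.from_json(cfg.to_json()) == cfg


class TestGenerateSession:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_trials_per_category=4, seed=9)
        s1, t1 = generate_session(cfg)
        s2, t2 = generate_session(cfg)
        np.testing.assert_array_equal(s1.epochs, s2.epochs)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        assert t1 == t2

    def test_balanced_design(self):
        cfg = SimulationConfig(n_trials_per_category=6, seed=1)
        session, _ = generate_session(cfg)
        assert session.category_counts() == {c: 6 for c in session.categories}
        assert session.n_samples == 2250

    def test_ground_truth_carries_config(self):
        cfg = SimulationConfig(n_trials_per_category=4, seed=2)
        _, truth = generate_session(cfg)
        assert truth.modulator_freq == cfg.modulator_freq
        assert truth.carrier_freq == cfg.carrier_freq
        assert truth.preferred_phase_deg["tool"] == 90.0

    def test_zero_depth_decouples_envelope_from_phase(self):
        """With coupling_depth 0 the gamma envelope is independent of
        modulator phase: circular-linear correlation ~ 0 on a long session."""
        cfg = SimulationConfig(
            n_trials_per_category=12, seed=5, coupling_depth=0.0, noise_sd=0.0,
            gamma_background_sd=0.0,
        )
        session, _ = generate_session(cfg)
        concat = session.concatenated
        dec_g = morlet_decompose(concat, 1000.0, [cfg.carrier_freq])
        dec_m = morlet_decompose(concat, 1000.0, [cfg.modulator_freq])
        stim = session.stimulus_mask() & dec_g.valid_mask(cfg.carrier_freq)
        env = np.sqrt(dec_g.power[0][stim].astype(float))
        phase = dec_m.phase[0][stim].astype(float)
        # circular-linear association via the phase-weighted envelope resultant
        r = np.abs(np.mean((env - env.mean()) * np.exp(1j * phase))) / env.std()
        assert r < 0.05

    def test_zero_depth_ignores_preferred_phases(self):
        base = SimulationConfig(n_trials_per_category=2, seed=3, coupling_depth=0.0)
        other = dataclasses.replace(
            base, category_preferred_phases=(10.0, 20.0, 30.0, 40.0)
        )
        s1, _ = generate_session(base)
        s2, _ = generate_session(other)
        np.testing.assert_array_equal(s1.epochs, s2.epochs)

    def test_coupled_envelope_concentrates_at_preferred_phase(self):
        """At depth 0.8 the gamma envelope mass clusters near the category's
        preferred modulator phase (noise-free check on one category)."""
        cfg = SimulationConfig(
            n_trials_per_category=3, seed=4, noise_sd=0.0, gamma_background_sd=0.0
        )
        session, truth = generate_session(cfg)
        concat = session.concatenated
        dec_g = morlet_decompose(concat, 1000.0, [cfg.carrier_freq])
        dec_m = morlet_decompose(concat, 1000.0, [cfg.modulator_freq])
        stim = session.stimulus_mask()
        codes = session.label_per_sample()
        for i, cat in enumerate(session.categories):
            sel = stim & (codes == i)
            env = np.sqrt(dec_g.power[0][sel].astype(float))
            phase = dec_m.phase[0][sel].astype(float)
            weighted_mean = np.angle(np.sum(env * np.exp(1j * phase)))
            err = np.degrees(
                np.abs(
                    np.angle(
                        np.exp(
                            1j
                            * (weighted_mean - np.radians(truth.preferred_phase_deg[cat]))
                        )
                    )
                )
            )
            assert err < 25.0


class TestNullSessions:
    def test_shared_phase_mode_sets_identical_truth(self, small_config):
        _, truth = generate_null_session(small_config, "pac_no_coding", 180.0)
        assert set(truth.preferred_phase_deg.values()) == {180.0}
        assert truth.coupling_depth == small_config.coupling_depth

    def test_no_pac_mode_zeroes_depth(self, small_config):
        _, truth = generate_null_session(small_config, "no_pac")
        assert truth.coupling_depth == 0.0

    def test_locked_mode_marks_ground_truth(self, small_config):
        _, truth = generate_null_session(small_config, "coding_no_pac")
        assert truth.coupling_depth == 0.0
        assert truth.phase_locked_categories

    def test_unknown_mode_rejected(self, small_config):
        with pytest.raises(ValueError, match="mode"):
            generate_null_session(small_config, "nonsense")

    def test_onset_phase_locking_only_in_locked_mode(self, small_config):
        """Locked sessions concentrate the modulator phase at onset per
        category; ordinary sessions leave it uniform."""
        locked, truth = generate_null_session(small_config, "coding_no_pac")
        plain, _ = generate_null_session(small_config, "no_pac")
        for session, expect_locked in ((locked, True), (plain, False)):
            dec = morlet_decompose(session.concatenated, 1000.0, [1.0])
            onsets = session.concat_map + session.onset_sample
            sel = session.labels == "scene"
            r = resultant_vector_length(dec.phase[0][onsets[sel]].astype(float))
            assert (r > 0.7) == expect_locked


class TestPersistence:
    def test_npz_round_trip(self, tmp_path, small_config):
        cfg = dataclasses.replace(small_config, n_trials_per_category=2)
        session, truth = generate_session(cfg)
        path = tmp_path / "session.npz"
        write_dataset(session, truth, path)
        loaded, loaded_truth = read_dataset(path)
        np.testing.assert_allclose(loaded.epochs, session.epochs)
        np.testing.assert_array_equal(loaded.labels, session.labels)
        assert loaded.onset_sample == session.onset_sample
        assert loaded_truth == truth

    def test_missing_file_reported(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_dataset(tmp_path / "absent.npz")

    def test_corrupt_file_names_missing_field(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, epochs=np.zeros((2, 10)))
        with pytest.raises(ValueError, match="sampling_rate"):
            read_dataset(path)

    def test_three_category_file_rejected(self, tmp_path):
        path = tmp_path / "threecat.npz"
        np.savez(
            path,
            epochs=np.zeros((3, 100)),
            sampling_rate=np.array(1000.0),
            labels=np.array(["house", "tool", "scene"]),
            onset_sample=np.array(10),
            stimulus_duration=np.array(1.0),
            ground_truth_json=np.array(GroundTruth(1.0, 84.0, {}, 0.8).to_json()),
        )
        with pytest.raises(ValueError, match="cardinality"):
            read_dataset(path)

    def test_events_csv_round_trip(self, tmp_path, small_config):
        cfg = dataclasses.replace(small_config, n_trials_per_category=2)
        session, _ = generate_session(cfg)
        path = events_to_csv(session, tmp_path / "events.csv")
        onsets, labels = events_from_csv(path)
        np.testing.assert_array_equal(labels, session.labels)
        np.testing.assert_array_equal(
            onsets, session.concat_map + session.onset_sample
        )
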