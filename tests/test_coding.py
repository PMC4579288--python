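"""Difference scores, clustering gate, PR, shuffle null and controls."""

import numpy as np
import pytest

from phasecode.coding import (
    CategoryPhaseSet,
    category_phase_locking_map,
    clustering_across_frequencies,
    clustering_gate,
    collect_hfa_phases,
    difference_scores,
    ds_phase_uniformity,
    gate_alpha,
    phase_difference_by_ds,
    phase_representation,
    pr_window_shuffle_null,
    time_resolved_category_contrast,
)
from phasecode.spectral import HFAEvents

DEG = np.pi / 180.0
CATS = ("house", "tool", "scene", "face")


def _cps(phase_sets):
    return CategoryPhaseSet(frequency=1.0, phases=dict(zip(CATS, phase_sets)))


class TestDifferenceScores:
    def test_identical_distributions_score_zero(self, rng):
        base = rng.vonmises(0.5, 5.0, 100)
        ds, _ = difference_scores(_cps([base, base, base, base]))
        assert ds == {c: 0 for c in CATS}

    def test_one_offset_category(self, rng):
        """One category at 90 deg, three at 270: the offset category scores 3,
        the others 1 (their only difference is with the offset one)."""
        sets = [rng.vonmises(90 * DEG, 5.0, 100)] + [
            rng.vonmises(270 * DEG, 5.0, 100) for _ in range(3)
        ]
        ds, _ = difference_scores(_cps(sets))
        assert ds["house"] == 3
        assert ds["tool"] == ds["scene"] == ds["face"] == 1

    def test_full_separation(self, rng):
        sets = [rng.vonmises(mu * DEG, 4.0, 100) for mu in (0, 90, 180, 270)]
        ds, pairwise = difference_scores(_cps(sets))
        assert ds == {c: 3 for c in CATS}
        assert all(p < 0.001 for p in pairwise.values())

    def test_relabelling_permutes_scores(self, rng):
        sets = [rng.vonmises(mu * DEG, 5.0, 80) for mu in (0, 0, 120, 240)]
        ds, _ = difference_scores(_cps(sets))
        ds_perm, _ = difference_scores(_cps(sets[::-1]))
        assert [ds[c] for c in CATS] == [ds_perm[c] for c in CATS][::-1]

    def test_empty_category_rejected(self, rng):
        sets = [rng.vonmises(0, 5, 50)] * 3 + [np.empty(0)]
        with pytest.raises(ValueError):
            difference_scores(_cps(sets))


class TestClusteringGate:
    def test_uniform_phases_fail(self, rng):
        sets = [rng.uniform(-np.pi, np.pi, 200) for _ in range(4)]
        gate, ok = clustering_gate(_cps(sets), alpha_gate=1e-4)
        assert not ok and not any(gate.values())

    def test_concentrated_phases_pass(self, rng):
        sets = [rng.vonmises(mu * DEG, 4.0, 100) for mu in (0, 90, 180, 270)]
        gate, ok = clustering_gate(_cps(sets), alpha_gate=1e-4)
        assert ok and all(gate.values())

    def test_electrode_fails_if_any_category_fails(self, rng):
        sets = [rng.vonmises(0.0, 4.0, 100) for _ in range(3)]
        sets.append(rng.uniform(-np.pi, np.pi, 100))
        gate, ok = clustering_gate(_cps(sets), alpha_gate=1e-4)
        assert not ok and sum(gate.values()) == 3

    def test_family_alpha_matches_printed_value(self):
        """0.01 / (72 PAC+ electrodes x 4 categories) < the printed 4e-5."""
        alpha = gate_alpha(72)
        assert alpha == pytest.approx(0.01 / 288)
        assert alpha < 0.00004


class TestPhaseRepresentation:
    @pytest.mark.parametrize(
        "ds, r, expected", [(0, 0.9, 0.0), (3, 0.5, 1.5), (2, 1.0, 2.0)]
    )
    def test_product(self, ds, r, expected):
        assert phase_representation(ds, r) == expected

    def test_range_validation(self):
        with pytest.raises(ValueError):
            phase_representation(4, 0.5)
        with pytest.raises(ValueError):
            phase_representation(2, 1.5)


class TestCollectPhases:
    def test_no_windows_gives_empty_sets(self, coding_session):
        session, _ = coding_session
        hfa = HFAEvents(
            frequency=1.0,
            windows=np.empty((0, 2), dtype=int),
            events=np.empty(0, dtype=int),
        )
        cps = collect_hfa_phases(np.zeros(session.concatenated.size), hfa, session)
        assert all(n == 0 for n in cps.counts.values())

    def test_stimulus_restriction_is_monotone(self, coding_analysis):
        inter = coding_analysis["inter"]
        rep = coding_analysis["report"]
        session = coding_analysis["session"]
        hfa = inter["event_sets"][rep.peak_modulated_freq]
        series = inter["phase_decomp"].phase[
            inter["phase_decomp"].freq_index(rep.f_max)
        ]
        unrestricted = collect_hfa_phases(series, hfa, session, stimulus_only=False)
        restricted = collect_hfa_phases(series, hfa, session, stimulus_only=True)
        for c in session.categories:
            assert restricted.counts[c] <= unrestricted.counts[c]

    def test_category_phase_means_recover_ground_truth(self, coding_analysis):
        """Circular means of per-category HFA phases within 20 deg of truth."""
        rep = coding_analysis["report"]
        truth = coding_analysis["truth"]
        for c, entry in rep.coding.items():
            err = abs(
                (entry["mean_phase_deg"] - truth.preferred_phase_deg[c] + 180) % 360
                - 180
            )
            assert err < 20.0, f"{c}: {err:.1f} deg"


class TestWindowShuffleNull:
    def test_strong_coding_beats_the_null(self, coding_analysis):
        pr = coding_analysis["inter"]["pr_null"]
        assert pr["defined"]
        assert all(pct >= 95.0 for pct in pr["percentile"].values())
        assert all(ds == 3 for ds in pr["observed_ds"].values())

    def test_shared_phase_session_stays_inside_the_null(self, shared_analysis):
        pr = shared_analysis["inter"]["pr_null"]
        assert pr["defined"]
        # DS = 0 forces PR = 0; surrogate PRs are also >= 0, so percentiles
        # cannot reach the 95th
        assert all(pct < 95.0 for pct in pr["percentile"].values())

    def test_shuffle_reproducible_under_seed(self, coding_analysis):
        session = coding_analysis["session"]
        inter = coding_analysis["inter"]
        rep = coding_analysis["report"]
        hfa = inter["event_sets"][rep.peak_modulated_freq]
        series = inter["phase_decomp"].phase[
            inter["phase_decomp"].freq_index(rep.f_max)
        ]
        a = pr_window_shuffle_null(hfa, series, session, 25, seed=3)
        b = pr_window_shuffle_null(hfa, series, session, 25, seed=3)
        np.testing.assert_array_equal(a["null_pr"], b["null_pr"])

    def test_too_few_windows_flagged(self, coding_session):
        session, _ = coding_session
        hfa = HFAEvents(
            frequency=1.0, windows=np.array([[100, 200]]), events=np.array([150])
        )
        out = pr_window_shuffle_null(
            hfa, np.zeros(session.concatenated.size), session, 25, seed=0
        )
        assert not out["defined"]


class TestPopulationSummaries:
    def _result(self, ds_map, mean_map, freq=1.0):
        from phasecode.coding import PhaseCodingResult

        return PhaseCodingResult(
            frequency=freq,
            counts={c: 50 for c in CATS},
            r={c: 0.5 for c in CATS},
            mean_phase_deg=mean_map,
            ds=ds_map,
            pairwise_p={},
            pr={c: ds_map[c] * 0.5 for c in CATS},
        )

    def test_symmetric_phases_give_120_mean_separation(self):
        res = self._result(
            {c: 3 for c in CATS},
            dict(zip(CATS, (0.0, 90.0, 180.0, 270.0))),
        )
        out = phase_difference_by_ds([res])
        assert out[3] == pytest.approx((90 + 180 + 90) / 3, abs=1e-9)

    def test_identical_phases_give_zero_at_ds_zero(self):
        res = self._result({c: 0 for c in CATS}, {c: 45.0 for c in CATS})
        out = phase_difference_by_ds([res])
        assert out[0] == pytest.approx(0.0, abs=1e-9)

    def test_uniformly_placed_means_look_uniform(self):
        res = self._result(
            {c: 3 for c in CATS}, dict(zip(CATS, (0.0, 90.0, 180.0, 270.0)))
        )
        out = ds_phase_uniformity([res] * 3)
        assert out["rayleigh_by_ds"][3]["p"] > 0.9
        assert out["ds3_counts_by_category"] == {c: 3 for c in CATS}

    def test_clustered_means_detected(self):
        res = self._result({c: 3 for c in CATS}, {c: 180.0 for c in CATS})
        out = ds_phase_uniformity([res] * 5)
        assert out["rayleigh_by_ds"][3]["p"] < 0.01


class TestPhaseLockingMap:
    def test_locked_session_detected_exclusively(self, locked_analysis):
        """Stimulus-onset phase locking per category is picked up at the
        modulator frequency during the stimulus period."""
        session = locked_analysis["session"]
        dec = locked_analysis["inter"]["phase_decomp"]
        out = category_phase_locking_map(session, dec, alpha=1e-6, time_step=25)
        k1 = int(np.argmin(np.abs(out["frequencies"] - 1.0)))
        k7 = int(np.argmin(np.abs(out["frequencies"] - 7.0)))
        stim_cols = (out["times_ms"] >= 0) & (out["times_ms"] <= 1000)
        for c in session.categories:
            # strong locking at the modulator frequency, none at 7 Hz
            assert out["significant"][c][k1][stim_cols].mean() > 0.5
            assert out["significant"][c][k7][stim_cols].mean() < 0.1

    def test_unlocked_session_stays_near_alpha(self, no_pac_analysis):
        session = no_pac_analysis["session"]
        dec = no_pac_analysis["inter"]["phase_decomp"]
        out = category_phase_locking_map(session, dec, alpha=1e-6, time_step=25)
        rate = np.mean([out["significant"][c].mean() for c in session.categories])
        assert rate < 0.01

    def test_masks_are_boolean(self, no_pac_analysis):
        out = category_phase_locking_map(
            no_pac_analysis["session"],
            no_pac_analysis["inter"]["phase_decomp"],
            time_step=50,
        )
        for mask in out["exclusive"].values():
            assert mask.dtype == bool


class TestFrequencySweep:
    def test_clustering_peaks_at_the_modulator(self, coding_analysis):
        """Summed clustering across a coarse sweep peaks at 1 Hz, not at
        neighboring frequencies."""
        session = coding_analysis["session"]
        rep = coding_analysis["report"]
        hfa = coding_analysis["inter"]["event_sets"][rep.peak_modulated_freq]
        grid = np.array([0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 8.0])
        out = clustering_across_frequencies(
            session.concatenated, session.sampling_rate, hfa, session, grid
        )
        assert grid[int(np.argmax(out["summed_clustering"]))] == 1.0
        assert out["percent_of_max"].max() == pytest.approx(100.0)

    def test_fmin_clustering_below_fmax(self, coding_analysis):
        """Phase clustering at F_max exceeds clustering at F_min."""
        fmin = coding_analysis["inter"]["fmin"]
        assert fmin["mean_delta_r"] > 0.2
        assert set(fmin["f_min_result"].r.keys()) == set(CATS)


class TestTimeResolvedContrast:
    def test_injected_power_offset_detected(self, rng):
        n_trials, n_times = 48, 60
        labels = np.array(list(CATS) * (n_trials // 4))
        values = rng.standard_normal((n_trials, n_times))
        values[labels == "face", 20:40] += 2.5
        out = time_resolved_category_contrast(
            values, labels, kind="power", n_perm=200, seed=1
        )
        face_row = out["ds_counts"][out["categories"].index("face")]
        assert face_row[25:35].min() == 3
        assert face_row[:10].max() <= 1

    def test_null_false_positive_rate_near_alpha(self, rng):
        labels = np.array(list(CATS) * 12)
        values = rng.standard_normal((48, 80))
        out = time_resolved_category_contrast(
            values, labels, kind="power", n_perm=200, alpha=0.05, seed=2
        )
        rate = np.mean([mask.mean() for mask in out["significant"].values()])
        assert rate < 0.12

    def test_phase_contrast_output_shape(self, rng):
        labels = np.array(list(CATS) * 10)
        values = rng.vonmises(0.0, 2.0, size=(40, 30))
        out = time_resolved_category_contrast(
            values, labels, kind="phase", n_perm=100, seed=3
        )
        assert out["ds_counts"].shape == (4, 30)
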