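"""Oscillatory-triggered coupling: segments, strengths, surrogates, PAC+."""

import numpy as np
import pytest

from phasecode.otc import (
    characterize_modulatory_signal,
    extract_segments,
    grid_spectrum,
    modulation_strength,
    modulatory_signal,
    pac_z_threshold,
    surrogate_z,
)
from phasecode.spectral import F_PHASE_GRID

RATE = 1000.0


class TestSegments:
    def test_single_event_returns_raw_slice(self, rng):
        raw = rng.standard_normal(10_000)
        stack, kept = extract_segments(raw, np.array([5000]), half_width=1000)
        assert stack.shape == (1, 2001)
        np.testing.assert_array_equal(stack[0], raw[4000:6001])

    def test_edge_events_dropped(self, rng):
        raw = rng.standard_normal(5000)
        stack, kept = extract_segments(raw, np.array([500, 2500, 4800]), 1000)
        np.testing.assert_array_equal(kept, [2500])

    def test_stack_height_equals_event_count(self, rng):
        raw = rng.standard_normal(50_000)
        events = rng.integers(1000, 49_000, size=37)
        stack, kept = extract_segments(raw, events, 1000)
        assert stack.shape[0] == kept.size == 37

    def test_no_usable_events_gives_empty_stack(self, rng):
        stack, kept = extract_segments(rng.standard_normal(1500), np.array([10]), 1000)
        assert stack.shape[0] == 0 and kept.size == 0


class TestModulatorySignal:
    def test_sum_not_mean(self):
        stack = np.ones((5, 11))
        np.testing.assert_array_equal(modulatory_signal(stack), np.full(11, 5.0))

    def test_single_segment_identity(self, rng):
        seg = rng.standard_normal(201)
        np.testing.assert_array_equal(modulatory_signal(seg[None, :]), seg)

    def test_peak_locked_events_sum_coherently(self):
        """k events at the peaks of a 2 Hz cosine of amplitude A give a
        modulatory signal ~ k*A*cos(2 pi 2 t) with peak-to-trough ~ 2kA."""
        amp, k = 1.5, 12
        t = np.arange(60_000) / RATE
        raw = amp * np.cos(2 * np.pi * 2.0 * t)
        events = np.flatnonzero(np.isclose(np.mod(t, 0.5), 0.0))[2:-2][:k]
        stack, kept = extract_segments(raw, events, 1000)
        sig = modulatory_signal(stack)
        assert kept.size == k
        assert modulation_strength(sig) == pytest.approx(2 * k * amp, rel=1e-6)
        assert sig[1000] == pytest.approx(k * amp, rel=1e-6)

    def test_linearity_over_event_set_union(self, rng):
        raw = rng.standard_normal(30_000)
        ev_a = rng.integers(1000, 29_000, 10)
        ev_b = rng.integers(1000, 29_000, 15)
        sig_a = modulatory_signal(extract_segments(raw, ev_a, 1000)[0])
        sig_b = modulatory_signal(extract_segments(raw, ev_b, 1000)[0])
        sig_union = modulatory_signal(
            extract_segments(raw, np.r_[ev_a, ev_b], 1000)[0]
        )
        np.testing.assert_allclose(sig_union, sig_a + sig_b, atol=1e-9)


class TestStrength:
    @pytest.mark.parametrize(
        "signal, expected",
        [(np.cos(np.linspace(0, 2 * np.pi, 1001)), 2.0), (np.full(100, 3.0), 0.0)],
    )
    def test_analytic(self, signal, expected):
        assert modulation_strength(signal) == pytest.approx(expected, abs=1e-6)

    def test_positive_homogeneity(self, rng):
        x = rng.standard_normal(500)
        assert modulation_strength(3.5 * x) == pytest.approx(
            3.5 * modulation_strength(x)
        )


class TestSurrogateZ:
    def test_observed_at_surrogate_mean_gives_zero(self, rng):
        raw = rng.standard_normal(30_000)
        _, strengths = surrogate_z(raw, 0.0, 20, 50, seed=1)
        z, _ = surrogate_z(raw, float(strengths.mean()), 20, 50, seed=1)
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_random_events_in_noise_stay_null(self, rng):
        """Uniform-random events in noise: |z| < 2 in >= 95% of runs."""
        inside = 0
        runs = 40
        for i in range(runs):
            local = np.random.default_rng(1000 + i)
            raw = local.standard_normal(20_000)
            events = local.integers(1000, 19_000, 30)
            stack, kept = extract_segments(raw, events, 1000)
            s = modulation_strength(modulatory_signal(stack))
            z, _ = surrogate_z(raw, s, kept.size, 50, seed=2000 + i)
            inside += abs(z) < 2.0
        assert inside / runs >= 0.9

    def test_seeded_reproducibility(self, rng):
        raw = rng.standard_normal(20_000)
        z1, s1 = surrogate_z(raw, 5.0, 10, 30, seed=7)
        z2, s2 = surrogate_z(raw, 5.0, 10, 30, seed=7)
        assert z1 == z2
        np.testing.assert_array_equal(s1, s2)

    def test_too_few_surrogates_rejected(self, rng):
        with pytest.raises(ValueError):
            surrogate_z(rng.standard_normal(5000), 1.0, 5, 1)


class TestThresholdArithmetic:
    def test_printed_threshold_recovered(self):
        """23 gamma frequencies x 167 electrodes -> z ~ 4.35 (two-sided)."""
        assert pac_z_threshold(23, 167) == pytest.approx(4.35, abs=0.02)

    def test_tail_probability_below_five_in_ten_thousand_percent(self):
        from scipy.stats import norm

        assert 2 * norm.sf(4.35) < 0.00005

    def test_threshold_grows_with_family_size(self):
        assert pac_z_threshold(23, 167) > pac_z_threshold(23, 10) > pac_z_threshold(1, 1)


class TestCharacterization:
    def test_trough_at_lag_zero_reads_180_degrees(self):
        """A 2.5 Hz cosine with its trough at the event time: F_max 2.5 Hz,
        preferred phase 180 deg (trough convention)."""
        t = (np.arange(2001) - 1000) / RATE
        sig = -np.cos(2 * np.pi * 2.5 * t)
        out = characterize_modulatory_signal(sig, RATE)
        assert out["f_max"] == 2.5
        assert out["preferred_phase_deg"] == pytest.approx(180.0, abs=1.0)

    def test_peak_at_lag_zero_reads_zero_degrees(self):
        t = (np.arange(2001) - 1000) / RATE
        out = characterize_modulatory_signal(np.cos(2 * np.pi * 3.0 * t), RATE)
        assert out["preferred_phase_deg"] == pytest.approx(0.0, abs=1.0) or (
            out["preferred_phase_deg"] == pytest.approx(360.0, abs=1.0)
        )

    def test_two_tone_mixture_against_dense_dft_oracle(self):
        """F_max from the dominant tone; F_min matches a brute-force DFT scan."""
        t = (np.arange(2001) - 1000) / RATE
        sig = 2.0 * np.cos(2 * np.pi * 1.0 * t) + 1.0 * np.cos(2 * np.pi * 7.0 * t)
        out = characterize_modulatory_signal(sig, RATE)
        assert out["f_max"] == 1.0
        # oracle: explicit DFT magnitude at each grid frequency
        x = sig - sig.mean()
        mags = [
            np.abs(np.sum(x * np.exp(-2j * np.pi * f * t))) for f in F_PHASE_GRID
        ]
        assert out["f_min"] == F_PHASE_GRID[int(np.argmin(mags))]

    def test_flat_spectrum_flagged_and_tied_to_lowest(self):
        out = characterize_modulatory_signal(np.zeros(2001), RATE)
        assert out["flat_spectrum"]
        assert out["f_min"] == F_PHASE_GRID[0]

    def test_grid_spectrum_angle_is_cosine_phase_at_center(self):
        t = (np.arange(2001) - 1000) / RATE
        phi = 0.8
        _, coeff = grid_spectrum(np.cos(2 * np.pi * 4.0 * t + phi), RATE, np.array([4.0]))
        assert np.angle(coeff[0]) == pytest.approx(phi, abs=0.01)


class TestParameterRecoveryProfile:
    def test_peak_gamma_and_modulator_recovered(self, coding_analysis):
        """Coding session: peak-z gamma frequency near the 84 Hz carrier,
        F_max at the 1 Hz modulator, z above the 23x167 family threshold."""
        rep = coding_analysis["report"]
        truth = coding_analysis["truth"]
        assert abs(rep.peak_modulated_freq - truth.carrier_freq) <= 4.0
        assert abs(rep.f_max - truth.modulator_freq) <= 0.5
        assert rep.max_z > rep.z_threshold

    def test_shared_phase_preferred_at_trough(self, shared_analysis):
        """Shared 180-deg coupling: OTC preferred phase at the trough."""
        rep = shared_analysis["report"]
        err = abs((rep.preferred_phase_deg - 180.0 + 180.0) % 360.0 - 180.0)
        assert err < 20.0

    def test_pac_plus_requires_spectral_peak_match(self, coding_analysis):
        """Criterion 2 of the PAC+ verdict: raw and modulatory spectra agree."""
        rep = coding_analysis["report"]
        prof = coding_analysis["inter"]["profile"]
        assert rep.pac_plus
        assert prof.diagnostics["criterion_peak_match"]
        assert prof.diagnostics["raw_spectrum_peak_hz"] == 1.0
        assert prof.diagnostics["modulatory_spectrum_peak_hz"] == 1.0
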