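"""Time-frequency decomposition and high-frequency-activity detection.

The analysis operates on the trial-concatenated series with Morlet wavelet
convolution (7 cycles) on two grids: a slow "phase" grid (0.5-12 Hz in
0.5 Hz steps) and a gamma "amplitude" grid (32-120 Hz in 4 Hz steps).
At each gamma frequency the power time course is z-scored and maximal
contiguous runs strictly above the empirical 95th percentile become "HFA
windows"; the peak-power sample inside each window is the "HFA event"
used as the time-locking point for oscillatory-triggered coupling.

Wavelets are zero-mean and unit-energy; the absolute power scale cancels
in the z-scoring. Samples within three wavelet SDs of either end of the
series are flagged and excluded from percentile estimation and window
detection, bounding edge bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from ._utils import boolean_runs, split_runs_at

__all__ = [
    "F_PHASE_GRID",
    "F_AMP_GRID",
    "SpectralDecomposition",
    "HFAEvents",
    "morlet_decompose",
    "zscore_power",
    "detect_hfa_windows",
    "locate_hfa_events",
    "detect_hfa_event_sets",
    "hfa_trial_timecourse",
]

#: slow (modulating) frequency grid, Hz
F_PHASE_GRID = np.arange(0.5, 12.0 + 1e-9, 0.5)
#: gamma (modulated) frequency grid, Hz — 23 center frequencies
F_AMP_GRID = np.arange(32.0, 120.0 + 1e-9, 4.0)


def _morlet_wavelet(freq: float, rate: float, n_cycles: float = 7.0):
    """Complex Morlet wavelet, zero-mean and unit-energy.

    Returns (wavelet, sigma_t_samples). Support truncated at 4 SDs.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    osc = np.exp(2j * np.pi * freq * t)
    # subtract the gaussian-weighted mean of the oscillation -> zero mean
    correction = np.sum(osc * gauss) / np.sum(gauss)
    w = (osc - correction) * gauss
    w /= np.sqrt(np.sum(np.abs(w) ** 2))
    return w, sigma_t * rate


@dataclass
class SpectralDecomposition:
    """Wavelet power and phase per analysis frequency for one series.

    power: (n_freqs, n_samples) nonnegative; phase: radians in (-pi, pi].
    ``edge_samples[k]`` samples at each end of the series are inside the
    wavelet support of frequency k and should not inform statistics.
    ``power_calibration[k]`` scales time-averaged power at a pure tone of
    amplitude A to A**2 / 2.
    """

    frequencies: np.ndarray
    power: np.ndarray
    phase: np.ndarray
    sampling_rate: float
    n_cycles: float
    edge_samples: np.ndarray
    power_calibration: np.ndarray

    def freq_index(self, freq: float) -> int:
        idx = int(np.argmin(np.abs(self.frequencies - freq)))
        if abs(self.frequencies[idx] - freq) > 1e-6:
            raise KeyError(f"{freq} Hz is not on the analysis grid")
        return idx

    def valid_mask(self, freq: float) -> np.ndarray:
        """True where the sample is outside the edge-flagged margins."""
        n_edge = int(self.edge_samples[self.freq_index(freq)])
        mask = np.ones(self.power.shape[1], dtype=bool)
        if n_edge > 0:
            mask[:n_edge] = False
            mask[-n_edge:] = False
        return mask


def morlet_decompose(
    signal: np.ndarray,
    rate: float,
    frequencies,
    n_cycles: float = 7.0,
) -> SpectralDecomposition:
    """Morlet wavelet decomposition (same-length complex convolution).

    power = squared magnitude; phase = angle, which for a cosine input
    advances linearly through (-pi, pi] with 0 at the cosine peak.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(frequencies >= rate / 2.0):
        raise ValueError("grid frequency at or above Nyquist")
    if np.any(frequencies <= 0):
        raise ValueError("frequencies must be positive")
    n = signal.size
    n_f = frequencies.size
    power = np.empty((n_f, n), dtype=np.float32)
    phase = np.empty((n_f, n), dtype=np.float32)
    edge = np.empty(n_f, dtype=int)
    cal = np.empty(n_f)
    for k, f in enumerate(frequencies):
        w, sigma_samples = _morlet_wavelet(f, rate, n_cycles)
        if w.size > 2 * n:
            raise ValueError(
                f"signal too short for the wavelet support at {f} Hz "
                f"({w.size} > 2x{n} samples)"
            )
        conv = fftconvolve(signal, w, mode="same")
        power[k] = (np.abs(conv) ** 2).astype(np.float32)
        phase[k] = np.angle(conv).astype(np.float32)
        edge[k] = min(int(np.ceil(3.0 * sigma_samples)), n // 2)
        # tone of amplitude A gives |conv| ~ A/2 * sum|w|, so scaling power
        # by 2/sum|w|^2 maps its time-averaged power to A^2/2
        gauss_sum = np.sum(np.abs(w))
        cal[k] = 2.0 / gauss_sum**2
    return SpectralDecomposition(
        frequencies=frequencies,
        power=power,
        phase=phase,
        sampling_rate=rate,
        n_cycles=n_cycles,
        edge_samples=edge,
        power_calibration=cal,
    )


def zscore_power(power: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score a power time course over the analyzed samples.

    Mean and SD are estimated on ``valid_mask`` samples (all samples by
    default) and applied to the whole series. Zero variance is an error.
    """
    power = np.asarray(power, dtype=float).ravel()
    ref = power if valid_mask is None else power[np.asarray(valid_mask, dtype=bool)]
    mu, sd = ref.mean(), ref.std()
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance power series")
    return (power - mu) / sd


@dataclass
class HFAEvents:
    """Supra-threshold HFA windows and their peak-power events at one frequency.

    windows: (n, 2) half-open [start, end) sample intervals, disjoint
    maximal runs strictly above ``threshold``; events: one sample index per
    window, at the window's power maximum (earliest on ties).
    """

    frequency: float
    windows: np.ndarray
    events: np.ndarray = field(default=None)
    threshold: float = np.nan

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_mask(self, n_samples: int) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for start, end in self.windows:
            mask[start:end] = True
        return mask


def detect_hfa_windows(
    z: np.ndarray,
    percentile: float = 95.0,
    valid_mask: np.ndarray | None = None,
    boundaries: np.ndarray | None = None,
    frequency: float = np.nan,
) -> HFAEvents:
    """Find maximal contiguous runs strictly above the empirical percentile.

    The threshold is the given percentile of the valid (non-edge) samples
    of the full concatenated series; runs crossing an epoch boundary are
    split there, since phase continuity is not guaranteed across the
    concatenation joints.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    z = np.asarray(z, dtype=float).ravel()
    if valid_mask is None:
        valid_mask = np.ones(z.size, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    threshold = float(np.percentile(z[valid_mask], percentile))
    above = (z > threshold) & valid_mask
    runs = boolean_runs(above)
    if boundaries is not None:
        runs = split_runs_at(runs, np.asarray(boundaries, dtype=int))
    return HFAEvents(frequency=frequency, windows=runs, threshold=threshold)


def locate_hfa_events(hfa: HFAEvents, z: np.ndarray) -> HFAEvents:
    """Mark one event per window at the power maximum (earliest on ties)."""
    z = np.asarray(z, dtype=float).ravel()
    events = np.array(
        [start + int(np.argmax(z[start:end])) for start, end in hfa.windows],
        dtype=int,
    )
    hfa.events = events
    return hfa


def detect_hfa_event_sets(
    decomp: SpectralDecomposition,
    percentile: float = 95.0,
    boundaries: np.ndarray | None = None,
) -> dict[float, HFAEvents]:
    """Windows and events at every frequency of a (gamma) decomposition."""
    out = {}
    for k, f in enumerate(decomp.frequencies):
        z = zscore_power(decomp.power[k], valid_mask=decomp.valid_mask(f))
        hfa = detect_hfa_windows(
            z,
            percentile=percentile,
            valid_mask=decomp.valid_mask(f),
            boundaries=boundaries,
            frequency=float(f),
        )
        out[float(f)] = locate_hfa_events(hfa, z)
    return out


def hfa_trial_timecourse(
    hfa: HFAEvents,
    session,
    bin_ms: float = 50.0,
):
    """Per-category percentage of trials with >= 1 HFA event per time bin.

    Returns ``(timecourse, frac_any_window)`` where ``timecourse`` is a
    DataFrame indexed by bin start time (ms relative to stimulus onset)
    with one column per category, and ``frac_any_window`` is the fraction
    of trials containing at least one HFA window anywhere in the epoch.
    """
    import pandas as pd

    n_trials, n_samp = session.n_trials, session.n_samples
    bin_samples = max(int(round(bin_ms * session.sampling_rate / 1000.0)), 1)
    n_bins = int(np.ceil(n_samp / bin_samples))
    counts = {c: np.zeros(n_bins) for c in session.categories}
    trials_per_cat = session.category_counts()

    if hfa.events is not None and len(hfa.events):
        trial_idx, offset = session.concat_to_trial(hfa.events)
        bins = offset // bin_samples
        for c in session.categories:
            sel = session.labels[trial_idx] == c
            if np.any(sel):
                # a trial counts once per bin, however many events it has
                pairs = np.unique(np.stack([trial_idx[sel], bins[sel]]), axis=1)
                np.add.at(counts[c], pairs[1], 1.0)
    times_ms = (
        (np.arange(n_bins) * bin_samples - session.onset_sample)
        / session.sampling_rate
        * 1000.0
    )
    timecourse = pd.DataFrame(
        {
            c: 100.0 * counts[c] / max(trials_per_cat[c], 1)
            for c in session.categories
        },
        index=pd.Index(times_ms, name="time_ms"),
    )

    trials_with_window = np.zeros(n_trials, dtype=bool)
    for start, end in hfa.windows:
        t0, _ = session.concat_to_trial(start)
        t1, _ = session.concat_to_trial(max(end - 1, start))
        trials_with_window[t0 : t1 + 1] = True
    frac_any_window = float(np.mean(trials_with_window)) if n_trials else 0.0
    return timecourse, frac_any_window
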