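"""Synthetic ECoG session generator with known cross-frequency structure.

One generated "session" stands for one electrode: stimulus-locked epochs of
a slow modulating rhythm (delta band by default) plus 1/f background noise
plus a gamma carrier whose amplitude envelope is tied to the modulator
phase through a von Mises window centered on the trial category's
preferred phase. Gamma gates on ``hfa_latency`` ms after stimulus onset
and off at image offset, emulating stimulus-driven high-frequency
activity. Ground truth (modulator/carrier frequency, per-category
preferred phase, coupling depth) travels with every session so downstream
stages can be scored for parameter recovery.

Conventions
-----------
Modulator phase is the *cosine* phase: 0 deg = oscillation peak,
180 deg = trough. Epoch modulator phase is uniform-random per trial
(stimulus onset carries no phase information) unless
``phase_locked_categories`` is set, which instead locks the onset phase to
the category's preferred phase — the "phase coding without coupling"
scenario used by the control analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import i0

from ._utils import as_rng, deg_to_rad
from .epochs import CATEGORIES, TrialEpochSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_session",
    "generate_null_session",
    "write_dataset",
    "read_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic electrode-session.

    Defaults follow the experimental design the generator emulates:
    1000 Hz sampling, epochs from 750 ms before to 1500 ms after image
    onset, 120 trials per category (480 total), 1 s image presentation,
    HFA onset ~150 ms after stimulus onset. ``noise_sd`` defaults to a
    ~10 dB modulator signal-to-noise ratio for a unit-amplitude modulator.
    """

    sampling_rate: float = 1000.0
    n_trials_per_category: int = 120
    epoch_window_ms: tuple[float, float] = (-750.0, 1500.0)
    modulator_freq: float = 1.0
    carrier_freq: float = 84.0
    category_preferred_phases: tuple = (0.0, 90.0, 180.0, 270.0)  # degrees
    coupling_depth: float = 0.8
    coupling_concentration: float = 4.0  # von Mises kappa
    hfa_latency: float = 150.0  # ms after onset
    stimulus_duration: float = 1.0  # s on screen
    modulator_amp: float = 1.0  # volts
    gamma_amp: float = 0.8  # peak carrier amplitude, volts
    gamma_baseline_frac: float = 0.15  # outside-stimulus gamma level
    slow_potential_frac: float = 1.2  # burst-locked slow field, x gamma_amp x depth
    slow_potential_concentration: float = 8.0  # von Mises kappa of the slow field
    gamma_background_sd: float = 0.6  # broadband (30-200 Hz) background, volts
    noise_sd: float = 0.224  # volts
    pink_noise_exponent: float = 1.0
    phase_locked_categories: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.coupling_concentration < 0:
            raise ValueError("von Mises concentration kappa must be >= 0")
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError("coupling_depth must lie in [0, 1]")
        phases = np.asarray(self.category_preferred_phases, dtype=float)
        if phases.shape != (4,):
            raise ValueError("category_preferred_phases needs exactly 4 entries")
        if np.any(phases < 0) or np.any(phases >= 360):
            raise ValueError("preferred phases must lie in [0, 360) degrees")
        window_s = (self.epoch_window_ms[1] - self.epoch_window_ms[0]) / 1000.0
        if window_s <= 0:
            raise ValueError("empty epoch window")
        n_cycles = window_s * self.modulator_freq
        if n_cycles < 1.0:
            raise ValueError(
                f"epoch window covers {n_cycles:.2f} modulator cycles; "
                "at least one full period is required"
            )

    @property
    def n_epoch_samples(self) -> int:
        return int(
            round(
                (self.epoch_window_ms[1] - self.epoch_window_ms[0])
                * self.sampling_rate
                / 1000.0
            )
        )

    @property
    def onset_sample(self) -> int:
        return int(round(-self.epoch_window_ms[0] * self.sampling_rate / 1000.0))

    def to_json(self) -> str:
        d = asdict(self)
        d["epoch_window_ms"] = list(self.epoch_window_ms)
        d["category_preferred_phases"] = list(self.category_preferred_phases)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["epoch_window_ms"] = tuple(d["epoch_window_ms"])
        d["category_preferred_phases"] = tuple(d["category_preferred_phases"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually put into a session."""

    modulator_freq: float
    carrier_freq: float
    preferred_phase_deg: dict  # category -> degrees
    coupling_depth: float
    phase_locked_categories: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _pink_noise(rng, n, exponent, sd, rate, f_floor=0.5):
    """FFT-shaped 1/f**exponent noise, flat below ``f_floor`` Hz, zero mean."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    f_eff = np.maximum(freqs[nz], f_floor)
    shape[nz] = f_eff ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_noise(rng, n, f_lo, f_hi, sd, rate):
    """Flat-spectrum noise confined to [f_lo, f_hi] Hz; ongoing broadband gamma."""
    if sd <= 0:
        return 0.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = ((freqs >= f_lo) & (freqs <= f_hi)).astype(float)
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _smooth_gate(t, t_on, t_off, ramp=0.025):
    """Raised-cosine gate: 0 before t_on, 1 between, 0 after t_off (seconds)."""
    g = np.zeros_like(t)
    rising = (t >= t_on) & (t < t_on + ramp)
    g[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - t_on) / ramp))
    g[(t >= t_on + ramp) & (t < t_off)] = 1.0
    falling = (t >= t_off) & (t < t_off + ramp)
    g[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - t_off) / ramp))
    return g


def generate_session(config: SimulationConfig) -> tuple[TrialEpochSet, GroundTruth]:
    """Generate one electrode-session with the configured coupling structure.

    Returns the epoch set (trials in pseudo-random category order, balanced
    across the four categories) and the ground truth. Bit-identical for a
    fixed config, including the seed.
    """
    rng = as_rng(config.seed)
    n_samp = config.n_epoch_samples
    rate = config.sampling_rate
    t = (np.arange(n_samp) - config.onset_sample) / rate  # 0 at image onset

    labels = np.repeat(np.array(CATEGORIES), config.n_trials_per_category)
    labels = labels[rng.permutation(labels.size)]
    pref = {
        c: deg_to_rad(p)
        for c, p in zip(CATEGORIES, config.category_preferred_phases)
    }

    gate = _smooth_gate(t, config.hfa_latency / 1000.0, config.stimulus_duration)
    kappa = config.coupling_concentration
    depth = config.coupling_depth

    epochs = np.empty((labels.size, n_samp))
    for i, lab in enumerate(labels):
        if config.phase_locked_categories:
            # category-specific phase at stimulus onset (t = 0)
            phi0 = pref[lab]
        else:
            phi0 = rng.uniform(0.0, 2.0 * np.pi)
        theta = 2.0 * np.pi * config.modulator_freq * t + phi0
        modulator = config.modulator_amp * np.cos(theta)
        if depth > 0:
            vm = np.exp(kappa * (np.cos(theta - pref[lab]) - 1.0))
            env = (1.0 - depth) + depth * vm
            # bursts ride on a local slow field deflection, phase-mean removed;
            # without it, amplitude-only coupling at phasor-balanced category
            # phases is invisible to event-locked averaging
            kd = config.slow_potential_concentration
            vm_d = np.exp(kd * (np.cos(theta - pref[lab]) - 1.0))
            slow = (
                config.slow_potential_frac
                * config.gamma_amp
                * depth
                * gate
                * (vm_d - np.exp(-kd) * i0(kd))
            )
        else:
            env = np.ones_like(t)
            slow = 0.0
        psi = rng.uniform(0.0, 2.0 * np.pi)
        carrier = np.cos(2.0 * np.pi * config.carrier_freq * t + psi)
        gamma = config.gamma_amp * (config.gamma_baseline_frac + gate * env) * carrier
        noise = _pink_noise(
            rng, n_samp, config.pink_noise_exponent, config.noise_sd, rate
        )
        background = _band_noise(
            rng, n_samp, 30.0, 200.0, config.gamma_background_sd, rate
        )
        epochs[i] = modulator + gamma + slow + noise + background

    session = TrialEpochSet(
        epochs=epochs,
        sampling_rate=rate,
        labels=labels,
        onset_sample=config.onset_sample,
        stimulus_duration=config.stimulus_duration,
    )
    truth = GroundTruth(
        modulator_freq=config.modulator_freq,
        carrier_freq=config.carrier_freq,
        preferred_phase_deg={
            c: float(p) for c, p in zip(CATEGORIES, config.category_preferred_phases)
        },
        coupling_depth=depth,
        phase_locked_categories=config.phase_locked_categories,
    )
    return session, truth


def generate_null_session(
    config: SimulationConfig,
    mode: str = "no_pac",
    shared_phase_deg: float = 180.0,
) -> tuple[TrialEpochSet, GroundTruth]:
    """Generate a control session for one of the dissociation scenarios.

    mode = "pac_no_coding": coupling is present but every category shares
    one preferred phase, so there is nothing category-specific to decode.
    mode = "no_pac": coupling depth forced to 0; the gamma envelope is
    independent of modulator phase.
    mode = "coding_no_pac": no coupling, but the modulator phase at
    stimulus onset is locked to the category's preferred phase — category
    information is in the phase series, not in gamma timing.
    """
    import dataclasses

    if mode == "pac_no_coding":
        cfg = dataclasses.replace(
            config, category_preferred_phases=(shared_phase_deg,) * 4
        )
    elif mode == "no_pac":
        cfg = dataclasses.replace(config, coupling_depth=0.0)
    elif mode == "coding_no_pac":
        cfg = dataclasses.replace(
            config, coupling_depth=0.0, phase_locked_categories=True
        )
    else:
        raise ValueError(f"unknown null mode: {mode!r}")
    return generate_session(cfg)


# ---------------------------------------------------------------------------
# session persistence: one .npz per session, JSON sidecars inside it
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = (
    "epochs",
    "sampling_rate",
    "labels",
    "onset_sample",
    "ground_truth_json",
)


def write_dataset(session: TrialEpochSet, truth: GroundTruth, path) -> Path:
    """Write one session (signals, labels, onsets, ground truth) to a file."""
    path = Path(path)
    np.savez(
        path,
        epochs=session.epochs,
        sampling_rate=np.array(session.sampling_rate),
        labels=session.labels.astype(str),
        onset_sample=np.array(session.onset_sample),
        stimulus_duration=np.array(session.stimulus_duration),
        ground_truth_json=np.array(truth.to_json()),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_dataset(path) -> tuple[TrialEpochSet, GroundTruth]:
    """Read a session back; raises naming any missing field."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as data:
        for fieldname in _REQUIRED_FIELDS:
            if fieldname not in data:
                raise ValueError(f"corrupt session file: missing field '{fieldname}'")
        labels = data["labels"].astype(str)
        n_cat = np.unique(labels).size
        if n_cat != 4:
            raise ValueError(
                f"label cardinality is {n_cat}, expected the 4-category set"
            )
        session = TrialEpochSet(
            epochs=data["epochs"],
            sampling_rate=float(data["sampling_rate"]),
            labels=labels,
            onset_sample=int(data["onset_sample"]),
            stimulus_duration=float(data["stimulus_duration"]),
        )
        truth = GroundTruth.from_json(str(data["ground_truth_json"]))
    return session, truth


def events_to_csv(session: TrialEpochSet, path) -> Path:
    """Write the trial-events table: trial_index, category_label, onset_sample.

    Onset is given in concatenated-series samples for interoperability with
    the EDF export of the concatenated signal.
    """
    import pandas as pd

    path = Path(path)
    onsets = session.concat_map + session.onset_sample
    pd.DataFrame(
        {
            "trial_index": np.arange(session.n_trials),
            "category_label": session.labels,
            "onset_sample": onsets,
        }
    ).to_csv(path, index=False)
    return path


def events_from_csv(path):
    """Read a trial-events table (trial_index, category_label, onset_sample)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"trial_index", "category_label", "onset_sample"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    return (
        df["onset_sample"].to_numpy(dtype=int),
        df["category_label"].to_numpy(dtype=str),
    )
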