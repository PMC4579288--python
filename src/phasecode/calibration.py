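"""False-positive calibration of the pipeline's inferential controls.

Runs the detection chain over a population of simulated no-coupling
electrodes and measures how often each flag fires: the surrogate-z PAC
criterion (expected essentially never at the Bonferroni threshold), the
PR window-shuffle null (expected ~5% per category at the 95th
percentile) and the label-shuffle decoding null (expected ~5% per
electrode). Sessions are short and the gamma grid reduced — the rates
under test do not depend on the problem size, and the threshold is
recomputed from the actual family.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._utils import spawn_seeds
from .coding import pr_window_shuffle_null
from .decoding import build_phase_features, classify, label_shuffle_null
from .otc import (
    extract_segments,
    modulation_strength,
    modulatory_signal,
    pac_z_threshold,
    surrogate_z,
)
from .spectral import detect_hfa_event_sets, morlet_decompose, zscore_power
from .synth import SimulationConfig, generate_null_session

__all__ = ["null_calibration"]

#: reduced gamma grid spanning the analysis band
SMALL_F_AMP = np.array([40.0, 56.0, 72.0, 84.0, 100.0, 116.0])


def null_calibration(
    n_electrodes: int = 100,
    n_trials_per_category: int = 8,
    seed: int = 0,
    n_otc_surrogates: int = 100,
    n_pr_shuffles: int = 100,
    n_decode_null: int = 50,
    f_amp_grid: np.ndarray = SMALL_F_AMP,
) -> dict:
    """Empirical false-positive rates over simulated no-coupling electrodes."""
    threshold = pac_z_threshold(len(f_amp_grid), n_electrodes)
    seeds = spawn_seeds(seed, n_electrodes)
    z_exceed = 0
    z_exceed_435 = 0
    pr_rejections = 0
    pr_tests = 0
    decode_rejections = 0
    decode_tests = 0
    base = SimulationConfig(n_trials_per_category=n_trials_per_category)
    for s in seeds:
        cfg = dataclasses.replace(base, seed=s)
        session, _ = generate_null_session(cfg, "no_pac")
        concat = session.concatenated
        rate = session.sampling_rate
        rng = np.random.default_rng(s)

        gamma = morlet_decompose(concat, rate, f_amp_grid)
        event_sets = detect_hfa_event_sets(
            gamma, boundaries=session.epoch_boundaries
        )
        max_z = -np.inf
        for f in f_amp_grid:
            ev = event_sets[float(f)]
            stack, kept = extract_segments(concat, ev.events)
            if kept.size == 0:
                continue
            strength = modulation_strength(modulatory_signal(stack))
            z, _ = surrogate_z(concat, strength, kept.size, n_otc_surrogates, rng)
            max_z = max(max_z, z)
        z_exceed += max_z > threshold
        z_exceed_435 += max_z > 4.35

        hfa = event_sets[84.0]
        k84 = gamma.freq_index(84.0)
        z_series = zscore_power(gamma.power[k84], valid_mask=gamma.valid_mask(84.0))
        phase_dec = morlet_decompose(concat, rate, [1.0])
        series = phase_dec.phase[0]
        pr = pr_window_shuffle_null(
            hfa, series, session, n_pr_shuffles, seed=rng, z_series=z_series
        )
        if pr.get("defined"):
            for flag in pr["significant"].values():
                pr_rejections += flag
                pr_tests += 1

        stim = session.stimulus_mask()
        events = hfa.events[stim[hfa.events]]
        if events.size >= 12:
            trial_idx, _ = session.concat_to_trial(events)
            labels = session.labels[trial_idx]
            if np.unique(labels).size >= 2:
                feats = build_phase_features(series[events])
                try:
                    acc = classify(feats, labels, seed=rng).accuracy
                    null = label_shuffle_null(feats, labels, n_decode_null, rng)
                    decode_rejections += acc >= np.percentile(null, 95)
                    decode_tests += 1
                except ValueError:
                    pass

    return {
        "n_electrodes": n_electrodes,
        "z_threshold": threshold,
        "pac_z_rate": z_exceed / n_electrodes,
        "pac_z_rate_435": z_exceed_435 / n_electrodes,
        "pr_rejection_rate": pr_rejections / pr_tests if pr_tests else np.nan,
        "pr_tests": pr_tests,
        "decode_rejection_rate": (
            decode_rejections / decode_tests if decode_tests else np.nan
        ),
        "decode_tests": decode_tests,
    }
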