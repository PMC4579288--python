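"""Detect phase-amplitude coupling with the event-locked (OTC) method.

Decomposes the session, finds HFA windows/events at each gamma frequency,
sums raw segments around the events and scores the modulation strength
against random-timestamp surrogates. Prints the peak modulated frequency,
the strongest/weakest modulating frequencies (F_max / F_min), the
preferred phase and the PAC+ verdict.
"""

import numpy as np

from phasecode import SimulationConfig, generate_null_session
from phasecode.otc import compute_modulation_profile, pac_plus_verdict
from phasecode.spectral import F_AMP_GRID, F_PHASE_GRID, detect_hfa_event_sets, morlet_decompose

# a trough-coupled electrode: every category's gamma prefers 180 degrees
config = SimulationConfig(n_trials_per_category=24, seed=2)
session, truth = generate_null_session(config, "pac_no_coding", shared_phase_deg=180.0)
concat = session.concatenated

gamma = morlet_decompose(concat, session.sampling_rate, F_AMP_GRID)
events = detect_hfa_event_sets(gamma, boundaries=session.epoch_boundaries)
phase_dec = morlet_decompose(concat, session.sampling_rate, F_PHASE_GRID)
raw_spectrum = np.array([
    phase_dec.power[k][phase_dec.valid_mask(f)].mean()
    for k, f in enumerate(phase_dec.frequencies)
])

profile = compute_modulation_profile(
    concat, events, session.sampling_rate, raw_spectrum, seed=0
)
verdict, diag = pac_plus_verdict(profile, n_electrodes=167)

print(f"max modulation z: {np.nanmax(profile.z_scores):.1f} "
      f"(threshold {diag['z_threshold']:.2f}) at {profile.peak_modulated_freq:.0f} Hz")
print(f"F_max {profile.f_max} Hz, F_min {profile.f_min} Hz")
print(f"preferred phase {profile.preferred_phase_deg:.0f} deg "
      "(180 = oscillation trough)")
print(f"PAC+ verdict: {verdict} (spectral peaks match: {diag['criterion_peak_match']})")
# Expected: z far above threshold near the 84 Hz carrier, F_max at the
# 1 Hz modulator, preferred phase near the trough it was coupled to.
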