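"""Cross-check coupling with the phase-binned modulation index (MI).

Band-pass filters the signal (delta/theta/alpha/broad phase bands vs a
51-200 Hz amplitude band), bins amplitude by phase (18 bins) and reports
MI = KL(P || uniform)/log(18) with an amplitude-shuffle surrogate z.
On trough-coupled data, the phase of maximal amplitude should agree with
the event-locked method's preferred phase (~180 degrees).
"""

from phasecode import SimulationConfig, generate_null_session
from phasecode.tortmi import mi_analysis

config = SimulationConfig(n_trials_per_category=24, seed=5)
session, _ = generate_null_session(config, "pac_no_coding", shared_phase_deg=180.0)

out = mi_analysis(session.concatenated, session.sampling_rate,
                  n_surrogates=200, seed=0)
print(f"{'band':6s} {'Hz':>10s} {'MI':>9s} {'z':>8s} {'sig':>5s} {'max-amp phase':>14s}")
for band, res in out.items():
    lo, hi = res["band_hz"]
    print(f"{band:6s} {lo:4.1f}-{hi:5.1f} {res['mi']:9.5f} {res['z']:8.1f} "
          f"{res['significant']!s:>5s} {res['max_amplitude_phase_deg']:10.0f} deg")
# Coupling lives in the delta band here, so the delta (and broad) rows are
# significant and the maximal-amplitude phase sits near the 180-degree trough.
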