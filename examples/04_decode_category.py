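"""Decode stimulus category from the phase at which HFA events occur.

Each HFA event during the stimulus period contributes (sin, cos) of the
slow-rhythm phase as features for a linear SVM (5-fold CV). Significance
is judged against two permutation nulls: shuffled category labels and
random surrogate event times.
"""

import numpy as np

from phasecode import SimulationConfig, generate_session
from phasecode.pipeline import analyze_electrode

config = SimulationConfig(n_trials_per_category=24, seed=4)
session, truth = generate_session(config)
report, inter = analyze_electrode(
    session, seed=0, n_electrodes_family=167, run_mi=False, run_fmin=False
)
dec = inter["decoding"]

print(f"events decoded: {dec.n_events}")
print(f"accuracy: {dec.accuracy:.3f}")
print(f"label-shuffle null: mean {dec.label_null.mean():.3f}, "
      f"95th pct {np.percentile(dec.label_null, 95):.3f} -> significant: {dec.sig_label}")
print(f"random-event null: mean {dec.event_null.mean():.3f}, "
      f"95th pct {np.percentile(dec.event_null, 95):.3f} -> significant: {dec.sig_event}")
print(f"significant against both nulls: {dec.sig_both}")
# Beating the label null shows the phases carry category information;
# beating the random-event null shows that information is concentrated at
# HFA event times specifically, not spread over the whole phase series.
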