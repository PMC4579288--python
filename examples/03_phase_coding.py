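"""Quantify category-specific phase coding with DS and PR.

Runs the full single-electrode pipeline on a coding session (distinct
preferred phase per category), then prints, per category: the circular
mean of HFA-event phases, the resultant vector length r, the difference
score DS (how many other categories differ, 0-3) and the PR = DS x r
with its window-shuffle-null percentile.
"""

from phasecode import SimulationConfig, generate_session
from phasecode.pipeline import analyze_electrode

config = SimulationConfig(n_trials_per_category=24, seed=3)
session, truth = generate_session(config)
report, inter = analyze_electrode(
    session, seed=0, n_electrodes_family=167, ground_truth=truth, run_mi=False
)

print(f"PAC+: {report.pac_plus}; analysis frequency F_max = {report.f_max} Hz; "
      f"clustering gate passed: {report.gate_pass}")
print(f"{'category':8s} {'true':>6s} {'mean':>7s} {'r':>5s} {'DS':>3s} "
      f"{'PR':>5s} {'null %ile':>9s}")
for cat, entry in report.coding.items():
    print(f"{cat:8s} {truth.preferred_phase_deg[cat]:6.0f} "
          f"{entry['mean_phase_deg']:7.1f} {entry['r']:5.2f} "
          f"{entry['ds']!s:>3s} {entry['pr']:5.2f} "
          f"{report.pr_percentile[cat]:9.1f}")
# DS = 3 for every category means each phase distribution differs from all
# three others; PR above the 95th percentile of the shuffle null means the
# coding is tied to where the HFA windows actually sit on the phase series.
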