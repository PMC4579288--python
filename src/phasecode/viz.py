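"""Small plotting helpers for inspection figures."""

from __future__ import annotations

import numpy as np


def plot_modulation_profile(profile, ax=None):
    """Modulation-strength z per gamma frequency with the PAC threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.gamma_frequencies, profile.z_scores, "o-", color="maroon")
    if np.isfinite(profile.z_threshold):
        ax.axhline(profile.z_threshold, ls="--", color="gray",
                   label=f"threshold {profile.z_threshold:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel("modulated frequency (Hz)")
    ax.set_ylabel("modulation strength (z)")
    return ax


def plot_phase_rose(phases_by_category, ax=None, bins=18):
    """Rose plot of HFA-event phases per category (phases in radians)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    width = 2 * np.pi / bins
    for cat, phases in phases_by_category.items():
        counts, _ = np.histogram(np.asarray(phases), bins=edges)
        ax.bar(edges[:-1] + width / 2, counts, width=width, alpha=0.4, label=cat)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), frameon=False)
    return ax
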