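"""Category-specific phase coding of high-frequency activity.

Phases of the slow rhythm are collected during HFA windows (all in-window
samples by default, restricted to the stimulus period) and pooled per
stimulus category. Two statistics quantify coding:

* the difference score (DS): for each category, the number (0-3) of other
  categories whose in-window phase distribution differs significantly
  (pairwise Watson-Williams tests at alpha 0.001), gated by a
  Bonferroni-corrected Rayleigh clustering test per category so that
  phase *differences* are only interpreted where phases actually cluster;
* the phase representation (PR): DS times the category's resultant vector
  length — a continuous composite suited to surrogate comparison, since
  an observed DS of 3 leaves no room above it for integer surrogates.

The primary inferential control for PR is a window-position shuffle that
reorders the alternating sequence of HFA / non-HFA segments along the
phase series, preserving the duration distribution while breaking the
window-phase alignment; pooled in-window samples are serially correlated,
so this permutation null, not the parametric Watson-Williams p, carries
the inference. Additional controls: PR inside non-HFA windows, the
analysis re-run at the weakest modulating frequency (F_min), a
time-frequency map of category-exclusive phase locking, and a
phase-clustering sweep over a dense frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import as_rng, boolean_runs, rad_to_deg_0_360
from .circstats import (
    circular_distance,
    circular_mean,
    rayleigh_test,
    resultant_vector_length,
    watson_williams,
)
from .spectral import HFAEvents, morlet_decompose

__all__ = [
    "CategoryPhaseSet",
    "PhaseCodingResult",
    "collect_hfa_phases",
    "difference_scores",
    "clustering_gate",
    "phase_representation",
    "pr_window_shuffle_null",
    "analyze_phase_coding",
    "fmin_control",
    "phase_difference_by_ds",
    "ds_phase_uniformity",
    "category_phase_locking_map",
    "clustering_across_frequencies",
    "time_resolved_category_contrast",
]

ALPHA_DS = 0.001  # pairwise Watson-Williams threshold for DS


@dataclass
class CategoryPhaseSet:
    """In-window phase samples per category, one electrode / one frequency."""

    frequency: float
    phases: dict  # category -> radians array
    stimulus_only: bool = True
    event_only: bool = False

    @property
    def counts(self) -> dict:
        return {c: len(p) for c, p in self.phases.items()}

    @property
    def categories(self) -> list:
        return list(self.phases.keys())


@dataclass
class PhaseCodingResult:
    """DS / clustering / PR summary for one electrode at one frequency."""

    frequency: float
    counts: dict
    r: dict  # category -> resultant vector length
    mean_phase_deg: dict  # category -> circular mean, degrees
    ds: dict  # category -> 0..3 (None when undefined)
    pairwise_p: dict  # (cat_a, cat_b) -> Watson-Williams p
    pr: dict  # category -> DS * r
    gate: dict = field(default_factory=dict)  # category -> clustering ok
    gate_pass: bool = False
    pr_percentile: dict = field(default_factory=dict)
    pr_null: np.ndarray = None
    pr_nonwindow: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "frequency": self.frequency,
            "counts": self.counts,
            "r": self.r,
            "mean_phase_deg": self.mean_phase_deg,
            "ds": self.ds,
            "pr": self.pr,
            "gate": self.gate,
            "gate_pass": self.gate_pass,
            "pr_percentile": self.pr_percentile,
        }


def _split_by_category(phase_series, mask, session):
    codes = session.label_per_sample()
    out = {}
    for i, cat in enumerate(session.categories):
        out[cat] = np.asarray(phase_series, dtype=float)[mask & (codes == i)]
    return out


def collect_hfa_phases(
    phase_series: np.ndarray,
    hfa: HFAEvents,
    session,
    stimulus_only: bool = True,
    event_only: bool = False,
) -> CategoryPhaseSet:
    """Pool slow-rhythm phases during HFA windows, per category.

    By default every in-window sample contributes (windows, not just the
    peak events); ``event_only`` switches to one phase per HFA event for
    sensitivity analysis. ``stimulus_only`` restricts to samples while the
    image is on screen, which is required whenever category labels matter.
    """
    n = len(phase_series)
    if event_only:
        mask = np.zeros(n, dtype=bool)
        if hfa.events is not None and len(hfa.events):
            mask[hfa.events] = True
    else:
        mask = hfa.window_mask(n)
    if stimulus_only:
        mask &= session.stimulus_mask()
    return CategoryPhaseSet(
        frequency=hfa.frequency,
        phases=_split_by_category(phase_series, mask, session),
        stimulus_only=stimulus_only,
        event_only=event_only,
    )


def difference_scores(
    cps: CategoryPhaseSet, alpha: float = ALPHA_DS
) -> tuple[dict, dict]:
    """Pairwise Watson-Williams tests and per-category difference scores.

    DS_c = number of other categories whose phase distribution differs at
    p < alpha; six tests, symmetric p "matrix" keyed by category pairs.
    """
    cats = cps.categories
    for c in cats:
        if len(cps.phases[c]) < 2:
            raise ValueError(f"category '{c}' has fewer than 2 phase samples")
    import warnings

    pairwise = {}
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # concentration warning handled by gate
                _, p = watson_williams(cps.phases[a], cps.phases[b])
            pairwise[(a, b)] = p
    ds = {
        c: int(
            sum(
                1
                for (a, b), p in pairwise.items()
                if c in (a, b) and p < alpha
            )
        )
        for c in cats
    }
    return ds, pairwise


def clustering_gate(cps: CategoryPhaseSet, alpha_gate: float) -> tuple[dict, bool]:
    """Rayleigh clustering test per category; electrode passes only if all do.

    The gate excludes spurious phase differences between categories in the
    absence of any phase clustering. ``alpha_gate`` is typically the
    Bonferroni-corrected family value 0.01 / (n_pac_plus_electrodes * 4).
    """
    gate = {}
    for c, ph in cps.phases.items():
        if len(ph) < 2:
            gate[c] = False
        else:
            _, p = rayleigh_test(ph)
            gate[c] = bool(p < alpha_gate)
    return gate, all(gate.values())


def gate_alpha(n_pac_plus_electrodes: int, n_categories: int = 4, family: float = 0.01) -> float:
    """Per-test clustering alpha: family 0.01 over PAC+ electrodes x categories."""
    return family / (n_pac_plus_electrodes * n_categories)


def phase_representation(ds: int, r: float) -> float:
    """PR = DS x resultant vector length, in [0, 3]; 0 whenever DS = 0."""
    if not 0 <= ds <= 3:
        raise ValueError("DS must lie in 0..3")
    if not 0.0 <= r <= 1.0 + 1e-12:
        raise ValueError("resultant length must lie in [0, 1]")
    return float(ds * r)


def _scores_from_phases(phases: dict, alpha_ds: float):
    """DS, r and PR per category from per-category phase arrays."""
    cps = CategoryPhaseSet(frequency=np.nan, phases=phases)
    if any(len(p) < 2 for p in phases.values()):
        return None
    ds, _ = difference_scores(cps, alpha_ds)
    out = {}
    for c in phases:
        r = resultant_vector_length(phases[c])
        out[c] = (ds[c], r, ds[c] * r)
    return out


def _scores_from_mask(phase_series, mask, session, alpha_ds):
    """DS, r and PR per category from an arbitrary in-window sample mask."""
    phases = _split_by_category(phase_series, mask, session)
    return _scores_from_phases(phases, alpha_ds)


def _interval_events(intervals, z_series):
    """One representative sample per [start, end) interval.

    The z-power argmax inside the interval when a z series is available
    (mirroring real HFA event placement), the midpoint otherwise.
    """
    if len(intervals) == 0:
        return np.empty(0, dtype=int)
    if z_series is None:
        return np.asarray([(a + b) // 2 for a, b in intervals], dtype=int)
    return np.asarray(
        [a + int(np.argmax(z_series[a:b])) for a, b in intervals], dtype=int
    )


def _scores_from_events(phase_series, events, session, alpha_ds, stim_mask):
    events = np.asarray(events, dtype=int)
    if stim_mask is not None and events.size:
        events = events[stim_mask[events]]
    codes = session.label_per_sample()
    phases = {
        c: np.asarray(phase_series, dtype=float)[events[codes[events] == i]]
        for i, c in enumerate(session.categories)
    }
    return _scores_from_phases(phases, alpha_ds)


def pr_window_shuffle_null(
    hfa: HFAEvents,
    phase_series: np.ndarray,
    session,
    n_shuffles: int = 200,
    seed=None,
    alpha_ds: float = ALPHA_DS,
    stimulus_only: bool = True,
    event_only: bool = True,
    z_series: np.ndarray | None = None,
) -> dict:
    """Window-position shuffle null for PR, plus the non-HFA-window control.

    The alternating sequence of HFA / non-HFA segment durations along the
    phase series is randomly re-ordered (durations preserved), DS,
    clustering and PR are recomputed per shuffle, and the observed PR is
    placed on its surrogate distribution (percentile per category). With
    ``event_only`` (default) each window contributes one phase, placed at
    the z-power argmax of the (shuffled) window when ``z_series`` is
    given; otherwise all in-window samples are pooled.
    """
    if n_shuffles < 20:
        raise ValueError("need at least 20 shuffles for a usable percentile")
    rng = as_rng(seed)
    n = len(phase_series)
    window_mask = hfa.window_mask(n)
    if hfa.n_windows < 2:
        return {"defined": False, "reason": "fewer than 2 HFA windows"}
    stim = session.stimulus_mask() if stimulus_only else np.ones(n, dtype=bool)

    if event_only:
        obs_events = (
            hfa.events
            if hfa.events is not None
            else _interval_events(hfa.windows, z_series)
        )
        observed = _scores_from_events(phase_series, obs_events, session, alpha_ds, stim)
        nonwindow_runs = boolean_runs(~window_mask)
        nonwindow = _scores_from_events(
            phase_series,
            _interval_events(nonwindow_runs, z_series),
            session,
            alpha_ds,
            stim,
        )
    else:
        observed = _scores_from_mask(phase_series, window_mask & stim, session, alpha_ds)
        nonwindow = _scores_from_mask(
            phase_series, (~window_mask) & stim, session, alpha_ds
        )
    if observed is None:
        return {"defined": False, "reason": "a category has too few in-window events"}

    # alternating run-length encoding of the window indicator
    change = np.flatnonzero(np.diff(window_mask.astype(np.int8))) + 1
    edges = np.r_[0, change, n]
    lengths = np.diff(edges)
    states = window_mask[edges[:-1]]

    cats = list(session.categories)
    null_pr = np.full((n_shuffles, len(cats)), np.nan)
    for s in range(n_shuffles):
        order = rng.permutation(lengths.size)
        perm_lengths = lengths[order]
        perm_states = states[order]
        if event_only:
            stops = np.cumsum(perm_lengths)
            starts = stops - perm_lengths
            win_intervals = np.column_stack(
                [starts[perm_states], stops[perm_states]]
            )
            ev = _interval_events(win_intervals, z_series)
            scores = _scores_from_events(phase_series, ev, session, alpha_ds, stim)
        else:
            shuffled = np.repeat(perm_states, perm_lengths)
            scores = _scores_from_mask(phase_series, shuffled & stim, session, alpha_ds)
        if scores is None:
            continue
        null_pr[s] = [scores[c][2] for c in cats]

    from scipy.stats import percentileofscore

    percentile = {}
    significant = {}
    for j, c in enumerate(cats):
        col = null_pr[:, j]
        col = col[np.isfinite(col)]
        if col.size:
            percentile[c] = float(percentileofscore(col, observed[c][2], kind="weak"))
            # strict comparison against the 95th-percentile *value*: ties at
            # zero (DS = 0 in most shuffles of a null electrode) stay null
            significant[c] = bool(observed[c][2] > np.percentile(col, 95))
        else:
            percentile[c] = np.nan
            significant[c] = False
    return {
        "defined": True,
        "observed_pr": {c: observed[c][2] for c in cats},
        "observed_ds": {c: observed[c][0] for c in cats},
        "observed_r": {c: observed[c][1] for c in cats},
        "percentile": percentile,
        "significant": significant,
        "null_pr": null_pr,
        "nonwindow_pr": {c: nonwindow[c][2] for c in cats} if nonwindow else None,
    }


def analyze_phase_coding(
    phase_series: np.ndarray,
    hfa: HFAEvents,
    session,
    frequency: float,
    alpha_ds: float = ALPHA_DS,
    alpha_gate: float = 1e-4,
    stimulus_only: bool = True,
    event_only: bool = True,
) -> PhaseCodingResult:
    """DS, clustering, gate and PR for one electrode at one frequency.

    By default each HFA event contributes one phase (statistically
    independent sampling units, keeping the parametric tests calibrated);
    ``event_only=False`` pools every in-window sample instead.
    """
    cps = collect_hfa_phases(
        phase_series, hfa, session, stimulus_only=stimulus_only, event_only=event_only
    )
    counts = cps.counts
    r = {}
    mean_deg = {}
    for c, ph in cps.phases.items():
        if len(ph):
            r[c] = resultant_vector_length(ph)
            mean_deg[c] = float(rad_to_deg_0_360(circular_mean(ph)))
        else:
            r[c] = np.nan
            mean_deg[c] = np.nan
    gate, gate_pass = clustering_gate(cps, alpha_gate)
    if all(n >= 2 for n in counts.values()):
        ds, pairwise = difference_scores(cps, alpha_ds)
    else:
        ds, pairwise = {c: None for c in counts}, {}
    pr = {
        c: (phase_representation(ds[c], r[c]) if ds[c] is not None else np.nan)
        for c in counts
    }
    return PhaseCodingResult(
        frequency=frequency,
        counts=counts,
        r=r,
        mean_phase_deg=mean_deg,
        ds=ds,
        pairwise_p=pairwise,
        pr=pr,
        gate=gate,
        gate_pass=gate_pass,
    )


def fmin_control(
    phase_decomp,
    profile,
    hfa: HFAEvents,
    session,
    alpha_ds: float = ALPHA_DS,
    alpha_gate: float = 1e-4,
    event_only: bool = True,
) -> dict:
    """Re-run the phase-coding computation at F_min and compare clustering.

    Returns results at both F_max and F_min (identical schema) and the
    per-category paired difference r(F_max) - r(F_min): frequency-specific
    coding predicts systematically positive differences.
    """
    results = {}
    for name, freq in (("f_max", profile.f_max), ("f_min", profile.f_min)):
        series = phase_decomp.phase[phase_decomp.freq_index(freq)]
        results[name] = analyze_phase_coding(
            series, hfa, session, freq, alpha_ds, alpha_gate, event_only=event_only
        )
    delta_r = {
        c: results["f_max"].r[c] - results["f_min"].r[c]
        for c in results["f_max"].r
    }
    return {
        "f_max_result": results["f_max"],
        "f_min_result": results["f_min"],
        "delta_r": delta_r,
        "mean_delta_r": float(np.nanmean(list(delta_r.values()))),
    }


# ---------------------------------------------------------------------------
# population-level summaries
# ---------------------------------------------------------------------------

def phase_difference_by_ds(results: list[PhaseCodingResult]) -> dict:
    """Mean absolute pairwise phase difference (degrees) per DS level.

    For each (electrode, category) the mean absolute circular distance
    between that category's mean phase and the other three categories'
    mean phases is computed, then averaged within each DS level. Greater
    DS is expected to come with greater phase separation.
    """
    by_level: dict[int, list] = {}
    for res in results:
        cats = list(res.mean_phase_deg.keys())
        means = {c: np.deg2rad(res.mean_phase_deg[c]) for c in cats}
        for c in cats:
            if res.ds.get(c) is None or not np.isfinite(means[c]):
                continue
            others = [
                abs(circular_distance(means[c], means[o]))
                for o in cats
                if o != c and np.isfinite(means[o])
            ]
            if others:
                by_level.setdefault(res.ds[c], []).append(np.rad2deg(np.mean(others)))
    return {level: float(np.mean(v)) for level, v in sorted(by_level.items())}


def ds_phase_uniformity(results: list[PhaseCodingResult]) -> dict:
    """Are phase-coded categories clustered at particular phases?

    Pools category mean phases by DS level and runs a Rayleigh test per
    level; also counts how often each category reaches DS = 3 (inputs for
    a category-evenness chi-square).
    """
    pooled: dict[int, list] = {}
    ds3_counts: dict[str, int] = {}
    for res in results:
        for c, d in res.ds.items():
            if d is None or not np.isfinite(res.mean_phase_deg[c]):
                continue
            pooled.setdefault(d, []).append(np.deg2rad(res.mean_phase_deg[c]))
            if d == 3:
                ds3_counts[c] = ds3_counts.get(c, 0) + 1
    uniformity = {}
    for level, phases in sorted(pooled.items()):
        if len(phases) >= 2:
            z, p = rayleigh_test(np.asarray(phases))
            uniformity[level] = {"z": z, "p": p, "n": len(phases)}
        else:
            uniformity[level] = {"z": np.nan, "p": np.nan, "n": len(phases)}
    return {"rayleigh_by_ds": uniformity, "ds3_counts_by_category": ds3_counts}


def _rayleigh_p_vec(r: np.ndarray, n: int) -> np.ndarray:
    big_r = n * r
    return np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)) - (1.0 + 2.0 * n))


def category_phase_locking_map(
    session,
    decomp,
    alpha: float = 1e-6,
    time_step: int = 10,
) -> dict:
    """Across-trial phase locking per (time, frequency) and category.

    For every category, a Rayleigh test across that category's trials at
    each (time, frequency) point; "exclusive" marks points significant for
    exactly one category. This is the control that detects stimulus
    phase locking whether or not any gamma coupling exists.
    """
    n_trials, n_samp = session.n_trials, session.n_samples
    phase = decomp.phase.reshape(decomp.frequencies.size, n_trials, n_samp)
    phase = phase[:, :, ::time_step]
    sig = {}
    for c in session.categories:
        sel = session.labels == c
        n_c = int(np.sum(sel))
        z = np.exp(1j * phase[:, sel, :].astype(np.float64))
        r = np.abs(z.mean(axis=1))
        p = _rayleigh_p_vec(r, n_c)
        sig[c] = p < alpha
    stack = np.stack([sig[c] for c in session.categories])
    n_sig = stack.sum(axis=0)
    exclusive = {
        c: sig[c] & (n_sig == 1) for c in session.categories
    }
    times_ms = (
        (np.arange(0, n_samp, time_step) - session.onset_sample)
        / session.sampling_rate
        * 1000.0
    )
    return {
        "significant": sig,
        "exclusive": exclusive,
        "frequencies": decomp.frequencies,
        "times_ms": times_ms,
        "alpha": alpha,
    }


def clustering_across_frequencies(
    signal: np.ndarray,
    rate: float,
    hfa: HFAEvents,
    session,
    grid=None,
    stimulus_only: bool = True,
    n_cycles: float = 7.0,
) -> dict:
    """Summed per-category phase clustering across a dense frequency sweep.

    At each frequency, the in-window resultant vector length is computed
    per category, summed across the four categories and divided by the
    maximum possible value of 4; the curve is reported as percent of its
    maximum. A frequency-specific effect shows a peak at the true
    modulating frequency rather than a smooth low-frequency gradient.
    """
    if grid is None:
        grid = np.arange(0.1, 12.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    n = len(signal)
    mask = hfa.window_mask(n)
    if stimulus_only:
        mask &= session.stimulus_mask()
    codes = session.label_per_sample()
    scores = np.zeros(grid.size)
    for k, f in enumerate(grid):
        decomp = morlet_decompose(signal, rate, [f], n_cycles=n_cycles)
        ph = decomp.phase[0]
        total = 0.0
        for i, _ in enumerate(session.categories):
            sel = mask & (codes == i)
            if np.sum(sel) >= 2:
                total += resultant_vector_length(ph[sel])
        scores[k] = total / 4.0
    percent = 100.0 * scores / scores.max() if scores.max() > 0 else scores
    return {"frequencies": grid, "summed_clustering": scores, "percent_of_max": percent}


def time_resolved_category_contrast(
    values: np.ndarray,
    labels: np.ndarray,
    kind: str = "power",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    categories=None,
) -> dict:
    """Time-resolved pairwise category contrasts with a trial-label permutation gate.

    ``values`` is (n_trials, n_times): power (contrasted with two-sample
    t statistics) or phase in radians (contrasted with Watson-Williams F).
    Significance per (pair, time) comes from ``n_perm`` trial-label
    shuffles at the given alpha; the output counts, per category and time
    point, how many of its three pairwise contrasts are significant
    (a time-resolved analog of the difference score).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if categories is None:
        categories = sorted(np.unique(labels).tolist())
    rng = as_rng(seed)

    def stat(a_vals, b_vals):
        if kind == "power":
            na, nb = a_vals.shape[0], b_vals.shape[0]
            ma, mb = a_vals.mean(axis=0), b_vals.mean(axis=0)
            va, vb = a_vals.var(axis=0, ddof=1), b_vals.var(axis=0, ddof=1)
            sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (ma - mb) / (sp * np.sqrt(1.0 / na + 1.0 / nb))
            return np.abs(np.nan_to_num(t))
        # phase: vectorized Watson-Williams F across time
        na, nb = a_vals.shape[0], b_vals.shape[0]
        n = na + nb
        za, zb = np.exp(1j * a_vals), np.exp(1j * b_vals)
        r1 = np.abs(za.sum(axis=0))
        r2 = np.abs(zb.sum(axis=0))
        big_r = np.abs(za.sum(axis=0) + zb.sum(axis=0))
        rw = (r1 + r2) / n
        kappa = np.where(
            rw < 0.53,
            2 * rw + rw**3 + 5 * rw**5 / 6,
            np.where(
                rw < 0.85,
                -0.4 + 1.39 * rw + 0.43 / np.maximum(1 - rw, 1e-9),
                1.0 / np.maximum(rw**3 - 4 * rw**2 + 3 * rw, 1e-9),
            ),
        )
        corr = 1.0 + 3.0 / (8.0 * np.maximum(kappa, 1e-9))
        denom = np.maximum(n - (r1 + r2), 1e-9)
        f = corr * (n - 2) * (r1 + r2 - big_r) / denom
        return np.maximum(np.nan_to_num(f), 0.0)

    pairs = [
        (a, b) for i, a in enumerate(categories) for b in categories[i + 1 :]
    ]
    n_times = values.shape[1]
    sig = {}
    for a, b in pairs:
        sel = (labels == a) | (labels == b)
        vals = values[sel]
        is_a = labels[sel] == a
        obs = stat(vals[is_a], vals[~is_a])
        exceed = np.zeros(n_times)
        for _ in range(n_perm):
            perm = rng.permutation(is_a)
            exceed += stat(vals[perm], vals[~perm]) >= obs
        p = (exceed + 1.0) / (n_perm + 1.0)
        sig[(a, b)] = p < alpha
    ds_counts = np.zeros((len(categories), n_times), dtype=int)
    for j, c in enumerate(categories):
        for (a, b), s in sig.items():
            if c in (a, b):
                ds_counts[j] += s
    return {
        "categories": list(categories),
        "ds_counts": ds_counts,
        "significant": sig,
        "alpha": alpha,
    }
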