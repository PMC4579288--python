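"""End-to-end orchestration: sessions -> spectral -> OTC -> coding -> decoding -> MI.

`analyze_electrode` runs the complete single-electrode analysis;
`run` executes it over a configured electrode population with
per-electrode derived seeds (stage-level reproducibility), computes the
population-dependent thresholds (PAC z threshold from the family size,
clustering-gate alpha from the PAC+ count), and collects machine-readable
reports plus a population summary. Per-electrode failures are isolated
and logged; the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import spawn_seeds
from .coding import (
    analyze_phase_coding,
    fmin_control,
    gate_alpha,
    pr_window_shuffle_null,
)
from .decoding import decode_electrode, expected_chance_electrodes
from .epochs import TrialEpochSet
from .otc import compute_modulation_profile, pac_plus_verdict
from .spectral import (
    F_AMP_GRID,
    F_PHASE_GRID,
    detect_hfa_event_sets,
    hfa_trial_timecourse,
    morlet_decompose,
    zscore_power,
)
from .synth import SimulationConfig, generate_null_session, generate_session
from .tortmi import mi_analysis

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ElectrodeReport", "analyze_electrode", "run",
           "summarize_population"]


@dataclass
class RunConfig:
    """One reproducible analysis run.

    ``electrodes`` is a list of specs: ``{"kind": "synthetic",
    "mode": "coding" | "pac_no_coding" | "no_pac" | "coding_no_pac",
    "config": SimulationConfig | dict}`` or ``{"kind": "dataset",
    "path": ...}`` for a stored session file. Analysis constants default
    to the study values: DS alpha 0.001, clustering-gate family alpha
    0.01, PAC family alpha 0.05, 100 OTC surrogates, 200 PR shuffles,
    50 + 50 decoding nulls, 500 MI shuffles.
    """

    electrodes: list = field(default_factory=list)
    f_phase_grid: np.ndarray = field(default_factory=lambda: F_PHASE_GRID.copy())
    f_amp_grid: np.ndarray = field(default_factory=lambda: F_AMP_GRID.copy())
    alpha_ds: float = 0.001
    gate_family_alpha: float = 0.01
    pac_family_alpha: float = 0.05
    n_otc_surrogates: int = 100
    n_pr_shuffles: int = 200
    n_decode_null: int = 50
    n_mi_surrogates: int = 500
    n_electrodes_family: int | None = None  # Bonferroni family; len(electrodes) if None
    run_mi: bool = True
    run_decoding: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if not self.electrodes:
            raise ValueError("electrode list is empty")
        for count in (self.n_otc_surrogates, self.n_pr_shuffles, self.n_decode_null):
            if count < 2:
                raise ValueError("surrogate counts must be >= 2")


@dataclass
class ElectrodeReport:
    """Per-electrode results across all stages (JSON-serializable)."""

    name: str
    seed: int
    pac_plus: bool
    peak_modulated_freq: float
    f_max: float
    f_min: float
    preferred_phase_deg: float
    max_z: float
    z_threshold: float
    coding: dict = None  # per-category r / DS / PR at F_max (None if gate fails)
    gate_pass: bool = False
    pr_percentile: dict = None
    pr_significant: dict = None
    decoding: dict = None
    mi: dict = None
    frac_trials_with_window: float = np.nan
    ground_truth: dict = None
    error: str = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)


def analyze_electrode(
    session: TrialEpochSet,
    name: str = "electrode",
    seed: int = 0,
    f_phase_grid=F_PHASE_GRID,
    f_amp_grid=F_AMP_GRID,
    n_electrodes_family: int = 1,
    alpha_ds: float = 0.001,
    alpha_gate: float = 0.01 / 4,
    pac_family_alpha: float = 0.05,
    n_otc_surrogates: int = 100,
    n_pr_shuffles: int = 200,
    n_decode_null: int = 50,
    n_mi_surrogates: int = 500,
    run_mi: bool = True,
    run_decoding: bool = True,
    run_fmin: bool = True,
    ground_truth=None,
) -> tuple[ElectrodeReport, dict]:
    """Complete analysis of one electrode-session.

    Returns ``(report, intermediates)``; the intermediates dict holds the
    full objects (profile, decompositions, coding results) for further
    inspection or plotting.
    """
    seeds = spawn_seeds(seed, 4)
    rate = session.sampling_rate
    concat = session.concatenated
    boundaries = session.epoch_boundaries

    gamma = morlet_decompose(concat, rate, f_amp_grid)
    event_sets = detect_hfa_event_sets(gamma, boundaries=boundaries)
    del gamma
    phase_dec = morlet_decompose(concat, rate, f_phase_grid)
    raw_spectrum = np.array(
        [
            phase_dec.power[k][phase_dec.valid_mask(f)].mean()
            for k, f in enumerate(phase_dec.frequencies)
        ]
    )
    profile = compute_modulation_profile(
        concat,
        event_sets,
        rate,
        raw_spectrum=raw_spectrum,
        phase_grid=np.asarray(f_phase_grid),
        n_surrogates=n_otc_surrogates,
        seed=seeds[0],
    )
    pac_plus, _ = pac_plus_verdict(profile, n_electrodes_family, pac_family_alpha)

    report = ElectrodeReport(
        name=name,
        seed=seed,
        pac_plus=pac_plus,
        peak_modulated_freq=profile.peak_modulated_freq,
        f_max=profile.f_max,
        f_min=profile.f_min,
        preferred_phase_deg=profile.preferred_phase_deg,
        max_z=float(np.nanmax(profile.z_scores)) if profile.z_scores.size else np.nan,
        z_threshold=profile.z_threshold,
        ground_truth=dataclasses.asdict(ground_truth) if ground_truth else None,
    )
    inter = {"profile": profile, "event_sets": event_sets, "phase_decomp": phase_dec}
    if profile.empty or not np.isfinite(profile.f_max):
        report.error = "no usable HFA events"
        return report, inter

    hfa = event_sets[profile.peak_modulated_freq]
    _, frac_any = hfa_trial_timecourse(hfa, session)
    report.frac_trials_with_window = frac_any

    fmax_series = phase_dec.phase[phase_dec.freq_index(profile.f_max)]
    coding = analyze_phase_coding(
        fmax_series, hfa, session, profile.f_max, alpha_ds, alpha_gate
    )
    inter["coding"] = coding
    report.gate_pass = coding.gate_pass
    # DS is reported only where the clustering gate holds (null otherwise)
    report.coding = {
        c: {
            "r": coding.r[c],
            "mean_phase_deg": coding.mean_phase_deg[c],
            "ds": coding.ds[c] if coding.gate_pass else None,
            "pr": coding.pr[c] if coding.gate_pass else None,
        }
        for c in coding.r
    }

    # z at the peak gamma frequency, for placing surrogate events in shuffles
    peak_gamma = morlet_decompose(concat, rate, [profile.peak_modulated_freq])
    z_peak = zscore_power(
        peak_gamma.power[0], valid_mask=peak_gamma.valid_mask(profile.peak_modulated_freq)
    )
    del peak_gamma
    pr_null = pr_window_shuffle_null(
        hfa, fmax_series, session, n_pr_shuffles, seeds[1], alpha_ds, z_series=z_peak
    )
    inter["pr_null"] = pr_null
    if pr_null.get("defined"):
        report.pr_percentile = pr_null["percentile"]
        report.pr_significant = pr_null["significant"]

    if run_fmin:
        inter["fmin"] = fmin_control(
            phase_dec, profile, hfa, session, alpha_ds, alpha_gate
        )

    if run_decoding:
        try:
            dec = decode_electrode(
                fmax_series, hfa, session, n_decode_null, seeds[2]
            )
            inter["decoding"] = dec
            report.decoding = dec.to_dict()
        except ValueError as exc:
            report.decoding = {"error": str(exc)}

    if run_mi:
        mi = mi_analysis(
            concat, rate, n_surrogates=n_mi_surrogates, seed=seeds[3]
        )
        inter["mi"] = mi
        report.mi = {
            band: {k: v for k, v in res.items() if k != "profile"}
            for band, res in mi.items()
        }
    return report, inter


def _materialize(spec, seed):
    """Turn one electrode spec into (name, session, ground_truth)."""
    kind = spec.get("kind", "synthetic")
    if kind == "dataset":
        from .synth import read_dataset

        session, truth = read_dataset(spec["path"])
        return spec.get("name", Path(spec["path"]).stem), session, truth
    if kind == "edf":
        from .epochs import load_edf_session

        session = load_edf_session(
            spec["path"],
            spec["events"],
            window_ms=tuple(spec.get("window_ms", (-750.0, 1500.0))),
            channel=spec.get("channel", 0),
        )
        return spec.get("name", Path(spec["path"]).stem), session, None
    cfg = spec.get("config", SimulationConfig())
    if isinstance(cfg, dict):
        cfg = SimulationConfig(**cfg)
    cfg = dataclasses.replace(cfg, seed=seed)
    mode = spec.get("mode", "coding")
    if mode == "coding":
        session, truth = generate_session(cfg)
    else:
        session, truth = generate_null_session(cfg, mode=mode)
    return spec.get("name", f"{mode}_{seed}"), session, truth


def run(config: RunConfig) -> tuple[list[ElectrodeReport], dict]:
    """Execute the full pipeline over the configured electrode population.

    Two passes: OTC / PAC+ first on every electrode (the clustering-gate
    alpha depends on the PAC+ count), then phase coding, PR, decoding and
    MI. Deterministic given ``config.seed``.
    """
    n_family = config.n_electrodes_family or len(config.electrodes)
    elec_seeds = spawn_seeds(config.seed, len(config.electrodes))

    sessions = []
    for spec, s in zip(config.electrodes, elec_seeds):
        sessions.append(_materialize(spec, s))

    # pass 1: PAC+ verdicts to size the clustering-gate family
    reports: list[ElectrodeReport] = []
    inters = []
    for (name, session, truth), s in zip(sessions, elec_seeds):
        try:
            rep, inter = analyze_electrode(
                session,
                name=name,
                seed=s,
                f_phase_grid=config.f_phase_grid,
                f_amp_grid=config.f_amp_grid,
                n_electrodes_family=n_family,
                alpha_ds=config.alpha_ds,
                alpha_gate=gate_alpha(1, family=config.gate_family_alpha),
                pac_family_alpha=config.pac_family_alpha,
                n_otc_surrogates=config.n_otc_surrogates,
                n_pr_shuffles=config.n_pr_shuffles,
                n_decode_null=config.n_decode_null,
                n_mi_surrogates=config.n_mi_surrogates,
                run_mi=config.run_mi,
                run_decoding=config.run_decoding,
                ground_truth=truth,
            )
        except Exception as exc:  # keep the run alive; report the failure
            logger.exception("electrode %s failed", name)
            rep, inter = (
                ElectrodeReport(
                    name=name, seed=s, pac_plus=False,
                    peak_modulated_freq=np.nan, f_max=np.nan, f_min=np.nan,
                    preferred_phase_deg=np.nan, max_z=np.nan,
                    z_threshold=np.nan, error=str(exc),
                ),
                {},
            )
        reports.append(rep)
        inters.append(inter)

    # recompute the gate at the population-level alpha and refresh DS reporting
    n_pac = max(sum(r.pac_plus for r in reports), 1)
    alpha_gate = gate_alpha(n_pac, family=config.gate_family_alpha)
    for rep, inter in zip(reports, inters):
        coding = inter.get("coding")
        if coding is None:
            continue
        from .coding import clustering_gate, collect_hfa_phases

        cps = collect_hfa_phases(
            inter["phase_decomp"].phase[
                inter["phase_decomp"].freq_index(coding.frequency)
            ],
            inter["event_sets"][rep.peak_modulated_freq],
            _session_of(inter, rep, sessions),
            event_only=True,
        )
        gate, gate_pass = clustering_gate(cps, alpha_gate)
        coding.gate, coding.gate_pass = gate, gate_pass
        rep.gate_pass = gate_pass
        for c in coding.r:
            rep.coding[c]["ds"] = coding.ds[c] if gate_pass else None
            rep.coding[c]["pr"] = coding.pr[c] if gate_pass else None

    summary = summarize_population(
        reports,
        alpha_gate=alpha_gate,
        n_family=n_family,
        pac_family_alpha=config.pac_family_alpha,
    )
    if config.output_dir:
        _write_outputs(config, reports, summary)
    return reports, summary


def _session_of(inter, rep, sessions):
    for name, session, _ in sessions:
        if name == rep.name:
            return session
    raise KeyError(rep.name)


def summarize_population(
    reports: list[ElectrodeReport],
    alpha_gate: float = None,
    n_family: int = None,
    pac_family_alpha: float = 0.05,
    groups: dict | None = None,
) -> dict:
    """Population proportions and the computed significance thresholds.

    ``groups`` optionally maps electrode name -> group (patient analog)
    for per-group proportions.
    """
    ok = [r for r in reports if r.error is None]
    n = len(reports)
    pac = [r for r in ok if r.pac_plus]
    gated = [r for r in pac if r.gate_pass]

    def _ds3(r):
        return any(
            v.get("ds") == 3 for v in (r.coding or {}).values()
        )

    summary = {
        "n_electrodes": n,
        "n_failed": n - len(ok),
        "pac_plus_fraction": len(pac) / n if n else np.nan,
        "gated_fraction_of_pac": len(gated) / len(pac) if pac else np.nan,
        "ds3_fraction_of_gated": (
            sum(_ds3(r) for r in gated) / len(gated) if gated else np.nan
        ),
        "decode_sig_label_fraction": _flag_fraction(ok, "sig_label"),
        "decode_sig_event_fraction": _flag_fraction(ok, "sig_event"),
        "decode_sig_both_fraction": _flag_fraction(ok, "sig_both"),
        "z_threshold": reports[0].z_threshold if reports else np.nan,
        "alpha_gate": alpha_gate,
        "expected_chance_one_test": expected_chance_electrodes(0.05, 1, n),
        "expected_chance_conjunction": expected_chance_electrodes(0.05, 2, n),
    }
    if groups:
        per_group = {}
        for g in sorted(set(groups.values())):
            members = [r for r in ok if groups.get(r.name) == g]
            if members:
                per_group[g] = {
                    "n": len(members),
                    "pac_plus_fraction": sum(r.pac_plus for r in members) / len(members),
                    "ds3_fraction": sum(_ds3(r) for r in members) / len(members),
                }
        summary["per_group"] = per_group
    return summary


def _flag_fraction(reports, flag):
    vals = [
        (r.decoding or {}).get(flag)
        for r in reports
        if r.decoding and "error" not in r.decoding
    ]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else np.nan


def _write_outputs(config: RunConfig, reports, summary):
    import pandas as pd

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rep in reports:
        (out / f"{rep.name}.json").write_text(json.dumps(rep.to_dict(), indent=1))
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, default=_json_default)
    )
    rows = []
    for rep in reports:
        row = {
            "name": rep.name,
            "pac_plus": rep.pac_plus,
            "gate_pass": rep.gate_pass,
            "peak_modulated_freq": rep.peak_modulated_freq,
            "f_max": rep.f_max,
            "f_min": rep.f_min,
            "preferred_phase_deg": rep.preferred_phase_deg,
            "max_z": rep.max_z,
        }
        if rep.decoding and "error" not in rep.decoding:
            row.update(
                accuracy=rep.decoding["accuracy"],
                sig_label=rep.decoding["sig_label"],
                sig_event=rep.decoding["sig_event"],
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "population.csv", index=False)
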