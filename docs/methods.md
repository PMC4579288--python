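# Methods

## The model and its assumptions

The package tests the phase-coding hypothesis: that stimulus category is
carried by *which phase* of a slow local-field oscillation concentrates
high-frequency activity (HFA), over and above the mere presence of
phase-amplitude coupling (PAC). Three phenomena are deliberately kept
separable throughout:

1. **PAC** — gamma amplitude depends on slow-oscillation phase,
   irrespective of category (event-locked OTC analysis).
2. **Phase coding** — the phase at which HFA events occur differs
   between categories (difference scores, phase representation,
   decoding).
3. **Stimulus phase locking** — the slow phase is reproducible across
   trials of a category regardless of gamma (time–frequency Rayleigh
   control map).

Any electrode can show each of these with or without the others; the
synthetic generator can produce all combinations, and the dissociation
tests verify the pipeline assigns each scenario its correct signature.

Assumptions inherited from the analysis design: epochs are
concatenated by direct abutment and treated as phase-discontinuous at the
joints (supra-threshold runs are split at epoch boundaries); the
percentile defining HFA windows is taken per frequency over the whole
concatenated series; "exceeding" the percentile means strictly greater,
so a constant series yields no windows; and the Watson–Williams test
assumes concentrated samples (a warning fires below within-group mean
r ≈ 0.45).

## Pipeline constants

| parameter | default | why |
|---|---|---|
| slow (phase) grid | 0.5–12 Hz, 0.5 Hz steps | delta–alpha modulators; 0.5 Hz matches the 2-s modulatory-signal resolution |
| gamma (amplitude) grid | 32–120 Hz, 4 Hz steps | 23 center frequencies spanning low/high gamma |
| wavelet | Morlet, 7 cycles, zero-mean, unit-energy | scale cancels in z-scoring; 3 SD edge margins excluded from statistics |
| HFA window percentile | 95 | top 5% of z-power per frequency |
| OTC segment | ±1 s around each event | 2 s ⇒ 0.5 Hz spectral resolution for F_max/F_min |
| OTC surrogates | 100 | random timestamps, equal count, drawn without replacement, same edge rule |
| PAC z threshold | computed: two-sided normal deviate of 0.05/(n_gamma × n_electrodes) | ≈ 4.36 at 23 × 167; computed rather than hard-coded so reduced grids stay calibrated |
| DS alpha | 0.001 per category pair | six Watson–Williams tests, DS = count of significant pairs |
| clustering-gate alpha | 0.01/(n_PAC+ × 4), computed at run time | excludes phase "differences" without phase clustering |
| PR shuffles | 200, significant if observed > 95th-percentile value | strict comparison keeps ties at zero (null electrodes) null |
| decoding | linear SVM, C = 1, stratified 5-fold, 50+50 nulls | chance level is electrode-specific, so only permutation nulls are used |
| MI | 18 phase bins, 51–200 Hz amplitude, 500 shuffles, z > 1.65 | binned-amplitude KL divergence normalized to [0, 1] |

Angles are radians in (−π, π] internally and degrees in [0, 360) at
reporting boundaries, with the cosine convention 0° = oscillation peak,
180° = trough.

## The synthetic generator

Each session (one electrode) is built per trial as

```
x(t) = A·cos θ(t) + gamma(t) + slow(t) + pink(t) + background(t)
```

with θ(t) = 2π f_m t + φ_trial the modulator phase (f_m = 1 Hz, A = 1),
φ_trial uniform per trial so stimulus onset carries no phase information
(unless the phase-locked control mode is on);
`gamma(t) = 0.8·(0.15 + g(t)·env(t))·cos(2π f_c t + ψ)` an 84 Hz carrier
whose envelope `env = (1−d) + d·exp(κ(cos(θ−μ_c)−1))` follows a von Mises
window (depth d = 0.8, κ = 4) at the trial category's preferred phase
μ_c, gated on by `g(t)` 150 ms after onset and off at image offset (25 ms
cosine ramps); 1/f "pink" noise at ~10 dB modulator SNR (sd 0.224, flat
below 0.5 Hz); and flat-spectrum 30–200 Hz background gamma (sd 0.6)
representing ongoing broadband activity.

`slow(t)` is a burst-locked slow-potential term: a sharper von Mises
deflection (κ = 8) of amplitude 1.2 × gamma amplitude × depth, phase-mean
removed and gated with the stimulus. It models the local slow field that
accompanies population bursts, and it is what makes coupling visible to
event-locked averaging when the four categories' preferred phases are
symmetric on the circle: amplitude-only coupling at phases summing to a
zero phasor (0/90/180/270°) cancels exactly in the event-locked average,
whereas the deflection is always peaked at the event itself, independent
of μ_c. Its leakage into the 1 Hz band (fundamental amplitude
2e^{−κ}I₁(κ)·c ≈ 0.2·c) biases recovered category phases by under ~10°,
inside the 20° recovery tolerance the tests assert.

The background gamma level (0.6) was set so that windows detected more
than ~8 Hz from the carrier are dominated by uncoupled background rather
than wavelet leakage of the bursts; without it, off-carrier windows stay
burst-locked and the surrogate-z profile plateaus far beyond the carrier.
Even so, a 7-cycle wavelet at 84 Hz has σ_f ≈ 12 Hz, so the recovered
peak modulated frequency scatters over roughly ±1 grid step around the
carrier; recovery summaries therefore aggregate over electrodes.

**What the generator does not emulate:** epileptiform or ocular
artifacts, non-stationary coupling strength, multi-electrode correlation
structure, broadband (non-sinusoidal) modulators, and inter-trial phase
continuity (epochs are independent). Passing tests therefore demonstrate
method correctness and calibrated inference under the modeled structure,
not robustness to every pathology of clinical recordings.

## Statistical choices

- **Sampling unit for DS/clustering/PR: one phase per HFA event.**
  Pooled in-window samples are serially correlated (the phase sweeps
  ~60° across a 170 ms window at 1 Hz), which inflates the effective n
  of the Watson–Williams test by two orders of magnitude and turns
  degree-scale sampling noise into spurious difference scores on
  electrodes whose categories genuinely share one phase. Event-level
  phases are approximately independent draws, keeping the parametric
  tests calibrated; the pooled-sample variant remains available via
  `event_only=False` for sensitivity analysis. The window-shuffle PR
  null is the primary inferential control either way.
- **PR significance** uses a strict comparison against the null's
  95th-percentile *value*; with percentile-of-score conventions, ties at
  PR = 0 (the typical null shuffle outcome) would otherwise count as
  extreme.
- **Watson–Williams** uses the high-concentration F formulation with the
  1 + 3/(8κ̂) correction and the standard piecewise A⁻¹(r̄)
  approximation for κ̂; it is validated against a 10⁴-draw permutation
  oracle (agreement within ±0.02 at n = 20/group).
- **Rayleigh p** uses the small-sample-corrected exponential
  approximation; its type-I error is verified at 0.05 ± 0.01 over 10⁴
  uniform replicates at n = 50.
- **Surrogate events** are drawn uniformly without replacement from the
  same edge-respecting range as real events; the random-event decoding
  null additionally preserves each trial's event count.
- **Ties**: window-peak ties resolve to the earliest sample; flat
  modulatory spectra resolve F_min to the lowest grid frequency and are
  flagged.
- **Degenerate inputs** raise explicit errors (zero-variance z-scoring,
  empty phase samples, all-zero MI amplitude, masks that empty a
  category) except where the contract requires an empty result (no
  usable OTC events returns an explicitly empty profile).

## Problem sizes

The emulated experiment is 120 trials per category (480 total). The test
suite and the acceptance script run reduced sessions chosen for
comfortable statistical margins: 48 trials/category in the test-suite
recovery fixtures and 64 in the acceptance script (the surrogate-z
criterion scales with the square root of the event count and clears its
threshold with margin at these sizes), 24 for the dissociation scenarios, and 8 for the no-coupling
calibration population (100 electrodes in the tests, 60 in the
acceptance script) with a six-frequency gamma grid — the false-positive
rates under test are threshold-calibrated by construction and do not
depend on grid size, since the Bonferroni threshold is recomputed from
the actual family.

## Known limitations

- The OTC peak-modulated-frequency estimate has the wavelet's spectral
  resolution, not the grid's: single-electrode estimates scatter ±1 bin
  around a narrowband carrier.
- The modulation-strength surrogate null is a peak-to-trough (extreme
  value) statistic and is mildly right-skewed; the z threshold is
  therefore slightly anticonservative near the nominal boundary. The
  spectral peak-match criterion absorbs most of this in practice, and
  the calibration tests measure the realized rates.
- EDF export quantizes to 16 bits (~10⁻⁵ relative amplitude error);
  round trips are verified through an independent reader (MNE).
- `time_resolved_category_contrast` tests each time point marginally
  with a trial-label permutation gate; it makes no multiple-comparison
  claim across time.
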