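# Methods

This note documents the models behind the synthetic-data generators, the
measurement conventions of the four analysis pipelines, and the design
choices made where the procedure was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Arena and rate-map conventions

The open field is a square arena, 50 cm on a side by default, discretized
into 15 × 15 bins; with these defaults each bin covers (50/15)² ≈ 11.1 cm².
The analysis convention fixes the bin *area*, not the arena side, so the
side length is a configurable parameter chosen to reproduce that area.

Occupancy accumulates one tracking interval (25 ms default) per sample into
the bin containing the sample's position, restricted to running periods:
samples with speed strictly above 3 cm/s. Speed is the centered
finite-difference displacement rate, boxcar-smoothed over 0.1 s. Bin
membership is half-open `[edge_i, edge_{i+1})` with the last bin closed, so
a position exactly on an interior edge belongs to the higher-index bin.

Rate maps divide speed-filtered spike counts by dwell time per bin; spike
positions are linearly interpolated from the tracking at spike times and
speed-filtered with the same threshold. Bins with zero dwell are undefined
(NaN) and are excluded from every subsequent sum — they are never imputed
with zeros. Smoothing uses a Gaussian kernel of σ = 1 bin (truncated at
4 σ), renormalized over visited bins so unvisited bins contribute no
weight; smoothing is applied to the rate map only, after division, never to
the occupancy.

## Spatial information

The default (`mode="skaggs"`) measure is the occupancy-weighted information
per spike,

    SI = Σ_x p_x (λ_x/λ̄) log₂(λ_x/λ̄),  λ̄ = Σ_x p_x λ_x,

with `0·log 0 ≡ 0`. A `mode="literal"` variant computes the unweighted sum
`(1/Σ_x P_x) Σ_x (λ_x/λ̄) log₂(λ_x/λ̄)` with occupancies normalized to
probabilities (so the prefactor is 1). The two modes agree on uniform maps
(both 0) and share scale invariance, but only the weighted form is
guaranteed non-negative: when occupancy concentrates on high-rate bins, the
unweighted sum over many below-average bins can be negative. The weighted
form is therefore the default and the only mode for which the non-negativity
property test is asserted.

Quadrant-restricted SI renormalizes both the occupancy probabilities and
the mean rate within the quadrant, so it equals the whole-map SI of the map
restricted to that quadrant's bins; a `mean_rate_scope="global"` switch
keeps the whole-map mean rate instead. The within-quadrant form is the
default: in null calibration experiments (no inhibition, two identical
sessions) the global-mean variant couples quadrant-level occupancy
fluctuations into the quadrant scores and grossly inflates the
inside-vs-outside test's false-positive rate, while the within-quadrant
form does not.

For an odd grid the central row and column have bin centers exactly on the
arena midlines; those 29 bins (on 15 × 15) are excluded from quadrant
analysis, leaving four quadrants of 49 bins each.

Unit inclusion follows the putative-pyramidal convention: whole-session
mean rate within [0.2, 5] Hz (inclusive) and at least 0.2 Hz in both the
first and last 15 minutes. These rates use unfiltered spike counts — the
speed filter applies to maps, not to the inclusion rule — with the
filtered variant available as a switch.

## The three-session quadrant-inhibition experiment

`pipeline.run_quadrant_inhibition_experiment` simulates three 30-min
exposures (S1, S2, S3). During S2 only, each unit's instantaneous rate is
flattened toward its own session-mean rate while the animal is inside one
target quadrant: λ → (1−d)·λ + d·λ̄ with degradation d. This models a loss
of spatial tuning with minimal change in average rate — the observed
phenotype — rather than silencing; no mechanistic claim is attached to it.
Per unit and session, the pipeline computes the smoothed quadrant SI; the
SI change (S2−S1, S3−S1) in the target quadrant ("inside") is compared to
the mean change over the other three quadrants ("outside") with a
two-sided Mann–Whitney test (exact null when n₁·n₂ ≤ 400 and untied,
normal approximation with continuity and tie correction otherwise).

A design point discovered during null calibration: units recorded
*simultaneously* share one trajectory per session, and the session-specific
dwell pattern induces a common shift in all of their quadrant-SI estimates.
A unit-level rank test treats units as exchangeable, so with 100 units on a
single trajectory its false-positive rate at α = 0.05 is ~25 % (and still
~22 % with four trajectories). The experiment driver therefore pools 5
units from each of 20 independent recordings by default
(`n_recording_sessions=20`), under which the measured null rejection rate
is 5 % — i.e. the condition under which the unit-level test is actually
valid. The validation experiment should be read accordingly: it
demonstrates recovery for a multi-recording unit pool, not for 100 units
from one implant.

## Synthetic data: what it emulates, and what it does not

**Trajectories.** A 2-D Ornstein–Uhlenbeck velocity process (mean speed
8 cm/s, persistence 1 s) integrated at 25 ms, with the free path folded at
the walls. This produces realistic speed distributions including sub-3 cm/s
epochs that exercise the speed filter. It does not reproduce thigmotaxis,
rearing pauses, or home-base behavior of real mice.

**Spike trains.** Inhomogeneous Poisson by thinning against the
piecewise-constant per-sample rate — adequate at 25-ms resolution for rates
up to ~40 Hz. Place fields are isotropic Gaussians (σ = 6 cm, peak 6 Hz,
baseline 0.5 Hz → mean rate ≈ 1 Hz, inside the 0.2–5 Hz inclusion band).
No theta modulation, phase precession, bursting or rate remapping.

**Punctum images.** Deterministic counts `round(density · area)` of 2-D
Gaussian puncta (σ = 120 nm, peak 1000) at 40-nm pixels, default densities
0.25/µm² per channel over a 20 × 20 µm field, Gaussian read noise.
A chosen fraction of A-puncta is placed at distance U(0, `coloc_radius`)
(default 40 nm) from distinct B-puncta. The defaults were set by a mask
geometry argument made before freezing the tests: with an analysis
threshold at 6.5 % of the punctum peak the single-punctum mask is ≈ 154 px,
large enough that genuinely colocalized pairs survive the 0.1-µm² area
filter with ~95 % of their area, while accidental A–B encounters at these
densities mostly produce sub-63-px overlaps that the filter removes. That
keeps the relative-density estimator's bias inside ±0.05 across the whole
truth range. Real STED data differ in punctum shape and size dispersion,
background autofluorescence and threshold subjectivity, so passing recovery
tests here validates the estimator's geometry, not its robustness to
acquisition artifacts.

**EPSC trains.** Linear superposition of unit-peak biexponential kernels
(τ_rise 2 ms, τ_decay 50 ms, inward amplitude −100 pA, onset latency 4 ms)
with per-pulse multiplicative depression (default ratio 0.05, i.e. nearly
absolute) and Gaussian noise at 20 kHz. `n_sweeps` averages independent
noise realizations, mirroring how evoked responses are averaged before
kinetic measurement; the parameter-recovery validation measures 10-sweep
averages at per-sweep SNR 10. No stochastic vesicle release, recovery from
depression within the train, or NMDA component.

**Nosepoke cohorts.** Poisson(120) pokes per animal-day; the probability of
choosing the assigned port follows p(t) = p∞ − (p∞ − p0)·exp(−t/τ_eff)
within each session (p0 = 1/8 chance, p∞ = 0.75, τ = 0.8 d). Ablation
(fraction of the projection removed; 12 TMP animals spread over 0.25–0.95,
12 vehicle animals at 0) slows learning in the novel sessions B/C/D via
τ_eff = τ·(1 + 6·ablation), and preserves the pre-manipulation port memory
in the return session A\*: its curve starts at
p0 + retention·(p_end_A − p0) with retention = 0.1 + 0.9·ablation. This
coupling is a phenomenological stand-in encoding the qualitative
dissociation — impaired new learning and impaired forgetting — and makes no
claim about mechanism or effect size in real animals.

## Colocalization pipeline conventions

Masks are strict (`intensity > threshold`). The "manual" threshold of an
interactive analysis is replaced by an explicit numeric parameter, recorded
in every result; `threshold="auto"` uses the triangle histogram method,
which is appropriate for background-dominated punctum images (Otsu's
criterion collapses into the noise mode when the foreground occupies less
than a few percent of pixels). Connected components use 8-connectivity by
default (switchable to 4). "Smaller than 0.1 µm²" is read strictly: at
40-nm pixels the 62.5-px boundary makes ≤ 62 px removed and ≥ 63 px
retained, with no integer ambiguity. The overlap mask is built from the
already area-filtered channel masks and filtered again. Centroid matching
is mutual-nearest-neighbor one-to-one within 2 µm, with a greedy
distance-sorted alternative.

## EPSC measurement conventions

All metrics operate on baseline-corrected traces (mean of the 50 ms before
the first stimulus) and are invariant to offset and polarity. Level
crossings are linearly interpolated. On noisy traces, peaks are localized
on a 1-ms boxcar-smoothed copy and the amplitude taken as the raw-trace
mean over ±0.25 ms around that point; rise and half-width crossings use a
lighter 0.3-ms window (heavier smoothing visibly biases crossings near the
flat peak); noiseless traces are measured on raw samples. Onset latency is
the 5 %-of-peak crossing, detected as the last below-to-above transition
before the peak at an effective level of at least 3× the smoothed-noise SD
and walked back down the 20–80 % slope to the nominal 5 % level — on a
noiseless monotonic rise this reduces exactly to the first 5 % crossing.
The decay fit is a monoexponential least-squares fit from the falling-phase
90 %-of-peak crossing to the earlier of the next stimulus or 95 % recovery.
The paired-pulse ratio subtracts the extrapolated monoexponential decay of
the first response before measuring the second peak, appropriate when the
decay (τ ≈ 50 ms) is slow relative to the 100-ms interval; a plain
peak-minus-prestim alternative is switchable. A "no response" flag is
raised when the candidate amplitude does not exceed 3× the baseline SD.

One validation caveat: the 20–80 % rise time at single-trace SNR 10 is
intrinsically sensitive to amplitude error, because the 80 % level sits on
the flat near-peak slope; the noisy-grid validation therefore asserts
amplitude, decay τ and latency, while rise time is validated on noiseless
closed forms (τ·ln 4).

## Behavior conventions

The daily error rate is non-assigned / total nosepokes per 24-h window
anchored at the injection time (day 0); the literal success-rate reading
is available as `definition="literal"`. The learning-criterion exclusion is
strict (< 0.70 on the last initial-learning day, day −1); animals with no
pokes on that day are excluded with a logged reason. Day 8 is the last day
of the third novel session (D) and day 9 the first day of the return
session (A\*); the ablation/performance analysis correlates surviving
terminal density with the day-8 error rate one-tailed for a negative
association and with the day-9 error rate one-tailed for a positive one.
Spearman correlations use average ranks for ties; the one-sided p comes
from full enumeration of the n! permutation null for n ≤ 10 (computed in
vectorized chunks) and from the t approximation with n − 2 degrees of
freedom otherwise.

## Numerical and validation choices

- All generators are pure functions of (parameters, seed); sub-streams are
  split with `numpy.random.SeedSequence` spawn keys, so per-unit and
  per-animal streams are independently reproducible.
- Validation problem sizes: 20 seeds for each stochastic recovery
  experiment; 100 units over 20 recordings for the quadrant experiment;
  20 image pairs per colocalization fraction; a 3×3×3 EPSC parameter grid;
  1,000 random 5×5 maps for the SI oracle. These sizes give the multi-seed
  rates quoted by the acceptance script while keeping the whole validation
  within about a minute.
- Mann–Whitney switches from the exact to the asymptotic null at
  n₁·n₂ > 400 or in the presence of ties; two constant identical samples
  define p = 1.
- Degenerate inputs are flagged, not silently coerced: silent maps and
  empty reference masks give NaN with a warning, non-positive durations,
  unsorted stimulus times and overlapping schedules raise `ValueError`.
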