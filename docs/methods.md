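# Methods

This package quantifies whether minimally invasive **subscalp EEG**
(electrode contacts implanted between scalp and cranium) records brain
activity noninferior to conventional scalp EEG. It implements the complete
measurement and decision chain — spectral estimation, topographic
comparison, agreement statistics, margin-based noninferiority verdicts —
together with a synthetic multimodal EEG generator that provides
ground-truth test beds for every stage. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic validation does and does not establish.

## Spectral estimation

Power spectral densities are estimated with the multitaper method over
5-second sliding windows with 50% overlap. Windows are tapered with DPSS
(Slepian) sequences at time-bandwidth product NW = 4; the **6 tapers**
whose spectral concentration exceeds 0.99 are retained (2NW − 2). The
marginally concentrated 7th taper (concentration 0.937) leaks roughly 10%
of a strong oscillation's power across the whole spectrum; with slow-wave
amplitudes this tilts the broadband fit and caps the measured band peak
power, so it is excluded — the standard concentration-based retention
rule. Densities are one-sided and normalized so that the integral over
frequency equals the signal variance (Parseval; verified to 5% on white,
sinusoidal and power-law inputs). The 5-s window gives a 0.2 Hz grid.

The **aperiodic (1/f) component** is a least-squares line in log10 power
versus log10 frequency over 1–45 Hz, excluding the oscillation band under
analysis plus a guard band (1 Hz below to 3 Hz above the band) that keeps
the oscillation's spectral skirts out of the fit. The model is knee-less;
the exponent is the negative slope. **Band peak power** is the maximal dB
departure of the spectrum above this line within the band — the unit of
the −0.5 dB noninferiority margin. It can be negative when no oscillation
is present.

In the cohort pipeline the aperiodic **exponent is estimated once per
recording** (median of the per-channel free fits) and only the offset is
fitted per channel. A per-channel slope, extrapolated below a one-sided
support (for the 0.5–4 Hz delta band the fit support is entirely above the
band), wobbles by ~1.7 dB at 2 Hz and would inject uncorrelated error into
every subscalp–scalp pair difference; the broadband slope is treated as a
property of the recording, not of a single channel. The `spectral` module
itself keeps the free per-spectrum fit.

**Magnitude-squared coherence** pools cross- and auto-spectra over all
taper × window segments: C(f) = |Σ X_a X_b*|² / (Σ|X_a|² Σ|X_b|²), clipped
to [0, 1], with a minimum of 8 sliding windows. For independent inputs the
estimator's bias floor exceeds the naive 1/K (K = tapers × windows)
because 50%-overlapping windows are correlated; the implementation carries
the exact floor, (K + 2(n_win − 1) Σ_kl q_kl²)/K², where q_kl is the inner
product between taper k and taper l time-shifted by one window step. The
analytic floor matches Monte-Carlo to three digits and is what the
calibration tests assert against.

## Topographic analysis

Each subscalp contact is paired with its **closest scalp contact** in 3D
(ties broken by contact name). Topographic maps — one scalar per contact —
are compared by Pearson spatial correlation, by default after thin-plate
spline interpolation of both maps onto a common head-disk grid
(azimuthal-equidistant projection about the vertex); a matched-contacts
mode correlates the paired per-contact values directly. Significance comes
from a permutation null: the subscalp map's value-to-contact assignment is
shuffled 100 times and the one-sided p-value is
(1 + #{null ρ ≥ observed}) / 101. ρ > 0.5 and ρ > 0.7 are reported as
moderate and strong. The permutation test is calibrated: over 1000
independent random map pairs it rejects at 5.0% ± 1.5% at α = 0.05.

## Agreement statistics and noninferiority

Paired subscalp/scalp measurements are assessed with:

* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures — the variant sensitive to systematic offsets, computed with
  pingouin and cross-checked against a hand-written ANOVA
  sums-of-squares implementation to 1e-10;
* **Bland-Altman** bias (mean subscalp − scalp difference) with a
  parametric t-interval and 1.96·SD limits of agreement;
* margin-based verdicts: ICC > 0.75 **and** bias not below the preset
  margin (−0.5 dB for oscillatory peak power, −1 μV for voltage, −0.03 for
  coherence). Two bias rules are implemented: the conservative
  CI-lower-bound rule (module default) and the point-estimate rule that
  compares the mean difference to the margin. The cohort pipeline uses
  the point-estimate rule, which is how such margins are read in
  practice when the mean is reported against a preset limit; every report
  row records which rule produced its verdict.
* **Cohen's κ** (unweighted, 5-stage confusion table) for sleep scoring,
  against the 0.60 substantial-agreement margin, with the exact two-sided
  binomial **sign test** for paired scorer comparisons (ties dropped).

## The synthetic cohort

No public recordings accompany the trial setting this package addresses,
so the generator produces co-registered subscalp/scalp/intracranial
recordings with known ground truth. Geometry is a single sphere of radius
92 mm: 25 scalp contacts at standard 10-20 angular positions (19 standard
plus 6 inferior temporal), subscalp contacts on the concentric sphere 7 mm
deeper along 1–4 trident leads (three branches 100–120 mm long fanning 30°
from a peripheral entry point — frontal, temporal left/right, parietal — 7
contacts per trident, 40 mm inter-contact spacing), and intracranial
contacts strictly inside.

**Source-to-sensor coupling.** Oscillatory sources project with an
exponential distance-decay gain exp(−d/λ) floored at 0.01 (below the
floor the gain is exactly zero — deep sources are extracranially
invisible). Dipolar discharge fields use a Gaussian kernel
exp(−d²/2σ²) times the signed cosine between the dipole moment and the
dipole-to-sensor direction, with the far (opposite-polarity) lobe
attenuated to 0.15: a flat-topped apex and a dominant pole, the shape of a
skull-smoothed focal field. An exponential kernel has a constant
log-gradient even at the field maximum, which would make neighboring
contacts 30 mm apart disagree by >20% at the apex — unlike real scalp
fields, whose extremum is locally flat.

**Sensing positions.** Extracranial contacts (scalp and subscalp alike)
sense the source field at their radial projection onto the scalp sphere;
intracranial contacts at their true position. This makes the generator's
null condition exact: with subscalp gain 1.0 and equal noise, a subscalp
contact and a scalp contact along the same radius record identical
signals, so any systematic subscalp deficit in an analysis is attributable
to the injected gain factor, not to the 7 mm depth offset built into the
geometry. The subscalp gain factor (amplitude scale on subscalp source
projections; default 1.0) is the single dial that breaks noninferiority.

**Stage-specific activity.** Each sleep-wake stage carries bilateral
narrowband source pairs (band-passed Gaussian noise, 6th-order zero-phase
Butterworth) on a 1/f^1.5 background (10 μV RMS, spectrally shaped white
noise) plus 2 μV white sensor noise per channel:

| stage | oscillation | band (Hz) | sources (polar, azimuth) | RMS/source |
|---|---|---|---|---|
| W (eyes closed) | posterior alpha | 8–12 | (75°, ±160°) | 22 μV |
| N2 | central sigma (spindles) | 11–16 | (48°, ±85°) | 18 μV |
| N3 | frontal delta (slow waves) | 0.5–4 | (55°, ±35°) | 140 μV |
| REM | frontal beta | 16–30 | (55°, ±35°) | 15 μV |

Sources sit on a 78 mm cortical shell with 80 mm spatial spread (110 mm
for alpha, whose posterior-to-frontal gradient spans the whole head).
Band edges are conventional clinical definitions. Delta is strongest
because slow waves are the largest EEG rhythm; amplitudes were chosen so
that band peak power sits 10–30 dB above the background across the head.
Each participant expresses each stage's oscillation with an individual
strength (lognormal, 4 dB SD) — oscillation power varies by an order of
magnitude across people, and this between-participant spread is what the
pooled scatterplots across n = 161 electrode pairs resolve.

**Events.** Interictal spikes are biphasic templates (70 ms, 20 ms rise)
from a deep (40 mm radius) mostly-radial dipole under the subscalp
coverage, amplitude 45 μV with 10% per-spike jitter and 2 dB
between-spike-type spread, Gaussian field σ = 160 mm. Seizures are linear
chirps (≈13 → 3 Hz) with an amplitude ramp over the first third, starting
at the SOZ and appearing phase-perturbed at the PZ after a propagation
delay; extracranial channels receive distance-weighted mixtures. Evoked
responses are Gaussian-windowed components (visual: occipital 10/−6 μV at
100/180 ms; auditory: bilateral temporal-central −6/+4 μV at 100/200 ms)
repeated at fixed inter-stimulus intervals. Simulated sleep scorers are
modelled by independently relabelling each epoch of the ground-truth
hypnogram with probability 0.08.

## The bundled cohort study

`pipeline.run_study` simulates 8 participants carrying 4, 4, 4, 4, 3, 2,
1, 1 tridents — 23 tridents, 161 subscalp contacts, hence 161 pooled
neighboring pairs — and runs six analyses: 120 s of eyes-closed wake
(alpha peak power per pair, pairwise alpha peak coherence), 120 s per
sleep stage (sigma/delta/beta peak power), sleep scoring (3 simulated
scorers × 2 modalities × 960-epoch nights; inter- and intra-rater κ, sign
test across nights), evoked blocks (250 visual / 180 auditory trials;
per-contact amplitude at the global-field-power peak), five 45-s seizures
per participant (closest-contact-triplet mean 0.5–30 Hz coherence with the
SOZ and PZ channels; n = 40 seizure pairs), and 30-spike peak-aligned
averages (full-coverage participants only, five spike types, n = 140
pairs; a 3 Hz zero-phase high-pass precedes averaging, as in clinical
spike review). Topographic spatial correlations with the 100-shuffle
permutation null are computed for the four full-coverage participants.
All randomness derives from the single study seed through stable hashed
child seeds, so re-running with the same seed reproduces the report
byte-for-byte.

These problem sizes are the package's defaults: long enough for stable
multitaper estimates (47 windows for 120-s segments, 17 for 45-s
seizures), small enough that a complete study runs in well under a minute
on one core.

## What the validation shows — and what it does not

The headline recovery property holds on the bundled cohort: with subscalp
gain 1.0 and equal noise, all noninferiority margins (ICC > 0.75 and the
−0.5 dB / −1 μV / −0.03 margins) pass in ≥ 95% of independent seeds; with
a −1.5 dB subscalp attenuation injected, all four dB verdicts fail in
every seed and the wake-alpha Bland-Altman bias recovers the injected
deficit to within ±0.3 dB. The sleep-stage dB biases carry small positive
geometric offsets (+0.3–0.5 dB, from the asymmetry between the subscalp
ensemble and the fixed scalp grid relative to the frontal/central
sources), so they under-recover the injected deficit while still failing
their margins; the wake-alpha measure, whose geometry is balanced, is the
calibrated recovery readout.

The generator is a test bed, not a forward model. It omits volume
conduction (no BEM/FEM), physiological artifacts (EMG, eye movement,
cardiac), electrode impedance drift and device deficiencies, non-stationary
sleep microstructure, and realistic spike/seizure waveform diversity.
Passing these tests therefore demonstrates that the analysis chain is
correct and calibrated — that it recovers known effects at the right
magnitude and rejects absent ones at the right rate — not that any
particular hardware is noninferior on real recordings.

## Numerical details

* Sampling rate 256 Hz; all bands of interest lie below the 45 Hz
  analysis ceiling with margin.
* AASM 30-s scoring epochs.
* Coherence requires ≥ 8 sliding windows; seizure segments shorter than
  22.5 s fall back to 2-s windows and are flagged in the profile.
* Spike alignment searches ±50 ms around the annotated onset for the
  alignment-channel extremum; epochs whose extremum lands on the search
  boundary are excluded. Epoch window ±250 ms.
* Evoked epochs span −100 to +300 ms with a −100–0 ms baseline; trials
  overlapping a recording edge are dropped and counted.
* Permutation p-values are (1 + #{null ≥ observed})/(n_shuffles + 1);
  n_shuffles < 19 is rejected (cannot resolve α = 0.05).
* The ICC confidence interval comes from the standard F-distribution
  interval; a perfect-agreement table returns ICC 1 with a degenerate
  interval. EDF export uses 16-bit quantization over a per-channel
  symmetric physical range in μV, 1-s records.
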