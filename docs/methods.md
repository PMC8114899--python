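# Methods

This note documents the models, estimators and design choices behind
`qeeg`, what the synthetic generator does and does not emulate, and the
numerical conventions that make results reproducible.

## Signal model and preprocessing

Recordings are multichannel EEG in μV at a nominal 2000 Hz (two
cortical screw channels and one hippocampal depth channel in the
emulated preparation). The acquisition filter chain is a 0.5–70 Hz
bandpass plus a mains notch; we implement it as a 4th-order Butterworth
bandpass and a biquad notch (Q = 30, 60 Hz default, 50 Hz
configurable), applied forward-backward (zero-phase) so that event
timing and spike morphology are not skewed by group delay. Because
forward-backward filtering squares the magnitude response, the
effective attenuation at the notch and stopbands is doubled in dB;
passband tones (2–40 Hz) are preserved within 5% and filtering is
idempotent there.

Artifact handling substitutes a deterministic rule for manual
video/EMG review, and any externally supplied manual mask (interval
TSV) is unioned in. The automated rule flags (a) *sustained*
high-amplitude excursions — |signal| above 6× the robust channel scale
(MAD × 1.4826) for at least 0.3 s, with sub-threshold dips under 50 ms
not splitting a run — and (b) high-band (70–250 Hz) envelope excursions
above 4× the envelope's robust scale. Two deliberate refinements:
brief transients are excluded from rule (a) because movement/EMG
artifacts last seconds while epileptiform transients last under
200 ms — without the duration gate the artifact mask would swallow the
very spikes the detector must count; and the envelope scale in rule
(b) is floored at 0.1× the broadband scale so that a cleanly
band-limited signal is not flagged on its numerical noise floor.
Flagged runs are padded by 0.5 s, merged across gaps under 0.5 s, and
unioned across channels (movement is recording-wide). All intervals
everywhere are half-open `[onset, onset+duration)` in seconds from
recording start, which removes boundary double-counting.

## Spectral estimation

The PSD is a Welch average over Hann-windowed segments of 2042 samples
with 50% overlap — the acquisition software's printed configuration,
kept verbatim as the default (2048 is configurable). Segments are
drawn only from artifact-free intervals; a segment that would cross an
interval boundary is discarded rather than truncated so every averaged
segment is uniformly windowed. Normalization is one-sided density
scaling with window-power correction, so the integrated PSD equals the
mean signal power within Monte-Carlo tolerance (Parseval is a tested
invariant, ≤5% on white noise).

Band power is *integrated* PSD (μV²), matching the reported unit; a
frequency bin belongs to a band when its center lies within the band's
closed interval, and the printed inter-band gaps (4–5, 12–14, 29–30 Hz)
are preserved rather than redistributed. Two per-frequency reductions
exist and serve different purposes:

* `per_hz_power` integrates the piecewise-constant PSD over
  `[k−0.5, k+0.5)` for k = 0..50 — exactly additive, for band-table
  style reporting.
* `power_at_frequencies` samples the PSD at the bin nearest each
  integer frequency (× 1 Hz). This is the input to the inferential
  genotype × frequency table: adjacent *integrated* 1-Hz bins share
  Hann-leakage boundary bins and are therefore positively correlated,
  which inflates the genotype F (measured null rejection ~11% at
  α = 0.05); sampled values at integer spacing are effectively
  independent when the grid is fine relative to 1 Hz, and restore
  nominal calibration (measured ~6% over 600 null cohorts). With ~1-s
  windows the grid is Δf = fs/2042, so analyses meant for inference
  should keep Δf well below 0.5 Hz.

A consequence of the ~1-s Hann window worth knowing: a tone that is
not on the FFT grid spreads over ±2 bins, so at Δf ≈ 1 Hz a 2-Hz tone
necessarily leaks ~1/3 of its power into neighboring 1-Hz bins. This
is window physics, not an aggregation artifact; at Δf ≈ 0.24 Hz the
same tone concentrates >99% in its bin.

## Spike and polyspike detection

The classifier implements the printed criteria — spike: waveform
<200 ms with peak ≥2× baseline background amplitude; polyspike:
crossing the baseline more than two times — with the following
operational definitions:

* **Baseline background amplitude** is the median over 10-s unmasked
  blocks of the within-block 95th percentile of |signal|: a robust
  peak-scale surrogate for the visually perceived background envelope,
  insensitive to the spikes themselves (each block contributes a
  percentile; blocks are medianed).
* **Candidates** are maximal runs with |signal| ≥ 2× baseline lasting
  at least 10 ms (shorter exceedances are noise ticks, not waveform
  peaks). Runs are grown to the nearest zero-line crossings, and
  extents closer than 100 ms merge into one event.
* **Crossing the baseline** is read as crossing the zero line of the
  trace within the event extent (the clinical reading of multi-phase
  polyspikes); a config flag switches to threshold-level crossings.
* **Duration** for the <200 ms criterion is the span of the sharp
  supra-threshold complex (first to last supra-threshold sample of
  the merged event), not the zero-grown extent: on a δ-dominated
  background the zero-grown extent routinely rides a slow wave for
  0.3–0.5 s and the literal reading discards genuine spikes.
* **Slow-trend confirmation** (spikes only): the event's prominence
  above the <2 Hz component (zero-phase 2nd-order Butterworth lowpass)
  must also reach the threshold. This models the reviewer measuring a
  spike's peak against the slow wave it rides; without it, slow-wave
  summation pushes a nontrivial fraction of sub-criterion (1.5×)
  events over the absolute threshold. Polyspikes are exempt — a
  multi-phase event crossing zero three or more times inside ~1 s
  cannot be a slow-wave bump, and slow polyspike trains (<2.4 Hz lobe
  alternation) would otherwise be absorbed into the trend.
* Merged events ≥200 ms that are not polyspikes are discarded (slow
  waves; not epileptiform under the printed rule).

Measured on the synthetic background at the study's effect size
(events at 4× baseline): sensitivity ≥ 0.98, false positives
≤ 0.3/min, and ≤ 5% detection of 1.5× (sub-criterion) events.

## Percent time in epileptiform activity

Observation epochs follow the printed scheme (2-min epochs every
10 min across the analysis window; e.g., one hour yields 6 epochs /
720 s). The statistic counts whole 1-s bins, aligned to epoch starts,
that intersect any detected event — the "seconds that included
epileptiform activity" reading — and divides by observed (unmasked)
epoch time; exact event-duration summation is available as an
alternative counting mode. Bins touching masked time are ineligible
and masked time is excluded from the denominator, so a fully masked
epoch drops out of both numerator and denominator. The statistic is
invariant to event order and to splitting events into abutting
sub-events, and is bounded in [0, 100] by construction.

## Statistics layer

* **Two-group comparisons**: two-sided F-ratio variance pre-test at
  α = 0.05 (the analysis software's convention); if rejected, Welch's
  t with Welch–Satterthwaite df, else the pooled Student t. The 95% CI
  of the mean difference uses the same df.
* **Two-way ANOVA** (genotype × frequency, 51 levels → interaction
  df₁ = 50): balanced designs use the classic cell-means
  decomposition; unbalanced designs use Type III sums of squares via
  sum-coded OLS. Degenerate inputs (zero residual and zero effect) are
  reported as F = 0, p = 1.
* **Sidak post hoc**: per frequency level, the genotype mean
  difference is tested on the pooled ANOVA residual;
  `p_adj = 1 − (1 − p_raw)^m` with m the number of frequency levels,
  and the simultaneous 95% CI uses the Sidak-adjusted critical value
  on the residual df (simultaneous, not per-comparison, by default).
* **Grubbs**: single-pass two-sided single-outlier test,
  G = max|x−x̄|/s against the t-based critical value; not iterated.
* **BCa bootstrap** (Gardner–Altman estimation): groups resampled
  independently with replacement (5000 resamples by default); bias
  correction from the bootstrap CDF at the observed statistic,
  acceleration from the delete-one jackknife over both groups; a
  single seeded generator per run makes the interval reproducible.
  Degenerate (constant) resample distributions return a point interval
  with a warning. Null coverage at n = 20/group measures ~94–95%.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes:

* **Background** = sum of five independent band-limited Gaussian noise
  components (4th-order Butterworth per band, zero-phase), scaled so
  the *expected* measured in-band power equals a per-band target
  shaped like the study's band-power tables (WT-like defaults δ 700,
  θ 220, α 100, β 115, γ 60 μV²; the AS condition multiplies δ by 1.7,
  the three-week cortical ratio in the published band table). The
  scale factor is a cached ensemble band gain estimated on a long
  (600 s) fixed-seed reference per (fs, band): it folds in both the
  filter gain and the analysis chain's capture (the ~1-s windows and
  per-segment detrend lose ~30% of δ power relative to time-domain
  variance). Deliberately, components are *not* normalized by their
  realized variance — the sample variance of a band with few
  low-frequency cycles fluctuates strongly, and dividing by it injects
  that fluctuation into every frequency bin as a common factor,
  correlating per-frequency measurements that must be independent for
  the ANOVA to be calibrated.
* **Events**: Poisson onsets; biphasic spikes (60–150 ms) and
  polyspikes of 4–5 alternating half-sine lobes spanning 0.6–1.2 s
  (4–5 lobes guarantee more than two zero crossings on the clean
  template, so every ground-truth event satisfies the printed criteria
  by construction); peaks at 4× the measured background baseline by
  default. Event times are shared across channels (events are
  brain-wide); noise is independent per channel.
* **Artifacts**: 1–5 s bursts of 20–250 Hz noise at 10× the background
  robust scale, at Poisson onsets; events avoid artifact intervals.
* **Neonatal discontinuity**: an exponential-length burst/suppression
  gate (means 3 s/3 s, suppression at 0.2× amplitude) multiplies the
  background, giving the bimodal 1-s-RMS distribution characteristic
  of discontinuous neonatal traces.
* **Cohorts**: n subjects per genotype, each a fresh seeded recording;
  the emitted tables (band powers per subject × channel; per-frequency
  long table) feed the statistics layer directly. Per-subject
  lognormal variation of the band targets is available
  (`subject_sigma`); the default is 0 because any *shared* per-subject
  multiplier violates the per-frequency ANOVA's independence
  assumption (51 pseudo-replicates per subject) and makes the genotype
  F anticonservative — with it off, between-subject variance is the
  finite-recording measurement noise, whose sampled per-frequency
  values are independent, and the test is calibrated (~6% null
  rejection at α = 0.05). Turning `subject_sigma` on reproduces the
  pseudoreplication hazard of analyzing per-frequency tables from
  heterogeneous cohorts — a known limitation of this analysis style on
  real data.

What the generator does **not** emulate: 1/f spectral continuity
across bands (the spectrum has shallow gaps where the printed bands
have gaps), sleep/wake state structure, electrode drift, chewing/EMG
harmonics, true spike-wave complexes or electrographic seizures, and
inter-channel propagation delays. Passing tests therefore demonstrate
correctness of the measurement and inference chain under the assumed
structure, not performance of the detector on real recordings.

## Problem sizes and numerics

Simulation-based checks run at desk scale: cohort calibration/power
simulations use single-channel 60-s recordings at 500 Hz (Δf ≈
0.24 Hz keeps per-frequency values independent, and ~28 Welch segments
keep them near-normal) with the
study's n = 8/group and δ × 1.7 effect; detector recovery uses 30
simulated minutes at 1000 Hz; bootstrap coverage uses 500 simulations
of n = 20/group with 1000 resamples. Effect sizes, detection
thresholds, and the nominal α are never scaled.

EDF output is 16-bit with per-channel symmetric physical ranges
(⌈max |signal|⌉), so round-trip error is bounded by range/2¹⁶;
recordings that are not a whole number of seconds are zero-padded to
the next 1-s record. CSV and annotation TSV round-trips are exact
(shortest round-trip float formatting). All generator outputs are pure
functions of (config, seed); the pipeline report serializes floats at
10 significant digits and records a config hash, seed and version for
provenance.
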