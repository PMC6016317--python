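# Methods

This note documents the models, estimators and design choices behind
`kindleeg`, and what the synthetic-data tests do and do not establish about
real recordings.

## Afterdischarge detection

**Rule.** An afterdischarge (AD) is an interval whose amplitude stays at
least `ratio` (default 2.5) times the baseline RMS for at least
`min_duration` (default 6 s). "Amplitude" is not a standard quantity; we
operationalize it as a **sliding-RMS envelope**: 0.5 s windows with 50 %
overlap. RMS is robust to isolated sample spikes, and 0.5 s is short
relative to the 6 s minimum while long enough to average over individual
spike cycles. Baseline RMS comes from a 7 s pre-stimulation stretch of the
same recording, which makes the detector exactly invariant to common
amplitude rescaling (gain changes).

**Gap bridging.** Spike-train ADs dip below threshold between consecutive
spikes; sub-threshold gaps up to `bridge_gap` (default 0.5 s) inside an
event are bridged before the duration rule is applied. The knob is exposed
because the appropriate value scales inversely with spike rate.

**Boundary localization.** A coarse 0.5 s window straddling an AD edge can
pass the threshold on partial overlap, stretching the measured extent by up
to a window per side and biasing ADD upward by ~0.5 s. Two measures bound
the error: (i) each super-threshold window is credited only the hop-length
interval centred on it, and (ii) event boundaries are refined by re-scanning
the same 0.5 s RMS at 10 ms steps near each coarse edge and placing the
boundary at the first/last passing window **center**. The center convention
makes the residual error approximately independent of how far the AD
amplitude exceeds threshold; empirically the per-event ADD error is within
±0.47 s (mean +0.12 s) across hundreds of simulated events, and the
detector never splits or merges well-separated events.

Events use the half-open convention [onset, onset + duration) in seconds.

**Labeling.** Detected events are matched to stage annotations by maximal
temporal overlap (minimum 1 s by default); ADD is taken from the detected
extent, stage/phase/animal/group from the annotation, and unmatched
detections are flagged and excluded downstream. Only the AD extent enters
spectral analysis; annotated time outside the detected interval is
discarded.

## Spectral analysis

Welch's method: 2 s sub-segments, 50 % overlap, periodic Hann taper, linear
detrend per sub-segment (removes electrode drift), density scaling so the
integrated density equals the signal variance (verified to 1 % as a test
invariant, and against a direct-summation DFT oracle to 1e-9). The 2 s
sub-segment gives 0.5 Hz resolution and five averaged periodograms on a
minimum-length 6 s AD — a deliberate bias/variance compromise; segment
length is a parameter.

**Bands.** delta [1,4), theta [4,8), alpha [8,12), beta [12,28), gamma
[28,40) Hz, half-open edges; aggregates LFB = delta ∪ theta, MFB = alpha,
HFB = beta ∪ gamma. Band power is the rectangle-rule integral of the
density over the half-open interval; fractions are normalized by total
power in [1,40) Hz. Starting the analysis at 1 Hz (rather than 0) excludes
DC offset and slow drift from every total; the scheme is configurable. The
theta/alpha ratio is a power ratio and raises an error (rather than
returning infinity) when alpha power is exactly zero.

**Peaks.** Spectral peaks are local maxima above a prominence threshold
(fraction of the in-range maximum); when computed from a raw segment the
PSD is zero-padded to a grid ≤ 0.05 Hz so peak frequencies are refined
below the native 0.5 Hz resolution. Zero-padding interpolates — it adds no
resolution — which is sufficient for reporting peak positions.

## Statistics

* **Normality**: Kolmogorov–Smirnov with **Lilliefors** critical values,
  because mean and SD are estimated from the tested sample; the plain KS
  test against fixed parameters would be anti-conservative.
* **One-way ANOVA** with Bonferroni-adjusted pairwise post hoc t-tests on
  the pooled within-group mean square (df = N − k), the standard
  Bonferroni-on-ANOVA convention. A summary-statistics form (means, SDs,
  ns) is provided and agrees with the raw-data form to 1e-9.
* **Two-way (group × phase) ANOVA** with **Type-II** sums of squares: the
  designs here are heavily unbalanced (event counts differ by an order of
  magnitude between cells), where Type-II main effects are the conventional
  choice. With an empty cell the additive model is fitted and the
  interaction is flagged as a missing-cell condition rather than silently
  reported.
* **Kruskal–Wallis** H with tie correction (H = 0, not an error, for
  complete ties) and **Pearson** r with the two-sided t-transform p-value;
  at small n the t p-value agrees with a 10⁴-draw permutation null within
  ≈0.03, which is the accuracy the tests assert.

Generalized-stage (GSS) group statistics are computed only when every group
contributes at least `gss_min_events` (default 3) events; below that the
cell is reported descriptively only, because tests on 1–2 highly unbalanced
observations are not meaningful.

## Synthetic kindling EEG

**Baseline** is 1/f^β colored noise (β = 1.5 by default), synthesized in
the frequency domain with complex-Gaussian coefficients for 1 Hz ≤ f ≤
Nyquist and scaled to `baseline_amplitude` RMS (50 µV). β = 1.5 keeps the
low-frequency band (delta–theta) dominant, as in resting rodent depth-EEG;
the mean LFB fraction of generated baselines is ≈ 0.77.

**AD segments** superpose a biphasic spike train (Ricker wavelets, default
5 Hz with 10 % timing jitter and ±20 % amplitude variation) on band-shaped
noise. Synthesis proceeds in three steps:

1. the spike train is generated and its per-band powers measured exactly
   from its FFT; its overall scale is capped so no band's spike power
   exceeds that band's target (at most 35 % of total power);
2. per-aggregate-band noise (1/f density within each band, cosine-tapered
   over the top 0.75 Hz so the analysis window's main lobe does not smear
   band-edge density into the neighbour above) receives the remaining
   per-band power; because the finite Hann/Welch analysis still smears a
   little power across edges, the per-band noise gains are then iterated
   (≤ 4 passes) against the default spectral analysis until the *recovered*
   fractions match the targets — the generator is calibrated closed-loop
   against the same estimator the pipeline uses;
3. the composed segment is uniformly rescaled, if necessary, so its 0.5 s
   sliding-RMS envelope never drops below 1.15 × (2.5 × baseline RMS); a
   uniform rescale preserves all band fractions. The default segment RMS is
   4 × baseline (2.5 × 1.6 headroom).

Per-event spectral variability is modelled by additive Gaussian jitter
(SD 0.03) on the target fraction triple, renormalized. The split between
within-animal and within-event variance is deliberately not asserted —
group-level tables constrain only the per-group event pool — so both the
jitter SD and the per-animal assignment are free parameters.

**Durations** are truncated normal at the per-phase (mean, SD). The
truncation floor is **6.5 s**, half a second above the 6 s detection rule:
with the floor at exactly 6 s, a draw of ~6.05 s can legitimately measure
at 5.9 s (boundary error ≤ 0.35 s) and then fail the minimum-duration rule,
breaking the otherwise-exact round trip between generator and detector.

**Default calibration** (`DEFAULT_PROFILES`). Kindle group: ISS fractions
(0.828, 0.082, 0.088), LSS (0.7091, 0.1323, 0.1557), LSS mean duration
12.4285 s (SD 1.5), GSS mean 22.28 s (SD 2.0), event counts 61/42/35;
LFSK: ISS (0.845, 0.065, 0.081), LSS (0.9124, 0.0451, 0.042), durations
9.373 / 16.9 s, counts 38/13/4; KLFS: ISS (0.851, 0.065, 0.074), LSS
(0.8825, 0.0582, 0.0592), durations 10.064 / 17.82 s, counts 39/14/6.
Printed fraction rows that sum to 0.99–1.00 are renormalized to 1. Two
quantities have no published values and are package choices: **ISS mean
duration** is set to 8.0 s (SD 1.5) for all groups — above the
detectability floor and below every LSS mean, consistent with the monotone
severity→duration pattern — and **GSS fraction targets** are set to
(0.60, 0.15, 0.25) / (0.75, 0.10, 0.15) / (0.72, 0.11, 0.17) for
Kindle/LFSK/KLFS, reflecting the qualitative description of elevated
MFB/HFB at generalization, attenuated under LFS.

**Sessions** lay events out sequentially: a 7 s lead baseline, then each AD
separated by 5 s of baseline. Annotations match the embedded segments
exactly. Sampling rate defaults to 1 kHz — a 12.5× Nyquist margin over the
40 Hz analysis ceiling; 10 kHz acquisition-grade rates are supported but add
nothing to a 0–40 Hz analysis. All generators are pure functions of
(config, profile, schedule, seed).

**Titration** models the AD-threshold staircase: intensities 30, 45, …,
345 µA, one Bernoulli draw per step from a monotone response curve
(deterministic step by default), exclusion if no response by the 350 µA
cap. The paper trail for a response model is empty, so the Bernoulli step
is the simplest monotone choice; a custom probability function can be
supplied.

## What the synthetic tests do and do not show

Passing the closed-loop suite establishes that the detector, the spectral
reduction and the statistics are mutually consistent and correctly
implement their definitions at realistic signal scales — every scheduled AD
recovered, zero false events on 100 seeded baselines, band fractions
recovered within ±0.03 and durations within ±0.5 s of calibration. It does
**not** establish detector performance on real recordings: the generator's
baseline is stationary (no movement artifact, chewing noise or electrode
pops), its ADs have stable within-event spectra and an enforced envelope
floor, and its annotations are exact. Real data will exercise the
gap-bridging and unmatched-event paths far harder than these simulations
do.

## Problem sizes and numerical choices

Default analyses run at 1 kHz with per-cell event counts matching the study
conditions (61/42/35 etc.); validation suites use 50–150 events per cell so
Monte-Carlo error on cell means (SE ≈ SD/√n) is small against the stated
tolerances. Tie-breaks and degenerate inputs are handled explicitly:
constant samples raise degenerate-input errors for normality/correlation,
complete ties give H = 0, identical constant groups give F = 0, zero total
power raises an undefined-fraction error, and zero alpha power raises an
undefined-ratio error. All stochastic tests fix seeds.

## Known limitations

* Single-channel only; no source localization, time–frequency analysis, or
  phase/coherence measures.
* The generator does not model the kindling *process* (no biophysics, no
  day-to-day progression beyond scheduled counts) or LFS pulse waveforms —
  only their statistical consequences on the EEG.
* Behavioural exclusion criteria (deep inhibitory state, unusual responses)
  have no signal-level definition and pass through as annotation flags only.
* Aggregation level for group statistics defaults to per-event; per-animal
  aggregation changes degrees of freedom and is exposed in the config
  rather than decided here.
* EDF writing is not supported (no writer in the dependency set); CSV +
  JSON sidecar is the native format, EDF reading available via `mne`.
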