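# Methods

`voltpipe` analyses fluorescence voltage-imaging movies of cultured
neurons labelled with a fast voltage-sensitive dye that brightens on
depolarization, recorded by a scientific camera at 300–500 Hz with
~2 ms exposure in epochs of about three minutes. This note documents the
models, the estimators, and the design choices made where the procedure
was genuinely open, in the order the pipeline applies them.

## Signal model

A recording is a T×H×W stack of camera counts. Each neuron *n* occupies a
compact spatial footprint *w_n(x)* (peak 1), and its activity is the
percent fluorescence change *s_n(t)* = ΔF/F₀. The expected counts at
pixel *x* and frame *t* are

    F(x, t) = B + β(t) · F₀ · Σ_n w_n(x) · (1 + s_n(t)/100),

with background *B*, baseline brightness *F₀*, and an optional
photobleaching factor β(t) = exp(−t/τ). Shot noise is Poisson in the
expected counts; the camera digitizes to 16 bits. ΔF/F₀ is built from two
components:

- **Action potentials** — an asymmetric lognormal-shaped pulse with rise
  time fixed at 0.25·FWHM (a symmetric Gaussian alternative exists for
  closed-form checks), peak amplitude 10 % ΔF/F₀ per AP by default,
  convolved with the spike train. The amplitude is of the order reported
  for fast red voltage dyes; only the amplitude-to-noise ratio matters
  for the recovery results below.
- **Plateau depolarizations** — soft-edged boxcars (erf edges, 50 ms time
  constant), default amplitude 2.5 % ΔF/F₀, i.e. about a quarter of an AP,
  matching the ratio of a ~25 mV sustained depolarization to a ~100 mV
  AP; default duration ~1 s at 0.5 events/min.

Spike trains are homogeneous Poisson thinned by an absolute refractory
period (5 ms default), or bursting: Poisson burst onsets each emitting
4–8 spikes at 30–150 ms intra-burst intervals plus a residual train of
isolated spikes, with the onset rate derived from the target overall rate
(default: 75 % of spikes inside bursts). Synchronized bursting shares one
onset train across the field of view with per-neuron participation 0.8,
emulating network bursts in dense primary cultures.

### Presets

Cohort presets are parameterized from reported statistics of three
hiPSC-derived lines and of primary rat hippocampal cultures:

| preset  | neurons | firing rate (Hz)   | AP FWHM (ms)            | pattern |
|---------|---------|--------------------|-------------------------|---------|
| WT4     | 24      | lognormal(1.03, 0.50) | 14.8                 | Poisson |
| WT156   | 36      | lognormal(0.6, 0.3)*  | 12.3                 | bursting |
| WT83    | 41      | lognormal(0.23, 0.16) | 12.2                 | Poisson |
| primary | 27      | lognormal(1.0, 0.5)*  | lognormal(10.1, 7.14), ≥ 2 ms | synchronized bursting |

Starred rates are this package's choices (no value is reported for those
cohorts); the others are moment-matched to the reported mean ± SD.
Lognormals are used because rates and widths are positive and skewed, and
because the lognormal reproduces the requested mean and SD *exactly* — a
normal truncated at zero (or at 2 ms for the heterogeneous AP widths)
would inflate the mean by up to 17 %, which would defeat recovery testing
against the reported values. The 2 ms floor on AP width is applied by
resampling and removes ~1 % of the lognormal mass.

All presets run 180 s at 500 Hz over a 200×150 px field of view. Since a
field of view holds at most 12 neurons, larger cohorts are split across
several movies. Per-neuron random streams are spawned from the master
seed with fixed keys, so adding a neuron never perturbs existing ones,
and identical configurations render bit-identical movies.

### Desk scaling

`SimConfig.scaled(f)` shrinks the FOV and soma radii by *f* (radii floored
at 2 px) **and multiplies the per-pixel baseline counts by 1/f²**. A
scaled movie is the same preparation imaged onto fewer pixels: the photon
budget per neuron — and hence the shot-noise level of an extracted soma
trace — is preserved. Without this, quarter-scale movies would carry 4×
the trace noise of the instrument being emulated and detection behaviour
would not transfer. Shot noise is drawn as exact Poisson below 30
expected counts and as a Gaussian of matching mean and variance above
(skew < 0.2 there), which is statistically indistinguishable at camera
count levels and considerably faster.

### What the generator does not model

No optics (point-spread function, oblique-illumination geometry), no
motion, no flat-field inhomogeneity, no dye internalization, no Ca²⁺
channel. Footprints are smooth super-Gaussian discs, not morphological
reconstructions; neuropil fluorescence is absent. Passing recovery tests
therefore demonstrates the correctness of the analysis chain under the
stated noise model, not robustness to optical artefacts in real
recordings.

## Denoising and ΔF/F₀

Movies are smoothed with a spatial Gaussian (σ = 1 px) and a centred
3-frame moving average (6 ms at 500 Hz, kept short so AP width bias from
smoothing stays below ~5 %; reflection padding at the edges). In the
pipeline the temporal average is applied to the *extracted trace* rather
than to every pixel — the two commute with the mask mean — and waveform
metrics are measured on traces **without** temporal smoothing so that the
moving average cannot broaden the APs it reports on.

Baseline F₀ is the 20th percentile of the raw trace in a sliding 10 s
window (evaluated on a 1 s anchor grid and interpolated, edges clamped to
the nearest full window), so sparse positive spikes do not inflate the
baseline while drift far slower than any AP is tracked. A global
percentile and a global mean are available for short synthetic segments.
ΔF/F₀ = 100·(F−F₀)/F₀ is scale-invariant by construction. An optional
monoexponential-plus-offset detrend exists for recordings with visible
photobleaching; it is off by default because the emulated regime shows
virtually none.

## Segmentation (PCA/ICA)

Pixel time courses are mean-subtracted and reduced by PCA
(3 × expected neuron count components, capped at 60; randomized solver
for large movies). The **signal subspace** is then selected as the
components whose explained variance exceeds twice the median eigenvalue
of the retained spectrum — the median estimates the flat noise floor, and
rotating noise components together with signal is what splits one neuron
across several independent components. ICA (FastICA, cube nonlinearity)
rotates only that subspace, operating on the concatenation of
variance-normalized temporal scores (weight μ) and unit-norm spatial
eigenimages (weight 1−μ), μ = 0.5 by default, i.e. independence is judged
jointly in space and time. The concatenated factors are orthonormal up to
a common scale, so the rotation is well-posed.

Each component is sign-flipped so its temporal skewness is positive
(spikes are positive-going), and components are sorted by spatial-filter
skewness. Masks are the largest connected component of
`filter ≥ 0.5·max(filter)`. Components with temporal skewness below 0.2
are discarded (spiking traces are strongly right-skewed; noise is not),
and masks overlapping a better component at Jaccard > 0.5 are treated as
duplicates. Traces are extracted as the filter-weighted mean over mask
pixels; the weighting visibly reduces cross-contamination between
overlapping somas relative to a plain mask mean.

## Spike detection (NEO)

Detection uses the nonlinear energy operator
ψ(t) = s(t)² − s(t−1)·s(t+1), computed exactly (no smoothing inside the
operator). Candidates are local maxima of ψ (leftmost sample of plateaus)
at or above 3 standard deviations of ψ; the SD is taken as the RMS about
zero over the full epoch, since ψ of noise is near-zero-mean. Candidate
times are moved to the trace's local maximum within ±2 frames and
candidates closer than 20 ms are resolved greedily by descending NEO
score, which removes double counts of one AP.

One amendment to the bare operator proved necessary: on an elevated
baseline *B* (a plateau), ψ of *B + noise* contains a
*B·(second difference of noise)* term that scales with the plateau height
and floods the threshold precisely in sparsely firing cells, where spikes
do not inflate the epoch SD. The detection trace is therefore high-pass
filtered (zero-phase Butterworth, 5 Hz, well below the ~10–100 Hz AP
band) before the NEO; waveform metrics still come from the unfiltered
ΔF/F₀. The filter is exposed as a config option (`highpass_hz=None`
restores the bare operator). With it, spike F1 against ground truth
exceeds 0.95 on every preset at default SNR, including the 0.23 Hz
cohort.

The 3·SD rule is only self-consistent when spikes contribute to the SD:
on pure noise, ~1–2 % of samples host suprathreshold ψ maxima regardless
of the noise level (the threshold is relative), so detection on traces
with essentially no spikes will report noise. This is a property of the
thresholding rule, not of the implementation; the tests pin the
false-positive rate against a direct Monte-Carlo of the operator rather
than against a Gaussian tail bound, which ψ does not obey.

## AP waveforms

For each detected spike a 300 ms window (151 samples at 500 Hz) centred
on the trace peak is cut; spikes closer than half a window to an edge are
excluded and counted. Alignment is integer-shift only. The local baseline
is the median of the first and last 50 ms of the window; FWHM is the
distance between the half-maximum crossings found by linear
interpolation, searching outward from the peak — with the peak search
anchored within ±2 frames of the aligned centre, so that a larger
neighbouring spike inside the window (doublets, bursts) cannot hijack the
measurement. Windows containing another detected spike are flagged
`overlap` but retained by default; waveforms whose half-max crossing is
missing are flagged and excluded from summaries. Amplitude, 10–90 % rise
and 90–10 % decay use the same interpolation.

At the default noise level the per-spike FWHM estimator carries a small
negative bias (≲ 3 % at 14.8 ms): noise inflates the apparent peak, which
raises the half-max level. Severely undersampled kernels (FWHM ≲ 2 frame
periods) are conversely overestimated by the linear interpolation. Both
effects are documented by the recovery tests; per-neuron mean waveforms
(also provided) largely average the first effect away.

## Events and firing statistics

A **burst** is four or more APs whose mean inter-spike interval is below
250 ms. The detector scans left to right: a burst seed is four
consecutive spikes meeting the bound, extended one spike at a time while
the running mean ISI stays below it; the scan resumes after the run. This
greedy rule is verified against an exhaustive enumeration oracle on
random trains. Remaining spikes are grouped by the same 250 ms gap
(provided no burst intervenes) into singlets, doublets and triplets, so
the taxonomy is a single partition of the spike train; a leftover group
of ≥ 4 is impossible for consistent inputs and raises.

**Plateaus** are detected on the ΔF/F₀ trace by excising detected APs
(−20/+80 ms, bridged by linear interpolation — the AP decay tail is
itself a slow signal), taking a rolling median (80 ms) and a zero-phase
5 Hz low-pass, and thresholding at 3× a MAD-based noise floor **or**
0.5 % ΔF/F₀, whichever is larger, for at least 200 ms. The absolute floor
exists because in very clean traces the statistical floor goes to zero
and sub-0.1 % drifts — biologically meaningless — would otherwise
qualify. An event is `on_plateau` if its median spike time falls inside a
plateau interval.

Instantaneous firing rate is operationalized as spike count divided by
recording duration (a mean of 1/ISI diverges for Poisson-like trains);
bursting rate is bursts per minute; burst duration is first-to-last spike
of the run; inter-burst intervals are measured onset-to-onset.

## Group statistics and scoring

Cohorts are compared with an unpaired two-tailed Student's t test (pooled
variance; Welch by flag), reported as mean ± SD with the usual
significance tiers (*p < 0.05, **p < 0.01, ***p < 0.001). No
multiple-testing correction is applied, and the report says so. Spike
detection is scored by greedy nearest-neighbour one-to-one matching
within ±6 ms (3 frames at 500 Hz); recovered ROIs are matched to
ground-truth masks by Jaccard overlap, greedily, one-to-one.

## Problem sizes used in validation

The recovery tests and the acceptance script run the presets at FOV scale
0.25 (50×38 px, with the photon budget preserved as above), full 180 s
epochs, all neurons — cohorts split across movies of ≤ 12 neurons. The
acceptance script pools 4–5 independently seeded cohort replicates per
preset so that the reported cohort means estimate the preset's population
mean (the single-cohort sampling SE of the heterogeneous AP-width preset
is 1.4 ms, i.e. 14 % of the mean, irreducible at n = 27 neurons). Unit
tests use smaller fields of view and shorter epochs chosen only for
speed; no analysis parameter differs between test and full-scale
configurations.

## Known limitations

- The ICA needs the expected neuron count as an upper bound for the PCA
  rank; badly overestimating it is harmless (the spectrum threshold
  prunes noise), but the threshold assumes a roughly flat noise spectrum,
  which strong structured background would violate.
- Activity-based segmentation cannot find silent neurons.
- The NEO threshold is relative; epochs with essentially no true spikes
  yield noise detections (see above). A minimum absolute ψ threshold
  would require amplitude calibration that recorded data may not offer.
- Overlapping somas are separated but not demixed pixel-wise; with heavy
  overlap (Jaccard ≳ 0.5) the duplicate filter may merge them.
- Plateau detection assumes plateaus are rarer and slower than APs;
  dense bursting on top of plateaus shortens the usable baseline and can
  shift interval edges.
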