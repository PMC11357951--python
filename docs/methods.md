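# Methods

This note documents the models, estimators, numerical choices and known
limitations of `fatiguelfp`. It is the package's own account of its
science; every empirical statement here is something the test suite or
`scripts/acceptance.py` computes.

## Session model

A session consists of two simultaneously recorded sites, M1 (primary
motor cortex) and CA1 (hippocampus), each carrying a low-frequency LFP
channel and multi-unit spike trains. The session timeline is a
pre-exercise baseline followed by ten minutes post-exercise, analysed as
six 2-minute epochs labelled `pre, post_0_2, post_2_4, post_4_6,
post_6_8, post_8_10`. Epoch windows are half-open `[start, end)`: a
sample or spike on a boundary belongs to the later epoch. When a
continuous recording is supplied, the pre epoch is the *last* 2 minutes
of the pre segment and the post segment is tiled with consecutive 2-min
windows; a trailing remainder shorter than one epoch is dropped with a
warning.

## LFP conditioning

Raw broadband data (10 kHz) are decimated to 500 Hz behind an 8th-order
Butterworth anti-aliasing low-pass at 0.8× the target Nyquist, demeaned,
clipped symmetrically at 8× the robust per-channel scale
(median(|x|)/0.6745, i.e. a Gaussian-consistent MAD), notched at 50 Hz
(2nd-order IIR, Q = 30) and band-passed 1.3–80 Hz with a 2nd-order
Butterworth. Already-decimated 500 Hz input skips the decimation stage.

All filtering is zero-phase (forward–backward) by default. This is a
deliberate choice: inter-site coherence and spike/LFP lag estimates must
not be corrupted by filter group delay. The cost is that each stage's
magnitude response is squared, so the stated filter orders are per-pass
orders. One visible consequence: the soft skirts of the squared
2nd-order 1.3–80 Hz band-pass attenuate the upper gamma range
appreciably (power gain ≈ 0.6 at 60 Hz, ≈ 0.3 at 75 Hz), which biases
the *estimated* spectral centroid a few Hz below the centroid of the
underlying signal (about 33 Hz measured for a planted 40 Hz centroid).
The bias is common to every epoch and cancels in all pre/post contrasts.

## Spectral estimators

All spectral quantities share one Welch configuration: Hann window, 50 %
overlap, segment length `round(fs / resolution)` samples, density
scaling. The default resolution 0.39 Hz gives 1282-sample segments at
500 Hz and K ≈ 92 averaged segments per 2-min epoch.

* **Band powers** integrate `psd × Δf` over bins whose centres fall in
  the half-open band, normalised by the total over the union of the
  scheme's bands (delta 1.5–4, theta 4–10, alpha 10–13, beta 13–30,
  gamma 30–80 Hz), so fractions sum to exactly 1. The 1.3–1.5 Hz sliver
  below the scheme is excluded from the normalisation.
* **Magnitude-squared coherence** uses the same windowing in numerator
  and denominator and is clamped to [0, 1] against round-off. A single
  averaged segment (MSC identically 1) is rejected. The estimator's
  small-sample bias for independent signals is 1/K; tests check the
  measured mean against that value.
* **Gravity frequency** is the PSD-weighted mean frequency over
  1.3–80 Hz (closed range on the bin centres); it is scale-invariant
  and always lies within the integration limits.
* **Power spectral entropy** is the Shannon entropy of the in-range PSD
  normalised to a probability vector, divided by log(bin count). Natural
  logarithms; the normalisation makes the value base-independent, 0 for
  a point mass, 1 for a flat spectrum. Zero in-range power makes GF and
  PSE undefined and raises.

## Spike path

Multi-unit activity is extracted with a zero-phase 2nd-order Butterworth
high-pass at 500 Hz followed by anti-aliased resampling to 2 kHz.
Detection finds negative crossings of −k·σ̂ with σ̂ the MAD-based noise
scale and k = 4.5 by default, aligns each event to the local trough,
enforces a 1 ms refractory lockout and cuts snippets 0.6 ms before to
1.0 ms after the trough. Events whose snippet would leave the recording
are dropped. Detection counts are monotone non-increasing in k.

Sorting projects snippets onto 3 principal components and partitions
them with k-means over k = 2..4, choosing k by silhouette score; if the
best silhouette is below 0.5 (one apparent template) a single cluster is
reported. k-means is seeded from the master seed, so labels are stable.
Sorting operates per channel, consistent with multi-unit electrodes.

Firing rate is spike count over epoch length per (unit, epoch); summing
`rate × duration` over epochs reproduces the total count exactly.

## Poisson-surprise bursts

For a unit with n spikes in an epoch of duration D, the baseline rate is
r = n/D and the seed criterion asks for three consecutive spikes whose
first two inter-spike intervals are each below half the epoch mean ISI.
The surprise of a window holding m spikes over span T (first to last
spike) is

    S = −ln P(N ≥ m),   N ~ Poisson(r·T).

Numerics: the tail is evaluated through the regularised incomplete gamma
identity `P(N ≥ m) = gammainc(m, rT)`; where that underflows (S beyond
~700 nats) a log-space series of the leading tail term takes over, so S
is accurate (1e-9 relative against an arbitrary-precision oracle in the
tests) arbitrarily deep into the tail. The log base is natural and
configurable.

Maximisation: each maximal run of consecutive sub-half-mean ISIs seeds a
search over *all* windows containing one of the run's qualifying ISI
pairs, bounded at 150 spikes of extension per side — this is extension
and trimming with unlimited lookahead, implemented exactly rather than
one step at a time, because one-step greedy extension stalls on local
maxima of S. Background seeds are first screened with a 12-spike
lookahead and discarded if even their best local window stays below the
retention threshold; on trains of ≤ 60 spikes the full search always
runs, so the screening cannot affect the small-train regime where the
exhaustive-oracle tests operate. Overlapping candidates are resolved by
a lazy greedy pass: the highest-surprise window is retained, and any
colliding candidate is re-optimised within the remaining free spikes.
Retained bursts satisfy S > 10, are non-overlapping and time-ordered,
and each contains a qualifying seed pair.

Degenerate inputs: fewer than three epoch spikes, or no qualifying seed
(e.g. a perfectly regular train), yield an empty burst list, not an
error. Note one boundary consequence of the seed criterion: a tiny train
that is itself one dense cluster can never contain a burst, because its
own ISIs define the mean ISI of the criterion.

Summaries per (region, epoch): burst count, normalised burst rate
(fraction of all spikes falling inside bursts), mean spikes per burst,
mean burst duration, and the fraction of units with at least one burst.
Means are reported missing (NaN) when an epoch has no bursts.

## Cross-correlograms

The correlogram histograms all target-minus-reference spike-time
differences within ±50 ms into 1 ms bins centred on 0, via a two-pointer
scan (O(n + pairs)). With M1 as reference, positive lag means CA1 fires
later. The peak lag is the maximum bin (optional boxcar smoothing), ties
broken toward the smallest |lag|. The flatness flag compares the peak
against the independent-Poisson chance level μ = n_ref · r_tgt · Δ plus
z·√μ, where z is the normal quantile Bonferroni-corrected over the
number of bins at family level 0.01 (z ≈ 3.7 for 101 bins). A plain
3√μ rule would flag a genuinely flat correlogram "non-flat" in roughly
one run in eight, because the peak is a maximum over ~100 bins.

## Synthetic sessions: what is emulated, and how

The generator's defaults are the study conditions; every estimated
quantity has a planted counterpart.

**LFP.** Each band is realised as Gaussian noise exactly confined to the
band by Fourier-domain (brick-wall) shaping of white noise, rescaled to
unit variance, then mixed across the two sites and scaled so band
variances equal the planted power fractions × (100 µV RMS)². Brick-wall
confinement is used for synthesis (the analysis filters remain
Butterworth) because time-domain 2nd-order band filters leak ~20 % of a
narrow band's power into its neighbours, which would defeat
fraction-level calibration of the planted spectrum.

**Coherence planting.** For a per-band target c, each site receives
`c^(1/4) · shared + sqrt(1 − sqrt(c)) · independent`. The mixing weight
is c^(1/4), not sqrt(c): with weight a on the shared component the
asymptotic MSC is |a²|² = a⁴, so a = c^(1/4) yields MSC = c. Simulation
recovers targets {0, 0.4, 0.7, 1.0} within ±0.02 at 120 s.

**Spectral profile.** Within-band spectra are flat; across bands the
default fractions follow a 1/f^α profile with α = 0.05, chosen so the
planted spectral centroid over 1.3–80 Hz sits at ≈ 40 Hz, the reported
pre-exercise gravity frequency at both sites. A steeper, textbook 1/f
profile (α = 1) would plant a centroid near 21 Hz, far from the value
the generator is supposed to embody; the near-flat profile is what the
reported centroid actually implies. The fractions remain configurable.

**Spikes.** M1 units are Poisson backgrounds with superimposed burst
episodes (episode starts Poisson at 8.5/min, spike count per episode
Poisson with mean 71.81, intra-burst ISIs exponential at 300 Hz). The
background rate is the planted unit rate *minus* the expected burst
spike rate, so the realised total rate calibrates to the planted
29.86 Hz — and the planted burst spike fraction is 10.17/29.86 ≈ 0.34.
Each M1 spike is relayed to the paired CA1 unit with probability 0.10,
delayed by the planted 3.5 ms lag plus 0.5 ms Gaussian jitter; CA1 units
add their own burst episodes (6.75/min, mean 78.16 spikes) and Poisson
background so their total rate matches the planted 25.84 Hz. The relay
probability is kept at 0.10 so that a thinned relayed episode (~7
spikes over ~0.24 s) scores S ≈ 1, far below the burst threshold, and
CA1's burst statistics stay those of its own planted episodes, while the
relayed stream still produces a many-sigma correlogram peak at the lag.

**Burst duration is emergent, not planted.** The in-vivo triplet
(71.81 spikes/burst, 6.06 s duration, 29.86 Hz unit rate) is not jointly
realisable under a surprise-based detector: 71.81 spikes over 6.06 s is
an 11.9 Hz episode, *below* the 29.86 Hz baseline, which can never reach
S > 10. The generator keeps the rate, spikes-per-burst and burst spike
fraction and lets duration follow from the 300 Hz intra-burst rate
(≈ 0.24–0.28 s measured). Reported burst durations therefore do not
match the in-vivo 6.06 s, and the detector's spikes-in-burst runs a few
percent above the planted mean because background spikes inside the
burst span are counted.

**Fatigue phases.** Per-phase multiplicative factors apply to band
fractions (before renormalisation), coherence targets, unit rates, the
lag, burst episode rate and spikes per burst. Post-exercise defaults
encode the observed directions — delta/theta ×1.35→×1.10,
alpha ×1.20→×1.05, beta ×0.75→×0.92, gamma ×0.70→×0.90, coherence and
rate ×0.70→×0.90, lag ×1.60→×1.15, burst size ×0.70→×0.90 — interpolated
linearly across the five post epochs (monotone partial recovery, never
reaching baseline within the session). The gravity-frequency drop is
emergent from the band shifts.

**Determinism.** One master seed; every (phase, band, channel, unit)
draws from an independent CRC-hashed substream, so outputs are
bit-reproducible and changing one component does not perturb the others.

**What the generator does not emulate.** No biophysics (conductance,
spike-frequency adaptation), no behaviour or treadmill dynamics, no
electrode drift, movement or cardiac artifacts beyond white noise, no
within-band spectral structure (oscillatory peaks), no cross-frequency
coupling, and no unit turnover across epochs (units persist; the in-vivo
analysis re-identified units per epoch). Passing recovery tests on this
data therefore demonstrates estimator correctness and calibration, not
robustness to real-world artifacts.

## Problem sizes in the test suite

Unit and calibration tests run on 2-min (or shorter) single phases at
the default rates; the end-to-end fatigue-direction test averages ten
replicate sessions generated at 60 s per phase with two units per
region, sizes at which every planted contrast exceeds its estimator
noise by a comfortable margin while the whole suite stays fast. The
acceptance script uses three full 120 s replicate sessions. Monotone-
recovery checks are noise-aware: they require the overall recovery to be
significant and no adjacent-epoch step to contradict the trend beyond
two standard errors, which is the sharpest statement ten replicates
support.

## Known limitations

* The estimated gravity frequency inherits the zero-phase band-pass
  attenuation bias described above (≈ −7 Hz at a planted 40 Hz
  centroid); cross-epoch contrasts are unaffected.
* Spike sorting at the 2 kHz multi-unit rate has only 3–4 samples per
  snippet; sorting accuracy claims in the tests are made at the 10 kHz
  broadband rate. The default pipeline therefore analyses planted spike
  trains directly and treats full broadband detection/sorting as an
  optional path (`use_broadband`).
* Group-level statistics across animals (normality tests, ANOVA
  families, post-hoc corrections) are out of scope; standard statistical
  packages handle pooled session results.
* The Poisson-surprise search is exact only within its 150-spike
  extension cap; bursts longer than that would be truncated (none occur
  under the study conditions).
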