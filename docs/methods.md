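# Methods

This note documents the models, parameters and numerical choices behind
`wingbeat`, and what the synthetic test scenes do and do not establish
about real recordings.

## The detection model

The extraction pipeline assumes raw recordings are *mostly silent*: a
stationary noise floor (amplifier hiss plus low-frequency ambient leakage
through the enclosure walls) with sparse, louder insect events. Under that
assumption a relative energy threshold — 1.6 times the mean windowed
energy of the whole file — separates events from floor: the mean is
dominated by floor windows, so events stand well above it, while a
recording containing nothing exceeds 1.6× its own mean nowhere, by
construction. The threshold is computed per input file, whatever its
duration; this generalizes the original per-session rule (fixed-length
acquisition files) without changing it for files of that length.

The prefilter (low-pass 1500 Hz order 4, high-pass 180 Hz order 30) exists
only to drive detection: its passband brackets the harmonics of insect
wingbeat sounds (fundamentals roughly 77–180 Hz, bounded above by the
~1 kHz neuromuscular limit of asynchronous flight muscle) while the very
steep high-pass rejects the low-frequency environmental noise that
enclosures attenuate least. Clips are always cut from the *unfiltered*
resampled signal; the filter never touches the published audio.

Filtering is causal forward-only, not zero-phase. The original procedure
does not specify bidirectional filtering, a causal contract matches
eventual streaming use, and the choice affects which windows sit just
above threshold, so it is fixed and documented for reproducibility. The
prefilter applies low-pass then high-pass; for LTI cascades the order only
matters at rounding level, and it is fixed for bit-reproducibility.

### Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `target_rate_hz` | 16000 | clip sample rate; resolves content to 8 kHz |
| `lp_cutoff_hz`, `lp_order` | 1500 Hz, 4 | detection low-pass |
| `hp_cutoff_hz`, `hp_order` | 180 Hz, 30 | detection high-pass |
| `window_len`, `hop` | 3279, 1024 samples | energy windowing at 16 kHz (~205 ms / 64 ms) |
| `threshold_factor` | 1.6 | activity threshold vs mean window energy |
| `clip_ms` | 2500 | clip length (40 000 samples at 16 kHz) |
| `min_isolated_ms` | 1000 | shorter isolated activity is discarded |
| `neighbor_range_ms` | 2500 | neighbourhood that rescues short activity |

Activity requires energy *strictly greater* than the threshold (makes the
constant-signal case unambiguous). Activity windows are merged into
intervals *before* the isolation pruning; merging first is one consistent
reading of an under-specified ordering and is the more conservative one
(merged activity is harder to discard).

### Segmentation

"Cover all activity with non-overlapping equal-length clips" admits many
placements; the implementation fixes a deterministic greedy rule: walk
intervals left to right, open a clip window at the start of the first
uncovered interval (shifted left if it would overrun the file end),
consume every interval the window fully covers; an interval running past
the window's end makes the next clip start exactly at that end, so long
activity is covered back-to-back. This satisfies all stated constraints —
non-overlap, fixed length, every clip contains activity, every activity is
clipped — and is reproducible. Recordings shorter than one clip yield zero
clips with a warning; events at the file boundary are covered by shifting
the window left.

## The level statistic

One number per clip: per channel, subtract the mean (offset correction)
and apply a 50 Hz 4th-order Butterworth high-pass; pool the per-channel
mean squares by averaging; report `10*log10(pooled/ref^2)`. Pooling mean
squares — rather than averaging per-channel dB values — is chosen because
it keeps the statistic exactly homogeneous: scaling all samples by `a`
shifts the level by exactly `20*log10(a)`. Offset correction before the
high-pass is immaterial for the result (the high-pass removes DC) and
fixed for reproducibility. The default reference is digital full scale
(dBFS); absolute SPL re 20 µPa needs the recording chain's Pa-per-unit
calibration and is only meaningful for data recorded with that chain.

## Date-disjoint splitting

Powerful classifiers can identify the *recording session* from cues
imperceptible to humans and infer the label from it; the defence is to
keep recording dates disjoint across train/validation/test within each
species. Assignment is greedy, largest date-group first (ties shuffled by
the seed), each group to the split with the largest remaining clip-count
deficit against targets of 70/15/15 by default. Exhaustive optimization is
rejected for scale; on random manifests with ≤ 8 dates the greedy L1
imbalance is within one date-group of the exhaustive optimum (verified in
the test suite). Species with fewer than three distinct dates go entirely
to train with a warning — no meaningful disjoint split exists. Splitting by
individual insect is *not* offered: individuals are typically not
documented in such datasets, which is a stated limitation of the data, not
of the splitter.

## Enclosure attenuation

Sweep segments per scenario are transformed (one-sided FFT magnitude per
segment and channel), averaged *in the linear magnitude domain*, converted
to dB and smoothed with a centered 51-point moving average whose window
shrinks symmetrically at the edges. Linear-domain averaging is the
standard spectral estimator and commutes with constructed attenuation
steps, which is what the identity tests exploit. Attenuation is the dB
difference against the open reference; loudspeaker and room response
cancel, so only relative absorption is measurable. Where the enclosure
blocks the stimulus entirely the curve shows the measurement chain's noise
floor; `noise_floor_db` reports the median level of the flattest decile of
bins (flatness = rolling variance over 51 bins) rather than correcting for
it. FFT length, windowing (none) and the dB floor ε = 1e-12 of full scale
are concrete choices; comparisons are only valid between spectra computed
with the same settings.

## Resampling

Polyphase with a Kaiser-window FIR (85 dB stopband, ~125 Hz transition,
−6 dB point half a transition below the output Nyquist). The narrow
transition is required by the toolkit's own contract — content at 7.9 kHz
must survive 48 kHz → 16 kHz resampling while 8.1 kHz content is
suppressed ≥ 40 dB (it would alias) — which a short general-purpose
default filter cannot meet. Output length is `round(n * ratio)` exactly.

## The synthetic scene generator

Scenes emulate the structure that matters to the pipeline, with defaults
chosen to represent the recording conditions the toolkit targets:

- **events**: harmonic stacks, fundamental drawn from 77–180 Hz (the
  wingbeat range of the target species), 1/k harmonic decay, seeded random
  phases, Tukey(0.1) onset/offset taper; default duration 1.5 s so the 1 s
  pruning rule never silently removes ground truth;
- **noise floor**: −60 dBFS RMS pink noise by default (everyday ambient
  noise is approximately 1/f; amplifier hiss is available as white),
  synthesized by spectral shaping with random phase;
- **geometry**: each event is mixed into all four channels of the 55 mm
  star array with 1/distance amplitude decay and the geometric propagation
  delay, applied as a frequency-domain fractional-sample phase shift
  (array delays at 48 kHz span only a few samples, so nearest-sample
  rounding would distort the inter-channel structure);
- **SNR**: stated in the detection band (180–1500 Hz) as event RMS at the
  nearest microphone over noise RMS, calibrated per event; fixture scenes
  use 20 dB, events ≥ 1.2 s, separations ≥ 6 s.

Scenes are fully deterministic under a fixed seed. What passing tests on
these scenes shows: the pipeline recovers well-separated, in-band events
at moderate SNR with high recall and precision, and its bookkeeping
(offsets, lengths, non-overlap, unfiltered output) is exact. What they do
not show: behaviour on reverberant or non-stationary backgrounds,
overlapping or marginal-SNR events, non-harmonic sounds (footsteps,
scratching), or microphone/channel asymmetries — real-data performance
claims need real data.

## Problem sizes in the test suite

The end-to-end recovery tests use two seeded 5-minute, 4-channel, 48 kHz
scenes (5 and 12 events); unit tests use 30–60 s scenes. Split validity is
checked on 1000 random manifests, and greedy balance against exhaustive
enumeration up to 8 date groups. These sizes exercise every code path at
full parameter defaults while keeping the suite runnable on a laptop.

## Known limitations

- The raw-input boundary is WAVE; vendor acquisition formats (e.g. TDMS)
  must be converted upstream.
- The energy threshold is file-relative: a file consisting *entirely* of
  continuous insect sound would raise its own mean and suppress detection;
  the method presumes mostly-silent sessions.
- Only the single loudest channel drives detection; an event audible only
  on another channel can be missed. This mirrors the production method and
  its computational rationale.
- The outer-pair/radius design-band formula encodes the mixed-spacing
  reading of the star array (lower bound from the 95.26 mm outer spacing,
  upper bound from the 55 mm radius); it is a design heuristic, not a
  beamformer implementation.
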