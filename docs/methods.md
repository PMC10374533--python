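# Methods

## The monitoring problem

River dolphins (boto and tucuxi) produce broadband echolocation clicks
quasi-continuously. In the seasonally flooded *várzea* forests of the Amazon,
boat-based visual surveys cannot reach most of the habitat, so long-term
hydrophone deployments (passive acoustic monitoring) are the practical way to
track presence. The soundscape mixes the target clicks with boat engine
cavitation, rain, and a dense bed of stationary insect-like tones; the task
is multi-label classification of 5-s audio segments into any subset of
{click, boat, rain}, followed by ecological aggregation of the per-segment
decisions. The two dolphin species are not discriminated: no click-based
method exists for separating them, so "click" means either species.

## Signal chain

1. **Ingestion** (`audio_io`). Recorders run at 96, 128, 192 or 512 kHz.
   Everything is brought to a common 96 kHz working rate by low-pass
   filtering and polyphase rational resampling (`scipy.signal.resample_poly`
   with ratios 1, 3/4, 1/2, 3/16). Plain decimation cannot produce 96 kHz
   from 128 or 512 kHz, so rational resampling is used for every rate;
   192 kHz reduces to decimation by two as a special case. Upsampling is
   refused. Recordings are cut into contiguous non-overlapping 5-s segments
   (480,000 samples); a trailing remainder is dropped rather than padded
   because the classifier contract is a fixed-length input and padded
   segments would distort class statistics.

2. **Front-end** (`features`). Each segment is Fourier transformed with a
   2048-sample Hamming window and 1112 samples of overlap (hop 936),
   giving 511 frames of a one-sided spectrum with 1024 bins spanning
   DC-48 kHz (DC kept, Nyquist dropped). Power is log10-transformed with a
   floor of 1e-12 relative to full-scale power, projected onto 128
   triangular Mel bands (HTK mel scale, fmin 0, fmax 48 kHz, unit-peak
   triangles by default; Slaney scale and area normalization are config
   switches), right-padded by one floor-valued frame to exactly 512 frames,
   and finally equalized over time: each Mel band's median over the 512
   frames is subtracted. Equalization cancels any time-constant additive
   component of the log spectrum — stationary insect tones, recorder
   self-noise — while transients (clicks, rain drops, engine throb) are
   preserved. The classifier input is therefore a 512 x 128 matrix whose
   per-band medians are exactly zero.

   The 511→512 padding is applied to the PSD before Mel projection, so the
   pad frame is processed like any real frame and a silent segment maps to
   a constant matrix.

3. **Classifier** (`cnn`). Five identical 2-D blocks — batch norm, 3x3
   convolution, ReLU, batch norm, 3x3 convolution, ReLU, 2x2 max pool —
   with filter counts 32, 64, 96, 128, 160. "Same" padding is required:
   five 2x2 poolings must take 512x128 to 16x4 exactly. The 16x4x160 map is
   reshaped to a 16-step sequence of 640 features and passed through two
   kernel-size-1 1-D convolutions (256 filters, batch norm + ReLU) and a
   final kernel-size-1 convolution with sigmoid activation, producing 16
   scores per class per segment (one per 5/16-s column). Training minimizes
   binary cross-entropy summed over columns, classes and batch with Adam
   (lr 1e-3, default betas); targets are column-resolved when bounding-box
   times are available and broadcast to all 16 columns otherwise.

   The network is implemented directly on NumPy (float32) with explicit
   backward passes. Convolutions use cache-blocked im2col GEMMs (the column
   buffer is sized to stay L2-resident), batch normalization uses fused
   single-pass sufficient statistics, and max-pool backward routes
   gradients by value equality — exact float ties share the gradient, which
   is harmless because tied rectified zeros are clamped by the preceding
   ReLU's backward mask. Given a seed, initialization, shuffling,
   augmentation and hence the trained weights are deterministic on a given
   BLAS build.

4. **Scoring** (`evaluation`). The 16 per-class scores of a segment are
   pooled into Q75: the mean of the values between the 75th and 100th
   percentile, i.e. the top 4 of 16 (boundary included; the fraction is
   configurable). Target sounds repeat within a segment, so averaging
   several high columns suppresses single-column spurious peaks.
   Precision-recall curves enumerate the ascending unique scores with
   predicted-positive defined as score >= threshold (the closed-bound
   convention used everywhere in the package), closed with the boundary
   terms TPR(T) = 0, PPV(T) = 1. Average precision is the step sum
   `AP = sum_t [TPR(t) - TPR(t+1)] PPV(t)`; micro mAP pools all classes'
   decisions into one curve before computing AP, which accounts for class
   imbalance. The operating threshold per class is the curve point where
   precision equals recall (minimum |PPV - TPR|, ties toward the higher
   threshold, located on the raw curve without interpolation). Spot
   validation draws 60 segments stratified 30/30 between predicted
   positives and negatives and reports TPR = TP/(TP+FN), TNR = TN/(TN+FP)
   on the sample; the stratification is config-exposed.

5. **Detection** (`detection`). Per-site, per-class thresholds (a YAML
   table) turn Q75 scores into flags. Because low-SNR clicks are confused
   with rain — and the classifier is more reliable on rain than on clicks —
   a posterior rain filter re-attributes any segment exceeding both the
   click threshold and the site's rain-filter threshold: the click flag is
   cleared and the segment marked rain-attributed. Boat flags are never
   touched; extending the filter to boat is a config option. The active
   learning loop samples positively classified segments above a threshold
   uniformly at random (seeded), exports WAV snippets and spectrogram
   images for manual verdicts, and merges verdicts back into the training
   manifest (duplicates by segment id rejected, so a double merge is a
   no-op).

6. **Ecology** (`ecology`). Daily acoustic presence is the daily duration
   with acoustic occurrences (5 s per positive segment; segments are
   non-overlapping so no merging window is applied) divided by the daily
   recording duration — a proportion, which makes sites with different
   duty cycles comparable. A 5-s segment belongs to the calendar minute
   containing its start time; under a 1-min-on/9-min-off duty cycle with
   saturated detections this yields exactly 6 positive minutes per hour.
   Dolphin-boat co-occurrence counts minutes containing at least one
   click-positive and one boat-positive segment; it can never exceed
   either class's positive-minute count. The day/night comparison computes,
   per day, positive-segment counts divided by the day (dawn-dusk) and
   night period durations in minutes, and applies a two-sided Wilcoxon
   rank-sum (Mann-Whitney) test per month: exact for small tie-free
   samples, tie-corrected normal approximation otherwise; all-tied input
   short-circuits to p = 1. Dawn/dusk can be injected per day or computed
   from site coordinates with the standard solar-elevation sunrise
   equation. The test is two-sided at alpha = 0.05: the alternative "one
   time of day has higher activity" does not privilege a direction.

## Synthetic soundscapes

No public recordings accompany the study conditions, so `synth` generates
ground-truthed audio at 96 kHz:

- **Clicks**: Gabor transients (Gaussian-windowed tones, ~200 us, spectral
  peak 28-42 kHz) repeated at a regular inter-click interval (40-110 ms)
  with +/-10% per-interval jitter; trains last 2-4.5 s at 18-28 dB SNR.
- **Boat**: low-passed (8 kHz) broadband noise amplitude-modulated at the
  engine throb rate (6-14 Hz) plus a stack of constant harmonics
  (f0 150-350 Hz); 2.5-4 s at 12-20 dB SNR. The constant harmonics are
  largely removed by median equalization — the modulated broadband
  component is what remains distinctive, as with real cavitation noise.
- **Rain**: a Poisson process (60-180 impulses/s) of ~0.8-ms damped
  full-band noise bursts, 12-20 dB SNR.
- **Background**: a pink-noise bed plus continuous narrowband insect-like
  tones (4-9 kHz), which the front-end's equalization cancels.

SNR is defined per event against the background bed's RMS in the event's
frequency band (clicks: peak amplitude relative to band RMS). Mixing is
linear; every event emits a ground-truth bounding-box annotation, and the
generator is byte-reproducible given its seed. The default training corpus
holds 600 five-second segments emulating the annotated-data structure of a
field campaign at reduced scale: click-heavy, boat and rain
under-represented (to exercise oversampling), multi-label segments present,
and a large background share. Timestamps follow a 1-min-on/9-min-off duty
cycle so schedule handling is exercised end to end.

What the generator does **not** emulate: propagation effects (multipath,
absorption, sediment scattering), species-specific click spectra, recorder
transfer functions, overlapping soundscapes of many simultaneous sources,
and the long-tailed SNR distribution of real archives. Passing tests on
this corpus therefore demonstrate that the pipeline's machinery is correct
and that the architecture can learn well-separated acoustic classes; they
do not certify field performance, which in the study setting is established
by manual validation and active learning on real recordings.

## Augmentation

Training first oversamples: segments containing a class with fewer than
`min_labels_per_epoch` labels (300 at field scale) are duplicated wholesale
by the ceiling factor, which can drag other classes' counts up since
segments are multi-label. Each epoch then regenerates the whole training
set through four transforms with freshly drawn parameters: time-warp
(factor 0.9-1.1, linear interpolation, clipped/padded back to 512 frames),
circular time shift (<= 16 frames), circular frequency shift (<= 4 Mel
bands), and a contrast adjustment. The inputs are log-power, so a power-law
contrast exponent gamma acts as multiplication of the log matrix by gamma
(drawn from 0.8-1.2); contrast is applied after equalization, on the CNN
input. The transform order is fixed (warp, time shift, frequency shift,
contrast).

## Scaled-down experiment sizes

Desk-scale runs use the reduced architecture (filters 8/16/24/32/40, head
width 64 — the same shape algebra, ~70k parameters), the 600-segment
corpus with a 50/50 random split, oversampling minimum 100 (scaled with
the corpus as 300 is to the field corpus), batch 16, Adam lr 1e-3, and 5
epochs, which is ample for the well-separated synthetic classes (loss
falls ~4x from epoch 1 and held-out micro mAP exceeds 0.99). The
acceptance script runs exactly this campaign plus an archive-condition
detection pass (where true click+rain coincidence is rare, since heavy
rain masks clicks) and the ecological summaries.

## Numerical choices and edge cases

- Log floor 1e-12 of full-scale power; the paper of record for this design
  states only that the PSD is log-transformed, so the floor is exposed in
  config.
- "Above threshold" is implemented as `>=` (closed bound) consistently in
  evaluation, detection and the rain filter.
- Q75's "between the 75th and 100th percentile" is read as the top
  `ceil(16 * 0.25) = 4` values, boundary inclusive.
- PR thresholds ascend so TPR is non-increasing, matching the boundary
  convention; AP is computed on the raw step curve without interpolation.
- An empty-denominator TPR or TNR in spot validation is returned as `None`
  with a warning, never silently as zero.
- A recording day with zero scheduled minutes yields an undefined (NaN)
  presence proportion, flagged in the output; detections on an unscheduled
  day raise a consistency error.
- Multi-channel WAVs use channel one with a warning; files without a
  parseable timestamp carry an explicit unknown epoch (`None`) rather than
  failing.

## Known limitations

- The NumPy network trains small configurations briskly but is not suited
  to field-scale training; the architecture and training recipe are,
  however, framework-agnostic and the checkpoint format records the full
  spec.
- Batch-norm running statistics make inference deterministic, but training
  curves are only reproducible on the same BLAS build.
- The rain filter deliberately sacrifices genuine clicks during rain;
  presence estimates during heavy rain are conservative.
- Day/night testing assumes dawn/dusk boundaries are known or computable;
  civil twilight refinements are out of scope.
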