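# Methods

## Problem and scope

Interictal high-frequency oscillations (HFOs) — brief bursts of 80–500 Hz
activity in intracranial EEG — occur both inside and outside the
epileptogenic zone (EZ), so merely detecting them does not delineate the
tissue that must be resected. This package implements a pipeline that
tries to *classify* individual HFOs as epileptogenic (label 0) or
non-epileptogenic (label 1): automatic ripple (80–200 Hz) and fast-ripple
(FR, 200–500 Hz) detection, four one-dimensional-to-two-dimensional
feature transformations — original waveform, band-filtered waveform,
Morlet scalogram, and the adjusted smoothed pseudo Wigner–Ville
distribution (ASPWVD) — rendered under fixed or fitted amplitude scales,
and a small convolutional network evaluated over repeated randomized
rounds. Patient recruitment, electrode localization, sleep staging and
clinical EZ delineation are out of scope: the pipeline takes a
pre-selected analysis segment and, for clinical data, a resected-channel
list.

Because clinical iEEG of this kind is not publicly deposited, the package
ships a first-class synthetic-data generator whose defaults emulate the
targeted acquisition conditions; every end-to-end claim the test suite
makes is a claim about that generator's output (see *Synthetic data*).

## Detection

Each channel is band-passed with a Hamming-window FIR filter of the
band's stated length (330 taps for ripples, 132 for FRs), applied
forward-backward so event centers stay aligned with the raw trace.
Baseline mean and SD are computed over the whole filtered segment; the
consecutive-peak rules are then applied to the strict local extrema of the
filtered trace, with amplitudes measured as absolute deviation from the
baseline mean:

* ripple: any 8 consecutive peaks all > 3.5 SD, of which ≥ 6 > 9 SD;
* FR: any 8 consecutive peaks all > 3 SD, of which ≥ 4 > 10.5 SD.

"Consecutive" means adjacent entries of the peak series — no
sub-threshold peak may intervene. Every length-8 window is tested;
overlapping qualifying windows merge, as do events whose contributing
peaks lie closer than 100 ms. The event center is the midpoint of the
first and last contributing peak. The implementation is cross-checked
against an exhaustive brute-force window scan on random peak series.
Note that with these constants the 3.5 SD clause of the ripple rule is
almost redundant (any window with six 9 SD peaks rarely has sub-3.5 SD
members); it is implemented literally.

**False-HFO rejection.** Band-pass filtering a sharp transient produces
ringing that can satisfy the peak rules. The criterion used here is
based on the raw waveform: a genuine oscillation keeps oscillating in
the raw trace, a filtered spike does not. An event is rejected when the
dominant raw deflection within ±100 ms of its center exceeds 6× the raw
channel SD *and* fewer than 4 strict raw extrema within ±25 ms of that
deflection reach half its amplitude. A biphasic transient has at most
two such extrema; a burst of ≥ 6 cycles has ≥ 5 near-full-amplitude
extrema inside that window at any in-band frequency, which is what makes
the criterion insensitive to burst frequency and duration. An earlier
candidate criterion (counting *filtered* peaks outside ±25 ms of the raw
peak) was discarded during design because short high-frequency bursts
(6 cycles at 180 Hz span ±17 ms) have no filtered peaks outside that
window and would be rejected wholesale.

Surviving events are cut into 5 s raw epochs (10,000 samples at 2 kHz)
centered on the event; class-balanced cohorts are drawn without
replacement with a seeded generator.

## Feature transformations

All features look at the central 200 ms (ripple) or 100 ms (FR) of the
epoch. Waveform features attach amplitude limits: fixed limits are
±1,000 µV (original), ±50/±10 µV (filtered ripple/FR); the fitted limit
is ±α with α the slice's absolute maximum (fallback 1 µV for an all-zero
slice, an arbitrary but harmless constant since the trace is then flat).

The Morlet scalogram uses the analytic Morlet wavelet with
nondimensional center frequency ω₀ = 8 ("center frequency of eight" read
as the standard ω₀ convention), evaluated at 1 Hz steps across the band
on the central 1,000 ms and cropped to the display window, keeping
boundary effects outside the image. It is calibrated so a tone of
amplitude A at a grid frequency yields energy A² µV²; fixed energy
limits are 0–1,000 µV² (ripple) and 0–10 µV² (FR).

The Wigner–Ville distribution is computed on the analytic signal
(Hilbert transform), which suppresses negative-frequency cross-terms.
The discrete kernel uses whole lags, `K[n, m] = z[n+m] z*[n−m]`, so
frequency bins are `k·fs/(2·nfft)` — a 0.5 Hz grid up to 1,000 Hz for a
2 kHz, 2,000-sample window. Summing over all frequency bins recovers
`nfft·|z(t)|²` exactly, which the tests assert on a Gaussian atom. The
smoothed pseudo WVD applies two independent Kaiser windows: `g`
(time-domain, 1,000 ms support) convolved along time with unit-sum
normalization, and `h`, a 127-point lag-domain taper whose Fourier
transform is the frequency smoothing window H(f). β = 14 for both; β
and the `h` length are exposed in `SmoothingWindows`. The "frequency of
1,000 Hz" attached to the smoother is read as the 0–1,000 Hz analysis
extent of the grid. With an impulse `g` and an all-ones `h` the SPWVD
reduces exactly to the WVD (asserted).

**Normalization chain.** Because EEG power decays steeply with
frequency, the raw SPWVD is nearly invisible at HFO frequencies. Three
steps address this:

1. *SPWVD index* — each frequency row is divided by its own maximum over
   the 1,000 ms window; nonpositive values map to 0. The result lies in
   [0, 1], every row with a positive entry attains 1, and the operation
   is idempotent. The normalization is computed on the full time window
   while *curve C* (step 2) is evaluated only inside the band × display
   window; this is the only reading under which curve C is not
   identically 1.
2. *Re-normalized SPWVD* (fitted scale) — curve C is the per-frequency
   maximum of the index inside the band and display window; each epoch
   is divided by its own curve maximum (`max_index`).
3. *ASPWVD* (fixed scale) — all epochs of a band cohort are divided by
   the cohort *median* of the `max_index` values (even cohorts use the
   midpoint of the two central values). Epochs above the median saturate,
   epochs below stay < 1, so between-epoch energy differences survive
   into the image, unlike in step 2.

Values exceeding 1 after division are clipped to 1: image intensities
must be bounded, and saturation is the intended behaviour of the
adjustment. Division by a zero normalizer raises a degenerate-epoch /
degenerate-cohort error rather than producing NaNs.

Since both the smoothing and the row normalization act on each frequency
row independently, the production path computes SPWVD rows only inside
the analysis band, and applies the scalar cohort division after painting
the native canvas; both shortcuts are bit-equivalent to the full-matrix
route and are asserted against it in the tests.

## Imaging

Features are painted on band-specific native canvases — 200 × 120
(width × height) for ripples, 400 × 300 for FRs, the orientation being a
documented reading of the stated pixel sizes — with ink/energy = 1 on a
0 background. Waveforms are drawn as connected vertical-span polylines
without anti-aliasing; time-frequency matrices are mapped linearly from
[0, limit] to [0, 1] and painted by nearest-neighbor lookup with
frequency increasing upward. Canvases are resized to 96 × 96 with
Pillow's bicubic filter (the Catmull–Rom a = −0.5, half-pixel-centered
convention of mainstream toolchains; reproduces linear ramps to < 10⁻³
away from borders) and clipped to [0, 1] after cubic overshoot. The
whole render path is deterministic, so identical inputs give
bit-identical PNG bytes.

## Classifier

Three conv(3×3) + batch-norm + ReLU + 2×2 max-pool blocks with 8/16/32
filters, a 128-unit fully connected layer, dropout 0.5, and a 2-way
softmax; inputs are centered by subtracting 0.5. Training is plain SGD
with momentum 0.9 and initial learning rate 0.01, halved every 5 epochs
(15 epochs, batch 32 by default); the parameter state with the best
validation accuracy is kept. Ties in the softmax argmax resolve to
class 0 (EZ). The layers are implemented directly on NumPy arrays
(im2col convolutions, float32), so results are deterministic per seed
on a single device. The filter counts, epoch budget and batch size are
deliberately compact so that a full repeated-rounds evaluation runs on
one CPU core in minutes; only the layer types, three-block structure and
the 0.01 initial learning rate are treated as fixed by the method, and
all other hyperparameters are exposed in `ArchConfig` / `TrainConfig`.

Evaluation: stratified 70/15/15 train/validation/test split per round
(per-event, not per-patient — the synthetic generator has no patient
structure; grouped splitting would be required for multi-patient
clinical use), re-split and retrained from scratch each round with seed
`base + round`, test sets disjoint from that round's training data
(asserted). Scores follow the EZ-positive convention: sensitivity
= 100·TP/(TP+FN), specificity = 100·TN/(TN+FP), accuracy
= 100·(TP+TN)/total, aggregated as mean ± sample SD over rounds. Zero
denominators yield NaN markers. Across-transform significance testing
(ANOVA/post-hoc) is not reimplemented; the per-round table those tests
would consume is what the pipeline emits.

## Synthetic data

The generator produces 2,000 Hz recordings of 1/f ("pink") noise —
white Gaussian noise shaped in the spectral domain, rescaled to an exact
target SD — with Gaussian-windowed sinusoidal bursts implanted at
Poisson-drawn, edge-respecting positions (≥ 2.5 s from the edges so a
5 s epoch always fits; ≥ 500 ms apart so epochs are single-event).
Burst envelopes use σ = duration/3, a deliberately flat-topped taper
that keeps the central eight oscillation peaks near full amplitude, so
that an implanted amplitude translates directly into the peak amplitudes
the detector thresholds. EZ and non-EZ events share their frequency
(default uniform 100–180 Hz for ripples, 250–400 Hz for FRs) and
duration (uniform 6–10 cycles) distributions and differ only in peak
envelope amplitude, normal with means 60 vs 30 µV and SD 10 µV by
default: amplitude is the separability knob, reflecting the view that
EZ/non-EZ differences are primarily amplitude differences. No published
amplitude distributions exist for the two classes; these defaults are
stand-ins, exposed in `SimConfig`. Interictal spikes are biphasic
derivative-of-Gaussian transients (default 200 µV, 20–40 ms).

What the generator does *not* emulate: patient and channel structure,
sleep-stage dynamics, physiological HFO subtypes, non-Gaussian artifact
families, and class differences in waveform shape or frequency. Passing
end-to-end tests therefore demonstrate that the pipeline's machinery —
detection rules, normalization chain, rendering, training loop — behaves
as specified and can exploit an amplitude cue; they say nothing about
classification accuracy on clinical recordings.

A consequence worth knowing: with the ripple rule above, the
strict threshold (9 × in-band SD ≈ 31.5 µV over a 10 µV pink-noise
background) sits *above* the default non-EZ amplitude mean, so detection
retains almost none of the 30 µV class. Classification cohorts are
therefore extracted at ground-truth event centers, while the detector is
validated separately at amplitudes it can see (≥ 12× background SD,
where recovery is ≥ 95%). On the clean synthetic cohorts every epoch's
band rows attain their row maximum at the centered burst, so
`max_index` = 1 for nearly all epochs and the cohort median is 1: the
fixed-scale ASPWVD and fitted-scale re-normalized images then coincide,
and the classes differ through the spectral extent of the saturated
region and the relative brightness of the background rather than through
an absolute intensity offset. In clinical data, where row maxima often
come from other activity in the 1,000 ms window, the median falls below
1 and the adjustment genuinely re-scales.

## Problem sizes and numerical choices

The shipped evaluation sizes are the package's own choices: cohorts of
300 events per class, 5 evaluation rounds, 15 training epochs
(`scripts/acceptance.py`), and a test suite with smaller cohorts for the
directional scale-mode comparison (150/class, fast ripples). Key
tolerances: FIR
passband gain within 5%, scalogram/SPWVD tone recovery within 1 Hz (the
0.5/1 Hz grids), WVD marginal to 1e-10 absolute, EDF round-trip within
half a quantization step of the stored physical range. Degenerate
inputs (zero SD baselines, all-nonpositive rows, zero normalizers,
events at epoch edges) raise typed errors or are handled by documented
fallbacks rather than propagating NaNs.

## Known limitations

* On this generator the fixed-vs-fitted accuracy contrast for waveform
  features is a near-tie rather than a clear win for fixed scaling: with
  a homogeneous noise floor, the fitted render's visible relative noise
  amplitude (noise SD / per-epoch maximum) is itself a monotone function
  of the burst amplitude, so the fitted scale removes the absolute cue
  but leaves an equivalent relative one. Clinical recordings, where
  baseline scale varies with reference and equipment, are the setting in
  which the two scales genuinely dissociate. The directional test states
  the claim as-is and is expected to be unresolvable here.
* The NumPy CNN is single-threaded BLAS-bound; it is sized for hundreds,
  not tens of thousands, of images per round.
* Determinism is guaranteed per device/BLAS configuration, not across
  platforms.
* The false-HFO criterion is a documented heuristic; alternative
  published rejectors (e.g. spectral-trough tests) are out of scope.
* The EDF writer targets plain EDF (16-bit, 1 s records, zero-padded
  tail); EDF+ annotations are not produced.
* Only sequential bipolar re-referencing is provided.
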