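# Methods

This note documents the model, the numerical choices, and the scope of the
synthetic validation, in the package's own terms.

## The brain rate

Cognitive activation is summarised per EEG window as a spectrum-weighted
frequency index.  For a window of `n` channels, each channel's one-sided FFT
magnitude spectrum (rectangular taper, bins restricted to the 0.5–45 Hz
analysis range) is partitioned into the five canonical bands

| band  | range (Hz) | mid-frequency f_b (Hz) |
|-------|-----------|------------------------|
| delta | [0.5, 4]  | 2.25 |
| theta | (4, 8]    | 6    |
| alpha | (8, 12]   | 10   |
| beta  | (12, 30]  | 21   |
| gamma | (30, 45]  | 37.5 |

and the brain rate is

    BR = Σ_ch Σ_b f_b · P(b, ch),      P(b, ch) = avg_b(FFT_ch) / avg(FFT_ch)

where `avg_b` is the arithmetic mean of the amplitudes at the bins inside
band `b` (the band *centroid*) and `avg` the mean over the whole analysis
range.  On the 0.5 Hz grid of a 2-s window at 128 Hz the five bands hold
8/8/8/36/30 of the 90 bins, so `P` re-balances bands of unequal width.
`P` and hence BR are invariant to the amplitude scale of the window.

Two conventions are implemented because the mean-ratio form of `P` does not
sum to one (a flat spectrum gives P ≡ 1 per band, i.e. 76.75 Hz per channel,
summed over channels):

* `mean_ratio` + `sum_channels` — the definitional form above, the package default;
* `power_fraction` + `mean_channels` — band power over total power, a proper
  convex weighting under which BR lies in [2.25, 37.5] Hz and is
  interpretable as a mean oscillation frequency.

Training is unaffected by the choice up to an affine rescaling of the
target, and MAPE is scale-free, so the default is faithfulness to the
defining equations; both are exposed in the configuration and recorded in
manifests.

Boundary inclusion follows the interval notation above: the 4.0 Hz bin
belongs to delta, 4.5 Hz to theta, and so on.  The denominator of `P`
averages over the full 0.5–45 Hz range — the union of the five bands,
matching the upstream band-pass.  Magnitude (not squared) spectra are used
for the centroids; the ratio form makes the distinction nearly neutral, and
`power_fraction` uses squared magnitudes where a power reading is the point.

## Head-map tensors

Per window, the five per-channel band centroids become a 32×32×5 image:

1. Electrode positions are served on an idealized unit sphere (Cz at the
   vertex, +x right ear, +y nasion), derived at run time from the standard
   10-05 coordinate table embedded in MNE: sphere-fitted, rotated so Cz is
   the vertex and Fpz lies on the +y meridian, then mirror-symmetrized so
   homologous left/right pairs are exactly symmetric.  No claim is made that
   this is the geometry of any particular recording system; only relative
   scalp geometry matters downstream.
2. The azimuthal equidistant projection maps a site at polar angle θ and
   azimuth φ to (θ cos φ, θ sin φ), preserving each electrode's great-circle
   distance from the vertex.
3. Each band's scattered centroid values are interpolated onto a regular
   32×32 grid with the piecewise-cubic Clough–Tocher scheme over a Delaunay
   triangulation of the projected sites.

Numerical conventions the method leaves open, fixed here and recorded in
manifests: grid extent is the bounding square of the projected electrodes
plus a 5% margin, fixed per montage so tensors are comparable across windows
and subjects; grid nodes outside the electrode convex hull (where
triangulation-based interpolation is undefined) take `fill_value = 0`; image
row 0 is the front of the head.  No per-map normalisation is applied by
default; an optional input-standardization flag exists for training
stability and is recorded whenever used.  No data augmentation is performed
anywhere (flips/zooms would scramble the cortical geography).

## Sequences and splits

Windows are 2 s long and shifted by 125 ms by default, so a 63-s trial at
128 Hz (8064 samples) yields 489 windows; sequences of z = 7 consecutive
window tensors (14 s of activity) are the training unit, each targeting the
brain rate of the window immediately after the sequence — the supervisory
signal is computed from the data itself.  A trial therefore yields
489 − 7 = 482 sequences (sequence stride: one window).  The 3-s pre-trial
baseline is included in windowing, matching the arithmetic above.

Splits are drawn at the trial ("video") level: whole trials are shuffled and
assigned ~70/15/15 to train/validation/test (round-half-up for train and
validation, remainder to test; 40 trials → 28/6/6, 10 → 7/2/1).  This keeps
every window of a test trial unseen during training.  Across-subject models
concatenate per-participant splits and repeat the whole procedure over
Monte-Carlo-sampled participant subsets.

## Architectures

Both regressors are built on a numpy NN core written for this package
(im2col convolution, max pooling, dense, inverted dropout, LSTM with full
backpropagation through time, Adam); every layer's analytic gradient is
verified against central differences in the test suite.

*CNN trunk* (VGG-style): conv blocks of 4×32, 2×64 and 1×128 filters, all
3×3 stride 1 with ReLU, each block closed by 2×2 stride-2 max pooling.  Two
readings of the conv padding are defensible — 1-pixel 'same' padding, which
preserves the 32x32 spatial resolution per layer, or 'valid'; the default
here is 'same' (trunk feature length 4·4·128 = 2048), with 'valid' behind a
flag (feature
length 1·1·128 = 128).  Standalone regression adds dense-512 ReLU → dropout
0.5 → dense-1 linear, and is trained on the same (window i → brain rate of
window i+1) pairing as the full model — i.e. z = 1 sequences — so its trunk
weights are directly transferable.

*CNN+LSTM*: the z frames pass through a single shared trunk (one parameter
set, so branch weights cannot diverge — verified structurally in the
tests), the z feature vectors feed one LSTM layer of 128 units of which
only the last output is used, and in parallel a 1D convolution (64 filters,
kernel 3, valid padding, ReLU) over the same feature sequence captures
frame-to-frame variation.  Its flattened output is concatenated with the
LSTM output and regressed through dropout 0.5 → dense-512 ReLU → dropout
0.5 → dense-1 linear.  For degenerate z < 3 the side kernel is clamped to z.

Classical LSTM gate formulations include cell-state (peephole) terms; the
default implementation is the standard framework form without them, with a
diagonal-peephole mode behind a flag.  The padding, peephole and side-kernel
flags all change the exact trainable-parameter count, which is therefore
computed (`count_parameters`) and written into every model manifest rather
than asserted against any nominal figure; the default reading totals
1,896,801 parameters.

## Training protocol

MSE loss; Adam with learning rate 1e-3 and moment decays 0.9/0.999; batch
size 32 by default (100 supported); at most 60 epochs with early stopping at
patience 6 on the validation loss — training halts after 6 consecutive
epochs without a new minimum and the weights of the best validation epoch
are restored.  Targets are used raw by default; optional standardization by
training-set mean/std (inverse-transformed before computing metrics, so
MAPE keeps its raw-scale meaning) is a recorded flag.  Runs are
deterministic given the seed: parameter init, dropout masks and batch
shuffling all derive from seeded generators.  Non-finite losses abort with a
diagnostic rather than silently producing a model.

Evaluation reports MSE, MAPE (percent) and the Pearson correlation between
predicted and observed brain-rate series per test trial plus their mean;
correlations undefined on constant series are reported as missing and
flagged, never dropped.

## The synthetic generator

Trials emulate the shape of a 32-channel video-watching study: 128 Hz, 63 s,
40 trials per participant, the 32-channel 10–20 layout.  Each trial is a sum
over bands of `envelope_b(t) · gain_b(ch) · carrier_b(ch, t)` plus broadband
noise, where carriers are unit-RMS narrow-band noise (band-limited by FFT
masking; a pure-tone mode exists for exact-bin oracles), envelopes are slow
sinusoidal modulations (periods 15–30 s, i.e. several windows long) around
realistic resting band amplitudes (delta/theta/alpha/beta/gamma =
8/6/10/4/1.5 µV RMS, modulation depths 0.3/0.4/0.8/0.6/0.3, broadband noise
2 µV), and gains are smooth anterior–posterior/lateral gradients over the
scalp.  These defaults were chosen once as a plausible resting-EEG
caricature with load-sensitive alpha/beta dynamics.

What the generator emulates: band-limited rhythms with slowly drifting
power, smooth spatial topographies, trial-to-trial variability.  What it
does not: volume conduction and dipolar source geometry, artifacts
(EOG/EMG), non-stationarity faster than the envelope time scale,
cross-band coupling.  Passing the learning checks therefore demonstrates
that the pipeline and optimizer can recover predictable band-power dynamics
end to end — not that the architecture reaches any particular accuracy on
real recordings.

## The reference learning experiment

`brainrate.experiments.reference_learning_experiment` is the standard
end-to-end check: one participant, 8 trials of 63 s, 2-s windows with a 2-s
(non-overlapping) shift, z = 7, both architectures trained for at most 20
epochs (batch 32, patience 6, input and target standardization on, flags
recorded) and compared on held-out trials against the constant-mean
predictor's MAPE.  The non-overlapping shift is this experiment's sizing
choice: with the default 125-ms shift adjacent sequences overlap by ~98%,
which multiplies near-duplicate instances without adding information at
this scale.  The full-protocol defaults (125 ms shift, 40 trials, 60
epochs) remain unchanged everywhere else.

## Known limitations

* The definitional brain rate is a channel sum of non-normalised weights;
  its absolute scale (hundreds to thousands of Hz for 32 channels) is not a
  physical frequency.  The bounded `power_fraction`/`mean_channels` variant
  exists for interpretability.
* EDF/BDF writing is a minimal single-record implementation (16/24-bit
  integer precision, per-channel physical scaling); reading is delegated to
  MNE, which also cross-checks the writer in the tests.
* The NN core is single-threaded numpy; it is adequate for the synthetic
  studies and for method development, not for full-scale cohort training.
* Early stopping interprets "retain the model from before the plateau" as
  restoring the best-validation-loss weights, the common framework reading.
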