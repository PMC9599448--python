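# brainrate

Self-supervised cognitive-load modelling from multi-channel EEG.

Mental workload has no agreed ground truth: most models fit subjective
ratings or ad-hoc task categories, which ties them to one experiment.  This
package implements an alternative in which the supervisory signal is
computed from the EEG itself: a **brain rate**, a spectrum-weighted index of
cognitive activation, is extracted per short window, and deep regressors
are trained to predict the *next* window's brain rate from the preceding
windows — self-supervision with no human labels.  It is aimed at
researchers in EEG/cognitive-workload methodology who want a reproducible,
label-free pipeline they can run end to end on synthetic data before
committing to a recording campaign.

## The method

For a 2-s window of `n`-channel EEG, each channel's one-sided FFT magnitude
spectrum over 0.5–45 Hz is split into the five canonical bands — delta
[0.5,4], theta (4,8], alpha (8,12], beta (12,30], gamma (30,45] Hz — and

    BR = Σ_ch Σ_b f_b · P(b, ch),   P(b, ch) = avg_b(FFT_ch) / avg(FFT_ch)

with `f_b` the band mid-frequencies (2.25, 6, 10, 21, 37.5 Hz) and `avg_b`
the mean amplitude inside band `b` (the band centroid).  Windows also become
32×32×5 *topology-preserving spectral head maps*: electrode positions on a
unit sphere are flattened by the azimuthal equidistant projection about the
vertex, and each band's per-channel centroids are Clough–Tocher-interpolated
onto a 32×32 grid.

Sequences of z = 7 consecutive head-map tensors (windows shifted by 125 ms;
a 63-s trial yields 489 windows and 482 sequences) are regressed onto the
brain rate of the 8th window by either a VGG-style CNN (7 conv layers:
4×32, 2×64, 1×128 filters, 3×3, with 2×2 max pooling; dense-512 head) or a
convolutional-recurrent model: z parallel CNNs *sharing one set of weights*,
a 128-unit LSTM over their feature vectors, a parallel 1D convolution over
the same feature sequence, and a linear output.  Training uses MSE, Adam
(lr 1e-3), batch 32, early stopping with patience 6; splits are drawn at
the trial level so test trials are never seen in training; evaluation
reports MAPE (%) and the per-trial Pearson correlation between predicted
and observed brain-rate series.

A synthetic-study generator produces DEAP-shaped cohorts (32 channels,
128 Hz, 63-s trials, 40 trials/participant) with controllable band-power
envelopes and known ground truth, so every stage — and the learning loop
itself — is testable without any external dataset.

## Worked example

```sh
$ python examples/01_brain_rate.py
band weights f_b (Hz): {'delta': 2.25, 'theta': 6.0, 'alpha': 10.0, 'beta': 21.0, 'gamma': 37.5}
mean P(b, ch) over channels: {'delta': 0.696, 'theta': 0.677, 'alpha': 4.343, 'beta': 0.669, 'gamma': 0.673}
brain rate (sum_channels, mean_ratio): 2826.76 Hz
brain rate (mean_channels, power_fraction): 10.66 Hz
```

The window is an alpha-dominant synthetic signal: the alpha weight (4.34)
dwarfs the other bands, and the bounded power-fraction variant lands at
10.66 Hz, next to the 10 Hz alpha mid-frequency.  The definitional value is
a sum of non-normalised weights over 32 channels, hence its larger scale.

```sh
$ python examples/03_sequences_and_splits.py
samples per trial: 8064  ->  windows: 489 (window 256 samples, shift 16)
sequences of z=7: 482 (= 489 - 7); first instance targets window 7
40 trials split at the video level: 28/6/6 (train/validation/test)
per-participant sequence counts: {'train': 13496, 'validation': 2892, 'test': 2892, 'total': 19280}
```

`examples/02_head_maps.py` renders head-map tensors, and
`examples/04_train_models.py` trains both architectures on a small
synthetic study and compares their held-out MAPE against the constant-mean
baseline (run with `quick` for a smoke pass).

There is also a thin CLI over the same library code:

```sh
brainrate simulate   -c config.yaml --out study      # synthetic study to disk
brainrate preprocess -c config.yaml -i study --out prepared
brainrate train      -c config.yaml -d prepared --out results
brainrate evaluate   -r results/results.csv
```

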