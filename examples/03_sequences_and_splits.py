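"""The sequence-generation arithmetic of the self-supervised protocol.

Shows, without any signal processing, how a 63-s trial at 128 Hz becomes
489 overlapping 2-s windows, 482 sequences of z = 7 with the 8th window's
brain rate as target, and how 40 trials split at the video level into
28/6/6, giving 13,496 / 2,892 / 2,892 sequences for one participant.
"""

import numpy as np

from brainrate import (SequencingConfig, assemble_dataset, build_sequences,
                       slide_windows, split_by_trial)

cfg = SequencingConfig()  # 2-s windows, 125-ms shift, z = 7
fs = 128.0
n_samples = int(63 * fs)
starts = slide_windows(n_samples, cfg.window_samples(fs), cfg.shift_samples(fs))
print(f"samples per trial: {n_samples}  ->  windows: {len(starts)} "
      f"(window {cfg.window_samples(fs)} samples, shift {cfg.shift_samples(fs)})")

brs = np.random.default_rng(0).uniform(50, 100, len(starts))
seqs = build_sequences(list(range(len(starts))), brs, z=cfg.sequence_length)
print(f"sequences of z={cfg.sequence_length}: {len(seqs)} "
      f"(= {len(starts)} - {cfg.sequence_length}); "
      f"first instance targets window {seqs[0].target_window_index}")

trials = [f"t{i:02d}" for i in range(40)]
plan = split_by_trial(trials, seed=1)
print(f"40 trials split at the video level: {len(plan.train)}/{len(plan.validation)}"
      f"/{len(plan.test)} (train/validation/test)")

per_trial = {
    t: build_sequences(list(range(len(starts))), brs, z=7,
                       participant_id="p01", trial_id=t)
    for t in trials
}
ds = assemble_dataset({"p01": per_trial}, {"p01": plan})
print("per-participant sequence counts:", ds.counts)
print("\nWhole trials stay in one part, so no test window was ever seen in training.")
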