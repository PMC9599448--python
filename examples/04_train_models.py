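"""Train the CNN and CNN+LSTM on a small synthetic study (a few minutes on CPU).

Generates a one-participant study with slow band-power drift, preprocesses
it into head-map tensors, trains both architectures to predict the next
window's brain rate, and compares their held-out MAPE with the constant-mean
baseline.  A model that learned anything real lands below the baseline.

Run with a smaller study for a quick smoke, e.g.:

    python examples/04_train_models.py quick
"""

import sys
import time

from brainrate.experiments import reference_learning_experiment

quick = len(sys.argv) > 1 and sys.argv[1] == "quick"
t0 = time.time()
df = reference_learning_experiment(seed=1, max_epochs=3 if quick else 20)

cols = ["arch", "n_train", "n_val", "n_test", "epochs", "best_epoch",
        "test_mape", "baseline_mape", "pearson_r_mean"]
print(df[cols].to_string(index=False))
print(f"\nelapsed: {time.time() - t0:.0f} s")
print("test_mape and baseline_mape are percent errors on the raw brain-rate "
      "scale; beating the baseline means the model predicts the drift of "
      "cognitive activation, not just its mean.")
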