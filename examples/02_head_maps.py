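"""Turn an EEG window into a 32x32x5 topographic spectral head-map tensor.

Generates one synthetic trial, converts its first 2-s window into the
head-map tensor (azimuthal equidistant projection + Clough-Tocher
interpolation of per-band centroids) and prints per-band summary statistics.
Optionally renders a PNG when a path is given on the command line.
"""

import sys

import numpy as np

from brainrate import standard_montage_1020, window_to_tensor
from brainrate.synth import DEAP_CHANNELS, generate_trial, slow_drift_schedule

schedule = slow_drift_schedule(seed=42)
rec, truth = generate_trial(schedule, seed=42)
window = rec.data[:, :256]

montage = standard_montage_1020(list(DEAP_CHANNELS))
tensor = window_to_tensor(window, rec.fs, montage=montage,
                          channel_names=rec.channel_names)

print(f"tensor shape: {tensor.grid.shape}  (rows front-to-back, bands {tensor.band_names})")
for b, name in enumerate(tensor.band_names):
    sl = tensor.grid[:, :, b]
    inside = sl[sl != tensor.fill_value]
    print(f"  {name:5s}: in-hull mean {inside.mean():7.3f} uV, max {inside.max():7.3f} uV")

print("\nEach slice is the scalp map of one band's spectral centroid; the band "
      "with the largest scheduled envelope should show the brightest map.")
alpha_sched = float(np.mean(truth["band_envelopes"]["alpha"][:256]))
print(f"scheduled alpha envelope over this window: {alpha_sched:.2f} uV")

if len(sys.argv) > 1:
    from brainrate.topomap import render_tensor
    render_tensor(tensor, sys.argv[1])
    print(f"rendered to {sys.argv[1]}")
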