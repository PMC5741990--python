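"""Simulate a short DTOF-level recording and extract its moments.

A layered-slab Monte Carlo provides detected photons (time of flight plus
per-layer path lengths); a step increase in intracerebral oxyhemoglobin
raises brain absorption, which preferentially removes late (deep) photons
and therefore *shortens* the mean time of flight <t>.
"""

import numpy as np

from trfnirs import (
    BlockDesign,
    DTOFSimConfig,
    OpticalLayerStack,
    build_timeline,
    delta_mean_tof,
    simulate_dtof_recording,
)
from trfnirs.pipeline import moment_series_from_frames

design = BlockDesign(lead_in_rest_s=9, n_cycles=1, task_s=9, cycle_rest_s=9,
                     frame_interval_s=0.3)
tl = build_timeline(design)

# 1 uM oxyhemoglobin step during the task block, -0.3 uM deoxyhemoglobin
hb = np.zeros((tl.n_frames, 2))
hb[tl.task_mask] = (1.0, -0.3)

cfg = DTOFSimConfig(stack=OpticalLayerStack(), chromophore_timecourse=hb,
                    photons_per_frame=1e6, mc_photons=300_000, seed=1)
frames = simulate_dtof_recording(cfg, tl, channels=("ch1",))

series = moment_series_from_frames(frames, design=design,
                                   baseline_window=(0, 30))
dt = delta_mean_tof(series)
for (ch, wl), d in sorted(dt.items()):
    task_d = d[tl.task_mask].mean()
    rest_d = d[tl.rest_mask].mean()
    print(f"{ch} @ {wl:.0f} nm: mean d<t> task {task_d:+.2f} ps, "
          f"rest {rest_d:+.2f} ps")
print("Negative d<t> during the task block = absorption increase in the "
      "brain layers, as expected for an oxyhemoglobin rise at 830 nm.")
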