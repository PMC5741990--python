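"""Build the question protocol and its theoretical activation model.

One question is asked as 30 s of rest followed by five alternating 30 s
blocks of motor imagery and rest, sampled every 300 ms.  The expected
hemodynamic response is the task boxcar convolved with a double-gamma HRF.
"""

import numpy as np

from trfnirs import BlockDesign, build_regressor, build_timeline

design = BlockDesign()  # 30 s lead-in + 5 x (30 s task + 30 s rest) @ 300 ms
tl = build_timeline(design)
reg = build_regressor(design)

mins, secs = divmod(int(design.total_duration_s), 60)
print(f"total duration      : {design.total_duration_s:.0f} s ({mins}:{secs:02d} min)")
print(f"frames              : {tl.n_frames}")
print(f"task frames         : {int(tl.task_indicator.sum())}")
print(f"regressor peak      : {reg.max():.2f} at t = {tl.times[reg.argmax()]:.1f} s")
print(f"first task onset    : {tl.times[tl.task_mask][0]:.1f} s")

# The regressor peaks a few seconds after each task onset: the vascular
# response lags neural activity, which is why a plain boxcar underfits.
lag = tl.times[np.argmax(reg[:300])] - design.lead_in_rest_s
print(f"hemodynamic lag     : ~{lag:.1f} s after block onset")
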