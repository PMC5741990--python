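"""Decode yes/no answers from synthetic two-wavelength question recordings.

A "yes" run carries a hemodynamic response (motor imagery) in the mean
time-of-flight series of every channel; a "no" run carries physiological
background only.  The full chain runs: baseline-referenced d<t> ->
MARA -> band-stop -> detrend -> absorption -> hemoglobin -> SVM per
channel -> any-channel answer rule.
"""

from trfnirs import generate_training_corpus, train_classifier
from trfnirs.pipeline import (
    DEFAULT_NOMINAL_SF,
    decode_recording,
    simulate_moment_recording,
)

model = train_classifier(generate_training_corpus(seed=7), seed=7)

for truth in ("yes", "no"):
    rec = simulate_moment_recording(answer=(truth == "yes"), noise_sd_ps=2.0,
                                    seed=42 if truth == "yes" else 43)
    ans, hemo = decode_recording(rec, model, DEFAULT_NOMINAL_SF,
                                 question=f"truth={truth}")
    print(f"question with truth '{truth}':")
    for d in ans.decisions:
        state = "ACTIVATED" if d.activated else "quiet"
        print(f"  {d.channel}: {state:9s} CNR={d.features.cnr:+6.2f} "
              f"r={d.features.r:+5.2f}")
    print(f"  -> decoded {ans.response.upper()} "
          f"({ans.n_activated}/4 channels, mean CNR {ans.mean_cnr:.2f}, "
          f"mean r {ans.mean_r:.2f})")
# Mean CNR/r are averaged over activated channels for a yes and over all
# channels for a no, matching how per-question summaries are reported.
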