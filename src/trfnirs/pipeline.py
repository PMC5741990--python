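"""End-to-end glue: recordings -> moments -> conditioning -> hemoglobin -> answer.

Two decoding paths are provided.  The full-physics path starts from DTOF
frames: per channel and wavelength the mean time of flight is extracted,
conditioned (MARA -> band-stop -> detrend), referenced to the lead-in
baseline, converted to intracerebral absorption changes through the
Monte Carlo sensitivity factors and inverted to hemoglobin; the
support-vector detector then votes per channel and the answer rule
aggregates.  The moment-level path applies the same conditioning and
detector directly to per-channel activation series in arbitrary units —
the domain the simulated training corpus lives in.
"""

from __future__ import annotations

import numpy as np

from .classify import (
    Answer,
    TrainedClassifier,
    classify_channel,
    decide_answer,
)
from .hrf import HRFModel, build_regressor
from .moments import IntegrationLimits, MomentSeries, delta_mean_tof, moments_of_recording
from .paradigm import BlockDesign
from .preprocess import FilterSpec, MaraSpec, preprocess_series
from .sensitivity import (
    ExtinctionTable,
    delta_mua_from_dtof,
    hemoglobin_from_mua,
)
from .simulate import SignalSimConfig, simulate_activation_series

__all__ = [
    "DEFAULT_NOMINAL_SF",
    "moment_series_from_frames",
    "simulate_moment_recording",
    "decode_recording",
    "answer_from_channel_series",
    "decoding_accuracy_study",
]

# Nominal intracerebral sensitivity factors (ps cm) used only to give
# moment-level simulations a physically plausible <t> scale; real analyses
# compute their own factors with run_sensitivity_mc.
DEFAULT_NOMINAL_SF = {760.0: 2500.0, 830.0: 2500.0}


def moment_series_from_frames(
    frames: dict[tuple[str, float], np.ndarray],
    bin_ps: float = 16.0,
    frame_interval_s: float = 0.3,
    limits: IntegrationLimits | None = None,
    baseline_window: tuple[int, int] | None = None,
    design: BlockDesign | None = None,
) -> MomentSeries:
    """Extract DTOF moments for every channel/wavelength of a recording.

    ``limits`` defaults to full-window integration: the sensitivity factors
    are full-window derivatives of <t>, and simulated recordings carry no
    dark background, so truncating flanks would only bias the recovered
    absorption scale.  Pass ``IntegrationLimits()`` for measured-style
    histograms with a dark-count floor.
    """
    design = design or BlockDesign()
    if limits is None:
        limits = IntegrationLimits.full()
    if baseline_window is None:
        baseline_window = (0, design.frames(design.lead_in_rest_s))
    data = {key: moments_of_recording(arr, bin_ps, limits=limits)
            for key, arr in frames.items()}
    return MomentSeries(data=data, frame_interval_s=frame_interval_s,
                        baseline_window=baseline_window)


def simulate_moment_recording(
    design: BlockDesign | None = None,
    answer: bool = True,
    hbo_amplitude_um: float = 1.0,
    hbr_amplitude_um: float = -0.3,
    noise_sd_ps: float = 2.0,
    physio_amplitude_ps: float = 1.0,
    channels: tuple[str, ...] = ("ch1", "ch2", "ch3", "ch4"),
    sf_ps_cm: dict[float, float] | None = None,
    extinction: ExtinctionTable | None = None,
    baseline_tof_ps: float = 1400.0,
    hrf: HRFModel | None = None,
    seed: int = 0,
) -> MomentSeries:
    """Synthetic two-wavelength <t> recording for a question run.

    A "yes" run carries a hemoglobin response (boxcar (*) HRF, peak
    ``hbo_amplitude_um`` / ``hbr_amplitude_um``) in every channel, mapped
    to mean-time-of-flight changes through the extinction coefficients and
    the (nominal) intracerebral sensitivity factors; physiological
    sinusoids and white noise are added in picosecond units per channel and
    wavelength.  A "no" run carries background only.
    """
    design = design or BlockDesign()
    sf = sf_ps_cm or DEFAULT_NOMINAL_SF
    ext = extinction or ExtinctionTable()
    reg = build_regressor(design, hrf)
    hb = np.vstack([hbo_amplitude_um * reg, hbr_amplitude_um * reg]).T
    if not answer:
        hb = np.zeros_like(hb)
    rng = np.random.default_rng(seed)
    data = {}
    for ch in channels:
        for wl in sorted(sf):
            dmua = hb @ ext.row(wl)
            dtof = -sf[wl] * dmua  # mua increase shortens <t>
            cfg = SignalSimConfig(
                design=design, activation_amplitude=0.0,
                physio_amplitudes=(physio_amplitude_ps,) * 3,
                noise_sd=noise_sd_ps,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            background, _ = simulate_activation_series(cfg)
            mt = baseline_tof_ps + dtof + background
            n = design.n_frames
            arr = np.column_stack([np.full(n, 1e6), mt, np.full(n, 2.3e5)])
            data[(ch, wl)] = arr
    return MomentSeries(data=data, frame_interval_s=design.frame_interval_s,
                        baseline_window=(0, design.frames(design.lead_in_rest_s)))


def decode_recording(
    series: MomentSeries,
    model: TrainedClassifier,
    sf_ps_cm: dict[float, float],
    question: str = "q1",
    extinction: ExtinctionTable | None = None,
    mara: MaraSpec | None = None,
    filt: FilterSpec | None = None,
) -> tuple[Answer, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Full decoding chain on a two-wavelength moment recording.

    Returns the Answer and the per-channel (dHbO, dHbR) series (uM).
    """
    design = model.design
    dt = delta_mean_tof(series)
    channels = sorted({ch for ch, _ in series.data})
    hemo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    decisions = []
    for ch in channels:
        per_wl = {}
        for (c, wl), d in dt.items():
            if c != ch:
                continue
            x = preprocess_series(d, series.frame_interval_s, mara, filt)
            per_wl[wl] = x
        dmua = delta_mua_from_dtof(per_wl, sf_ps_cm)
        hbo, hbr = hemoglobin_from_mua(dmua, extinction)
        hemo[ch] = (hbo, hbr)
        decisions.append(classify_channel(hbo, model, channel=ch))
    return decide_answer(decisions, question=question), hemo


def answer_from_channel_series(
    channel_series: dict[str, np.ndarray],
    model: TrainedClassifier,
    question: str = "q1",
    preprocessed: bool = False,
) -> Answer:
    """Moment-level decoding: classify per-channel series and aggregate."""
    decisions = [
        classify_channel(x, model, channel=ch, preprocessed=preprocessed)
        for ch, x in sorted(channel_series.items())
    ]
    return decide_answer(decisions, question=question)


def decoding_accuracy_study(
    model: TrainedClassifier,
    n_trials: int = 100,
    noise_range: tuple[float, float] = (1.0, 5.0),
    activation_amplitude: float = 5.0,
    n_channels: int = 4,
    seed: int = 0,
) -> dict[str, float]:
    """Monte Carlo study of yes/no decoding accuracy on synthetic questions.

    Each trial simulates one question run: ``n_channels`` channels sharing
    the trial's noise level (drawn uniformly over ``noise_range``), all
    carrying the activation response for a "yes" trial and none for a "no"
    trial.  Returns per-class accuracy over ``n_trials`` of each class.
    """
    rng = np.random.default_rng(seed)
    design = model.design
    correct = {"yes": 0, "no": 0}
    for truth in ("yes", "no"):
        for _ in range(n_trials):
            noise_sd = float(rng.uniform(*noise_range))
            chans = {}
            for c in range(n_channels):
                cfg = SignalSimConfig(
                    design=design,
                    activation_amplitude=(activation_amplitude
                                          if truth == "yes" else 0.0),
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                series, _ = simulate_activation_series(cfg, model.hrf)
                chans[f"ch{c + 1}"] = series
            ans = answer_from_channel_series(chans, model)
            if ans.response == truth:
                correct[truth] += 1
    return {"yes_accuracy": correct["yes"] / n_trials,
            "no_accuracy": correct["no"] / n_trials,
            "n_trials_per_class": n_trials}
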