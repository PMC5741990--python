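"""Moment-level synthetic signals: activation, rest, training corpus, artifacts.

Activation runs are a five-cycle boxcar convolved with the hemodynamic
response, riding on three physiological sinusoids (0.1 Hz Mayer waves,
0.2 Hz respiration, 1 Hz cardiac) plus white Gaussian noise; rest runs drop
the activation term.  The training corpus draws the noise standard deviation
uniformly over [1, 10] per data set, in the same arbitrary signal units as
the activation amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hrf import HRFModel, build_regressor
from .paradigm import BlockDesign, Timeline, build_timeline

__all__ = [
    "SignalSimConfig",
    "simulate_activation_series",
    "simulate_rest_series",
    "generate_training_corpus",
    "ArtifactSpec",
    "inject_motion_artifacts",
]

PHYSIO_FREQS_HZ = (0.1, 0.2, 1.0)  # Mayer waves, respiration, cardiac


@dataclass(frozen=True)
class SignalSimConfig:
    """Configuration of one simulated moment-level run.

    Amplitudes and ``noise_sd`` share the same arbitrary signal units.
    ``noise_sd`` in [1, 10] matches the corpus the classifier is trained on;
    other values are allowed for exploration.
    """

    design: BlockDesign = field(default_factory=BlockDesign)
    activation_amplitude: float = 5.0
    physio_amplitudes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    physio_freqs_hz: tuple[float, float, float] = PHYSIO_FREQS_HZ
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.physio_amplitudes) != len(self.physio_freqs_hz):
            raise ValueError("physio amplitudes and frequencies must pair up")

    @property
    def paper_faithful_noise(self) -> bool:
        return 1.0 <= self.noise_sd <= 10.0


def _physio_component(cfg: SignalSimConfig, times: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(times)
    for amp, f in zip(cfg.physio_amplitudes, cfg.physio_freqs_hz):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += amp * np.sin(2.0 * np.pi * f * times + phase)
    return out


def simulate_activation_series(
    cfg: SignalSimConfig, hrf: HRFModel | None = None
) -> tuple[np.ndarray, Timeline]:
    """Simulate one activation run.

    series = amplitude x (boxcar (*) HRF, unit peak) + physiological
    sinusoids (random phase) + white Gaussian noise.  Deterministic given
    ``cfg.seed``.
    """
    timeline = build_timeline(cfg.design)
    rng = np.random.default_rng(cfg.seed)
    series = cfg.activation_amplitude * build_regressor(cfg.design, hrf)
    series = series + _physio_component(cfg, timeline.times, rng)
    series = series + rng.normal(0.0, cfg.noise_sd, timeline.n_frames)
    return series, timeline


def simulate_rest_series(cfg: SignalSimConfig) -> np.ndarray:
    """Simulate one rest run: physiological sinusoids plus noise only."""
    series, _ = simulate_activation_series(replace(cfg, activation_amplitude=0.0))
    return series


def generate_training_corpus(
    n_per_class: int = 50,
    noise_range: tuple[float, float] = (1.0, 10.0),
    seed: int = 0,
    design: BlockDesign | None = None,
    hrf: HRFModel | None = None,
    activation_amplitude: float = 5.0,
) -> pd.DataFrame:
    """Generate the labelled simulated corpus used to train the classifier.

    Returns a DataFrame with one row per data set: ``label`` (1 activation,
    0 rest), ``noise_sd`` (uniform over ``noise_range``), ``seed`` (per-item
    seed for exact re-simulation) and ``series`` (the simulated run).  The
    default 50+50 split yields the 100-set corpus.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    design = design or BlockDesign()
    rng = np.random.default_rng(seed)
    lo, hi = noise_range
    rows = []
    for label in (1, 0):
        for _ in range(n_per_class):
            noise_sd = float(rng.uniform(lo, hi))
            item_seed = int(rng.integers(0, 2**31 - 1))
            cfg = SignalSimConfig(
                design=design,
                activation_amplitude=activation_amplitude if label else 0.0,
                noise_sd=noise_sd,
                seed=item_seed,
            )
            series, _ = simulate_activation_series(cfg, hrf)
            rows.append({"label": label, "noise_sd": noise_sd,
                         "seed": item_seed, "series": series})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ArtifactSpec:
    """Motion-artifact injection plan: spike and baseline-shift counts and sizes.

    Amplitudes are multiples of the series standard deviation.
    """

    n_spikes: int = 0
    spike_amplitude_sd: float = 10.0
    spike_width_frames: int = 1
    n_shifts: int = 0
    shift_amplitude_sd: float = 8.0


def inject_motion_artifacts(
    series: np.ndarray, spec: ArtifactSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt a series with synthetic motion artifacts.

    Returns ``(corrupted, mask)`` where ``mask`` marks exactly the modified
    frames (for spikes, the spike frames; for baseline shifts, every frame
    from the shift onward).  Reproducible given ``seed``.
    """
    series = np.asarray(series, dtype=float)
    out = series.copy()
    mask = np.zeros(series.size, dtype=bool)
    n_events = spec.n_spikes + spec.n_shifts
    if n_events == 0:
        return out, mask
    sd = series.std()
    if sd == 0:
        sd = 1.0
    rng = np.random.default_rng(seed)
    # keep events away from the edges so detection windows fit
    margin = max(5, spec.spike_width_frames)
    positions = rng.choice(np.arange(margin, series.size - margin),
                           size=n_events, replace=False)
    for k, pos in enumerate(positions):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if k < spec.n_spikes:
            sl = slice(pos, min(pos + spec.spike_width_frames, series.size))
            out[sl] += sign * spec.spike_amplitude_sd * sd
            mask[sl] = True
        else:
            out[pos:] += sign * spec.shift_amplitude_sd * sd
            mask[pos:] = True
    return out, mask
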