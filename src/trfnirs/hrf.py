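"""Hemodynamic response function models and task regressors.

The expected activation time course is the task boxcar convolved with a
hemodynamic response function (HRF).  The default HRF is the canonical
double-gamma: a positive gamma peaking near 6 s minus a later undershoot
gamma near 16 s at 1/6 amplitude — the field-standard shape used by SPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, special

from .paradigm import BlockDesign, boxcar

__all__ = ["HRFModel", "double_gamma_hrf", "build_regressor"]


@dataclass(frozen=True)
class HRFModel:
    """Double-gamma HRF parameterization.

    Shape parameters follow the usual (shape, scale) gamma-density
    convention with time in seconds; ``undershoot_ratio`` is the
    peak-to-undershoot amplitude ratio.
    """

    family: str = "double-gamma"
    peak_shape: float = 6.0
    peak_scale_s: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_scale_s: float = 1.0
    undershoot_ratio: float = 6.0
    duration_s: float = 32.0

    def kernel(self, dt_s: float) -> np.ndarray:
        """Sampled causal kernel on [0, duration_s) at spacing ``dt_s``."""
        if self.family != "double-gamma":
            raise ValueError(f"unknown HRF family {self.family!r}")
        t = np.arange(0.0, self.duration_s, dt_s)
        h = _gamma_density(t, self.peak_shape, self.peak_scale_s)
        h = h - _gamma_density(t, self.undershoot_shape,
                               self.undershoot_scale_s) / self.undershoot_ratio
        area = h.sum() * dt_s
        if not (np.isfinite(area) and area > 0):
            raise ValueError("HRF kernel must integrate to a finite positive value")
        return h


def _gamma_density(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp / scale
                      - special.gammaln(shape) - shape * np.log(scale))
    return out


def double_gamma_hrf(dt_s: float, model: HRFModel | None = None) -> np.ndarray:
    """Convenience: sampled default double-gamma kernel."""
    return (model or HRFModel()).kernel(dt_s)


def build_regressor(design: BlockDesign, hrf: HRFModel | None = None,
                    normalize: bool = True) -> np.ndarray:
    """Theoretical activation model: boxcar convolved with the HRF.

    Returned aligned to the design's timeline (same length).  With
    ``normalize`` the regressor is scaled to unit peak so that simulated
    activation amplitudes are expressed directly in signal units.
    """
    box = boxcar(design)
    kern = (hrf or HRFModel()).kernel(design.frame_interval_s)
    reg = signal.fftconvolve(box, kern)[: box.size] * design.frame_interval_s
    if normalize:
        peak = np.abs(reg).max()
        if peak > 0:
            reg = reg / peak
    return reg
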