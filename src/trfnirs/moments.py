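"""Statistical moments of photon time-of-flight distributions (DTOFs).

Each 300 ms frame yields one DTOF per channel and wavelength: a histogram of
photon arrival times at 16 ps resolution.  The moments are

    N    = sum(c_i)                       total photon count
    <t>  = sum(t_i c_i) / N               mean time of flight
    V    = sum(t_i^2 c_i) / N - <t>^2     variance

computed over an integration window.  Late photons travel deeper, so changes
in <t> are preferentially sensitive to cerebral absorption; only the change
in <t> relative to a baseline window is carried downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DTOF",
    "MomentFrame",
    "MomentSeries",
    "IntegrationLimits",
    "compute_moments",
    "moments_of_recording",
    "delta_mean_tof",
]


class MomentError(ValueError):
    """DTOF unsuitable for moment computation (e.g. empty window)."""


@dataclass(frozen=True)
class DTOF:
    """One photon time-of-flight histogram.

    ``bin_counts`` may be float (background-corrected or reweighted
    histograms) but must be finite and non-negative after correction.
    """

    bin_counts: np.ndarray
    bin_width_ps: float = 16.0
    t0_offset_ps: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.bin_counts, dtype=float)
        if counts.ndim != 1 or counts.size == 0:
            raise MomentError("bin_counts must be a non-empty 1-D array")
        if not np.all(np.isfinite(counts)):
            raise MomentError("bin_counts must be finite")
        if np.any(counts < 0):
            raise MomentError("bin_counts must be non-negative")
        object.__setattr__(self, "bin_counts", counts)

    @property
    def times_ps(self) -> np.ndarray:
        """Bin-center arrival times, picoseconds."""
        return self.t0_offset_ps + np.arange(self.bin_counts.size) * self.bin_width_ps


@dataclass(frozen=True)
class MomentFrame:
    N: float
    mean_tof_ps: float
    variance_ps2: float


@dataclass(frozen=True)
class IntegrationLimits:
    """Window rule for moment integration.

    ``fraction_of_peak`` keeps the contiguous window around the peak where
    background-corrected counts exceed that fraction of the peak (common
    time-domain practice; the flanks carry mostly background).
    ``background_fraction`` estimates a constant background from that
    leading fraction of bins (pre-peak region) and subtracts it, flooring
    corrected counts at zero.  ``full()`` disables both.
    """

    fraction_of_peak: float = 0.01
    background_fraction: float = 0.10

    @classmethod
    def full(cls) -> "IntegrationLimits":
        return cls(fraction_of_peak=0.0, background_fraction=0.0)


def compute_moments(d: DTOF, limits: IntegrationLimits | None = None) -> MomentFrame:
    """Moments N, <t>, V of one DTOF over the resolved integration window."""
    limits = limits or IntegrationLimits()
    counts = d.bin_counts
    t = d.times_ps
    if limits.background_fraction > 0:
        n_bg = max(1, int(round(limits.background_fraction * counts.size)))
        counts = np.clip(counts - counts[:n_bg].mean(), 0.0, None)
    if limits.fraction_of_peak > 0:
        peak = counts.max()
        above = counts >= limits.fraction_of_peak * peak
        if peak > 0 and above.any():
            ipk = int(counts.argmax())
            lo = ipk
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = ipk
            while hi < counts.size - 1 and above[hi + 1]:
                hi += 1
            counts = counts[lo:hi + 1]
            t = t[lo:hi + 1]
    n = counts.sum()
    if n <= 0:
        raise MomentError("all-zero integration window: moments undefined")
    mean = float((t * counts).sum() / n)
    var = float((t * t * counts).sum() / n - mean * mean)
    return MomentFrame(N=float(n), mean_tof_ps=mean, variance_ps2=max(var, 0.0))


@dataclass
class MomentSeries:
    """Per-channel, per-wavelength moment time series at the frame rate.

    ``data[(channel, wavelength_nm)]`` is an (n_frames, 3) array of
    (N, mean_tof_ps, variance_ps2); ``baseline_window`` is the half-open
    frame range defining the Delta reference (default: the lead-in rest).
    """

    data: dict[tuple[str, float], np.ndarray]
    frame_interval_s: float
    baseline_window: tuple[int, int] = (0, 100)

    def __post_init__(self) -> None:
        lengths = {v.shape[0] for v in self.data.values()}
        if len(lengths) > 1:
            raise MomentError(f"inconsistent frame counts across channels: {lengths}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def mean_tof(self, channel: str, wavelength_nm: float) -> np.ndarray:
        return self.data[(channel, wavelength_nm)][:, 1]


def moments_of_recording(
    frames: np.ndarray,
    bin_width_ps: float = 16.0,
    t0_offset_ps: float = 0.0,
    limits: IntegrationLimits | None = None,
) -> np.ndarray:
    """Moments for a stack of DTOF frames, shape (n_frames, n_bins) -> (n_frames, 3)."""
    out = np.empty((frames.shape[0], 3))
    for i, row in enumerate(frames):
        m = compute_moments(DTOF(row, bin_width_ps, t0_offset_ps), limits)
        out[i] = (m.N, m.mean_tof_ps, m.variance_ps2)
    return out


def delta_mean_tof(
    series: MomentSeries,
) -> dict[tuple[str, float], np.ndarray]:
    """Change in mean time of flight relative to the baseline window.

    Delta<t>(t) = <t>(t) - mean(<t> over baseline_window), per channel and
    wavelength.
    """
    lo, hi = series.baseline_window
    if not (0 <= lo < hi <= series.n_frames):
        raise MomentError(
            f"baseline window {series.baseline_window} outside run of "
            f"{series.n_frames} frames"
        )
    out = {}
    for key, arr in series.data.items():
        mt = arr[:, 1]
        out[key] = mt - mt[lo:hi].mean()
    return out
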