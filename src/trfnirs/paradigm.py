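"""Block-design motor-imagery paradigm: timelines and task regressors.

The communication protocol is a block design: a rest lead-in followed by
``n_cycles`` alternating task/rest cycles.  The default configuration is a
30 s lead-in plus five cycles of 30 s motor imagery and 30 s rest, sampled
every 300 ms — 330 s (5:30 min) per question.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlockDesign", "Timeline", "build_timeline", "boxcar", "DEFAULT_DESIGN"]

_DIV_TOL_S = 1e-9


class ParadigmError(ValueError):
    """Invalid block-design configuration."""


@dataclass(frozen=True)
class BlockDesign:
    """Timing of one question run.

    Parameters
    ----------
    lead_in_rest_s : float
        Rest period before the first task block, seconds.
    n_cycles : int
        Number of task/rest cycles (>= 1).
    task_s : float
        Duration of each task (motor-imagery) block, seconds.
    cycle_rest_s : float
        Duration of the rest block closing each cycle, seconds.
    frame_interval_s : float
        Sampling interval of the instrument (one DTOF per frame), seconds.
    """

    lead_in_rest_s: float = 30.0
    n_cycles: int = 5
    task_s: float = 30.0
    cycle_rest_s: float = 30.0
    frame_interval_s: float = 0.3

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ParadigmError(f"n_cycles must be >= 1, got {self.n_cycles}")
        for field in ("lead_in_rest_s", "task_s", "cycle_rest_s", "frame_interval_s"):
            value = getattr(self, field)
            if not value > 0:
                raise ParadigmError(f"{field} must be > 0, got {value}")
        for field in ("lead_in_rest_s", "task_s", "cycle_rest_s"):
            value = getattr(self, field)
            n = value / self.frame_interval_s
            if abs(n - round(n)) * self.frame_interval_s > _DIV_TOL_S:
                raise ParadigmError(
                    f"{field}={value} s is not an integer multiple of "
                    f"frame_interval_s={self.frame_interval_s} s"
                )

    @property
    def cycle_s(self) -> float:
        """Duration of one task+rest cycle, seconds."""
        return self.task_s + self.cycle_rest_s

    @property
    def total_duration_s(self) -> float:
        return self.lead_in_rest_s + self.n_cycles * self.cycle_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s / self.frame_interval_s))

    def frames(self, duration_s: float) -> int:
        """Number of frames spanned by ``duration_s``."""
        return int(round(duration_s / self.frame_interval_s))


@dataclass(frozen=True)
class Timeline:
    """Sample-level view of a :class:`BlockDesign`.

    ``times`` are frame timestamps (s, frame start), strictly increasing with
    constant spacing; ``task_indicator`` is 1 on task frames, 0 on rest frames.
    """

    times: np.ndarray
    task_indicator: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.times.shape != self.task_indicator.shape:
            raise ParadigmError("times and task_indicator must have equal length")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def task_mask(self) -> np.ndarray:
        return self.task_indicator.astype(bool)

    @property
    def rest_mask(self) -> np.ndarray:
        return ~self.task_mask


def build_timeline(design: BlockDesign) -> Timeline:
    """Expand a block design into frame timestamps and a task indicator.

    Frames cover ``[0, total_duration_s)`` at ``frame_interval_s`` spacing.
    Block boundaries are half-open ``[start, end)`` so no frame is
    double-counted; the frame at t=0 belongs to the lead-in rest.
    """
    n = design.n_frames
    times = np.arange(n) * design.frame_interval_s
    indicator = np.zeros(n, dtype=float)
    for c in range(design.n_cycles):
        start = design.lead_in_rest_s + c * design.cycle_s
        end = start + design.task_s
        # half-open [start, end); nudge against float round-off
        indicator[(times >= start - _DIV_TOL_S) & (times < end - _DIV_TOL_S)] = 1.0
    return Timeline(times=times, task_indicator=indicator,
                    frame_interval_s=design.frame_interval_s)


def boxcar(design: BlockDesign) -> np.ndarray:
    """Task regressor: the 0/1 task indicator as a real vector.

    One rectangular pulse per cycle, aligned to :func:`build_timeline`.
    """
    return build_timeline(design).task_indicator.copy()


DEFAULT_DESIGN = BlockDesign()
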