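"""Block-design task protocol (rest - task - rest) on a uniform frame grid.

The verbal-fluency paradigm used throughout this package is a single task
block flanked by rest periods.  All time series live on the protocol's
frame grid; the task window is taken inclusive of both endpoints so that
closed-form checks (boxcar integrals, symmetric centroids) are exact on a
uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TaskProtocol:
    """Timing of one rest/task/rest block.

    Parameters
    ----------
    rest_pre_s : float
        Pre-task rest duration in seconds. Also the default baseline window.
    task_s : float
        Task (stimulus) duration in seconds.
    rest_post_s : float
        Post-task rest duration in seconds.
    fs_hz : float
        Frame rate of the hemodynamic time series in Hz.
    """

    rest_pre_s: float = 30.0
    task_s: float = 60.0
    rest_post_s: float = 70.0
    fs_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rest_pre_s", "task_s", "rest_post_s", "fs_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def duration_s(self) -> float:
        return self.rest_pre_s + self.task_s + self.rest_post_s

    @property
    def task_onset_s(self) -> float:
        return self.rest_pre_s

    @property
    def task_end_s(self) -> float:
        return self.rest_pre_s + self.task_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs_hz

    def task_mask(self, times: np.ndarray | None = None) -> np.ndarray:
        """Boolean mask of frames inside the task window (endpoints included)."""
        t = self.frame_times_s if times is None else np.asarray(times, float)
        return (t >= self.task_onset_s) & (t <= self.task_end_s)

    def baseline_window(self) -> tuple[float, float]:
        """Default baseline window: the whole pre-task rest."""
        return (0.0, self.rest_pre_s)

    def baseline_mask(
        self,
        times: np.ndarray | None = None,
        window: tuple[float, float] | None = None,
    ) -> np.ndarray:
        t = self.frame_times_s if times is None else np.asarray(times, float)
        w0, w1 = window if window is not None else self.baseline_window()
        if not (0.0 <= w0 < w1 <= self.rest_pre_s + 1e-9):
            raise ValueError("baseline window must lie inside the pre-task rest")
        return (t >= w0) & (t < w1)

    def tail_mask(self, times: np.ndarray | None = None, length_s: float = 20.0) -> np.ndarray:
        """Frames in the final stretch of the post-task rest (quality checks)."""
        t = self.frame_times_s if times is None else np.asarray(times, float)
        start = self.duration_s - min(length_s, self.rest_post_s / 2.0)
        return t >= start
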