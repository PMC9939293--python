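"""Frame-indexed stimulus schedules.

A recording session is a sequence of stimulus epochs (gray screen, oriented
gratings, natural-image sets) presented at a fixed imaging frame rate. The
schedule maps every imaging frame to exactly one stimulus label and keeps the
epoch table (label, kind, cycle, frame span) needed for trial averaging.

Frame-count convention: an epoch of ``duration`` seconds at ``frame_rate`` Hz
spans ``ceil(duration * frame_rate)`` frames, with half-open frame spans
``[start, stop)``. A 3-s stimulus at 4.22 Hz therefore spans 13 frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRAY = "gray"

#: Grating orientations used throughout (degrees of stimulus angle).
GRATING_ANGLES_DEG = (0, 45, 90, 135)


def grating_label(angle_deg: float) -> str:
    return f"grating_{int(angle_deg)}"


def natimg_label(set_index: int) -> str:
    return f"natimg_{'AB'[set_index]}"


def frames_for(duration_s: float, frame_rate: float) -> int:
    """Number of imaging frames spanned by an epoch (ceiling convention)."""
    return int(math.ceil(duration_s * frame_rate - 1e-9))


@dataclass
class StimulusSchedule:
    """Per-frame stimulus labels plus the epoch table of a session.

    Attributes
    ----------
    labels : array of str, one per imaging frame.
    epochs : DataFrame with columns ``label, kind, cycle, start, stop,
        duration_s, angle_deg`` (``angle_deg`` is NaN for non-gratings).
    frame_rate : imaging rate in Hz.
    image_index : per-frame natural-image index in ``0..19`` (two sets of
        ten images), ``-1`` outside natural-image epochs.
    """

    labels: np.ndarray
    epochs: pd.DataFrame
    frame_rate: float
    image_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.image_index is None:
            self.image_index = np.full(self.labels.size, -1, dtype=int)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.labels) != int(self.epochs["stop"].max() if len(self.epochs) else 0):
            raise ValueError("labels do not cover the epoch table")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def stimulus_labels(self) -> list[str]:
        """Distinct non-gray labels in presentation order of first occurrence."""
        out: list[str] = []
        for lab in self.epochs["label"]:
            if lab != GRAY and lab not in out:
                out.append(lab)
        return out

    def epochs_of(self, label: str) -> pd.DataFrame:
        """All epochs carrying ``label``, in temporal order."""
        return self.epochs[self.epochs["label"] == label].reset_index(drop=True)

    def frames_of(self, label: str) -> np.ndarray:
        """Indices of all frames carrying ``label``."""
        return np.flatnonzero(self.labels == label)

    def preceding_gray_span(self, epoch_start: int, duration_s: float) -> tuple[int, int]:
        """Frame span of the ``duration_s`` of gray screen immediately before
        the epoch starting at ``epoch_start``.

        Raises ``ValueError`` if fewer gray frames are available than requested.
        """
        n = frames_for(duration_s, self.frame_rate)
        start = epoch_start - n
        if start < 0 or not np.all(self.labels[start:epoch_start] == GRAY):
            raise ValueError(
                f"no {duration_s}-s gray window before frame {epoch_start}"
            )
        return start, epoch_start

    def to_frame(self) -> pd.DataFrame:
        """Per-frame table (frame, time_s, label, image_index)."""
        t = np.arange(self.n_frames) / self.frame_rate
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": t,
                "label": self.labels,
                "image_index": self.image_index,
            }
        )


class _ScheduleBuilder:
    def __init__(self, frame_rate: float) -> None:
        self.frame_rate = frame_rate
        self.rows: list[dict] = []
        self.labels: list[str] = []
        self.image_index: list[int] = []
        self.cursor = 0

    def add(self, label: str, duration_s: float, kind: str, cycle: int,
            angle_deg: float = np.nan, image_set: int | None = None) -> None:
        n = frames_for(duration_s, self.frame_rate)
        self.rows.append(
            dict(label=label, kind=kind, cycle=cycle, start=self.cursor,
                 stop=self.cursor + n, duration_s=duration_s, angle_deg=angle_deg)
        )
        self.labels.extend([label] * n)
        if image_set is None:
            self.image_index.extend([-1] * n)
        else:
            # ten images per 3-s set; image changes every 0.3 s
            for i in range(n):
                img = min(int(i / n * 10), 9)
                self.image_index.append(image_set * 10 + img)
        self.cursor += n

    def build(self) -> StimulusSchedule:
        return StimulusSchedule(
            labels=np.array(self.labels, dtype=object),
            epochs=pd.DataFrame(self.rows),
            frame_rate=self.frame_rate,
            image_index=np.array(self.image_index, dtype=int),
        )
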