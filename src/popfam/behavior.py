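"""Force-plate trajectory reconstruction and stimulus-zone preference.

The animal's position on a 42-cm square force-plate actometer is the
force-weighted centroid of the four corner-sensor coordinates,

    x = (X1*f1 + X2*f2 + X3*f3 + X4*f4) / (f1 + f2 + f3 + f4)

(and likewise for y), computed per sample after moving-average smoothing of
the force channels. Trajectories are down-sampled from 100 Hz to 2 Hz by
block means. Active exploration is any sample moving at >= 3 cm/s; the
stimulus-zone preference (SZP) index is the difference between exploration
time in the chamber half facing the stimulus monitor and the other half,
divided by total exploration time: +1 means all exploration near the
stimulus, negative values after familiarization indicate recognition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .synthdata import PLATE_SIDE_CM, SENSOR_XY, ForcePlateTrace

__all__ = [
    "SZPResult",
    "forces_to_position",
    "downsample",
    "exploration_mask",
    "szp_index",
]


@dataclass
class SZPResult:
    szp: float
    stimulus_zone_s: float
    non_stimulus_zone_s: float
    total_exploration_s: float
    undefined: bool = False


def forces_to_position(
    trace: ForcePlateTrace,
    smooth: bool = True,
    smoothing_window: int = 5,
) -> np.ndarray:
    """Per-sample (x, y) in cm from the four force channels.

    Forces are moving-average smoothed (window ``smoothing_window`` samples,
    50 ms at 100 Hz) before the centroid; pass ``smooth=False`` for the raw
    centroid. Samples with zero total force are interpolated from their
    neighbors.
    """
    f = np.asarray(trace.forces, dtype=float)
    if smooth:
        f = uniform_filter1d(f, size=smoothing_window, axis=0, mode="nearest")
    total = f.sum(axis=1)
    ok = total > 0
    if not ok.any():
        raise ValueError("no sample carries positive total force")
    xy = np.full((f.shape[0], 2), np.nan)
    xy[ok] = (f[ok] @ SENSOR_XY) / total[ok, None]
    if not ok.all():  # interpolate flagged zero-force samples
        idx = np.arange(f.shape[0])
        for c in range(2):
            xy[~ok, c] = np.interp(idx[~ok], idx[ok], xy[ok, c])
    return xy


def downsample(path: np.ndarray, from_hz: float = 100.0, to_hz: float = 2.0) -> np.ndarray:
    """Block-mean decimation of a path; a final partial block is dropped."""
    factor = from_hz / to_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("decimation factor must be a positive integer")
    k = int(round(factor))
    p = np.atleast_2d(np.asarray(path, dtype=float))
    n_blocks = p.shape[0] // k
    if n_blocks == 0:
        raise ValueError("path shorter than one decimation block")
    return p[: n_blocks * k].reshape(n_blocks, k, -1).mean(axis=1)


def exploration_mask(path: np.ndarray, rate_hz: float = 2.0,
                     speed_threshold: float = 3.0) -> np.ndarray:
    """Boolean per-sample mask of active exploration (speed >= 3 cm/s).

    Speed at sample i is the displacement from sample i-1 times the sample
    rate; the first sample has no defined speed and is False.
    """
    p = np.atleast_2d(np.asarray(path, dtype=float))
    if p.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute speed")
    speed = np.linalg.norm(np.diff(p, axis=0), axis=1) * rate_hz
    mask = np.zeros(p.shape[0], dtype=bool)
    mask[1:] = speed >= speed_threshold
    return mask


def szp_index(
    path: np.ndarray,
    mask: np.ndarray,
    stimulus_side: str,
    rate_hz: float = 2.0,
) -> SZPResult:
    """Stimulus-zone preference over actively explored samples.

    The zone boundary is the chamber midline perpendicular to the monitor
    axis; ``stimulus_side`` is one of left/right (x midline) or bottom/top
    (y midline). Samples exactly on the midline count as non-stimulus zone.
    A session with zero exploration time is flagged undefined.
    """
    p = np.atleast_2d(np.asarray(path, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    mid = PLATE_SIDE_CM / 2.0
    if stimulus_side == "right":
        in_sz = p[:, 0] > mid
    elif stimulus_side == "left":
        in_sz = p[:, 0] < mid
    elif stimulus_side == "top":
        in_sz = p[:, 1] > mid
    elif stimulus_side == "bottom":
        in_sz = p[:, 1] < mid
    else:
        raise ValueError(f"unknown stimulus_side: {stimulus_side!r}")
    dt = 1.0 / rate_hz
    t_sz = float(np.sum(mask & in_sz)) * dt
    t_nsz = float(np.sum(mask & ~in_sz)) * dt
    total = t_sz + t_nsz
    if total == 0:
        return SZPResult(szp=float("nan"), stimulus_zone_s=0.0,
                         non_stimulus_zone_s=0.0, total_exploration_s=0.0,
                         undefined=True)
    return SZPResult(
        szp=(t_sz - t_nsz) / total,
        stimulus_zone_s=t_sz,
        non_stimulus_zone_s=t_nsz,
        total_exploration_s=total,
    )
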