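"""Fluorescence preprocessing: neuropil correction, F0, dF/F0, spike events.

The raw cellular fluorescence F is contaminated by surrounding neuropil
signal Fneu; the corrected trace is ``Fcorr = F - 0.5 * Fneu``. The baseline
F0 is either the mode of the Fcorr density (multi-stimulus sessions) or the
mean of the 10 s of gray screen preceding stimulus onset (plasticity
sessions); activity is expressed as the fraction ``dF/F0 = (Fcorr - F0)/F0``
(0.05 means "5%"). Spike events are frames whose deconvolved activity
exceeds the per-neuron mean + 2 SD.

All thresholds are strict inequalities, matching the analysis they implement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .schedule import StimulusSchedule
from .synthdata import Recording

__all__ = [
    "ActivityTraces",
    "neuropil_correct",
    "estimate_f0_mode",
    "estimate_f0_window",
    "compute_dff",
    "threshold_events",
    "qc_filter",
    "recording_quality_flag",
    "preprocess",
]


@dataclass
class ActivityTraces:
    """Preprocessed per-neuron activity for one session.

    dff : dimensionless dF/F0 matrix (neurons x frames).
    f0 : per-neuron baseline fluorescence (a.u.).
    events : deconvolved amplitudes surviving the mean + 2 SD threshold
        (sub-threshold entries are zero).
    binary : {0,1} indicator of spike-event frames.
    kept : per-neuron QC mask (True = analyzed).
    """

    dff: np.ndarray
    f0: np.ndarray
    events: np.ndarray
    binary: np.ndarray
    kept: np.ndarray
    schedule: StimulusSchedule

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def frame_rate(self) -> float:
        return self.schedule.frame_rate


def neuropil_correct(F: np.ndarray, Fneu: np.ndarray, coeff: float = 0.5) -> np.ndarray:
    """Subtract scaled neuropil: ``Fcorr = F - coeff * Fneu``."""
    F = np.asarray(F, dtype=float)
    Fneu = np.asarray(Fneu, dtype=float)
    if F.shape != Fneu.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs Fneu {Fneu.shape}")
    if not 0.0 <= coeff <= 1.0:
        raise ValueError("correction coefficient must be in [0, 1]")
    return F - coeff * Fneu


def estimate_f0_mode(trace: np.ndarray, grid_points: int = 512) -> float:
    """Baseline F0 as the mode of the trace's kernel density estimate.

    Gaussian KDE with Silverman bandwidth, evaluated on a ``grid_points``
    grid spanning [min, max]; ties break toward the smaller value. A
    constant trace returns that constant.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 samples to estimate F0")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in trace")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])  # argmax returns first (smaller) tie


def estimate_f0_window(
    trace: np.ndarray,
    schedule: StimulusSchedule,
    window_s: float = 10.0,
) -> float:
    """Baseline F0 as the mean over the ``window_s`` of gray screen
    immediately preceding the first stimulus epoch (plasticity sessions)."""
    stim = schedule.epochs[schedule.epochs["kind"] != "gray"]
    if stim.empty:
        raise ValueError("schedule has no stimulus epoch")
    onset = int(stim.iloc[0]["start"])
    start, stop = schedule.preceding_gray_span(onset, window_s)
    return float(np.mean(np.asarray(trace, dtype=float)[..., start:stop]))


def compute_dff(Fcorr: np.ndarray, F0: np.ndarray | float) -> np.ndarray:
    """Fractional fluorescence change ``(Fcorr - F0) / F0``; requires F0 > 0."""
    F0 = np.asarray(F0, dtype=float)
    if np.any(F0 <= 0):
        raise ValueError("F0 must be positive")
    f0_col = F0[..., None] if F0.ndim == 1 else F0
    return (np.asarray(Fcorr, dtype=float) - f0_col) / f0_col


def threshold_events(deconv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep deconvolved amplitudes strictly above mean + 2 SD per neuron.

    The mean and SD are computed over the full trace including zeros. A
    zero-variance trace yields zero events.
    """
    d = np.atleast_2d(np.asarray(deconv, dtype=float))
    if np.any(d < 0):
        raise ValueError("deconvolved activity must be nonnegative")
    thr = d.mean(axis=1) + 2.0 * d.std(axis=1)
    events = np.where(d > thr[:, None], d, 0.0)
    binary = (events > 0).astype(np.int8)
    if deconv.ndim == 1:
        return events[0], binary[0]
    return events, binary


def qc_filter(
    dff: np.ndarray,
    f0: np.ndarray,
    mode: str = "multistim",
    peak_threshold: float = 0.10,
) -> np.ndarray:
    """Per-neuron quality mask.

    multistim: keep neurons with at least one dF/F0 peak strictly greater
    than ``peak_threshold`` (10%) anywhere in the session.
    plasticity: additionally drop neurons whose F0 lies strictly outside
    mean +/- 2 SD of the population F0.
    """
    if mode not in ("multistim", "plasticity"):
        raise ValueError(f"unknown mode: {mode!r}")
    kept = np.max(dff, axis=1) > peak_threshold
    if mode == "plasticity":
        mu, sd = float(np.mean(f0)), float(np.std(f0))
        kept &= (f0 >= mu - 2.0 * sd) & (f0 <= mu + 2.0 * sd)
    return kept


def recording_quality_flag(
    dff: np.ndarray,
    schedule: StimulusSchedule,
    novel_label: str,
    min_mean_dff: float = 0.01,
) -> bool:
    """True when the recording fails the session-quality check: the mean
    population dF/F0 during the novel stimulus is below ``min_mean_dff`` (1%)."""
    frames = schedule.frames_of(novel_label)
    if frames.size == 0:
        raise ValueError(f"stimulus {novel_label!r} absent from schedule")
    return float(np.mean(dff[:, frames])) < min_mean_dff


def preprocess(recording: Recording, mode: str = "multistim",
               neuropil_coeff: float = 0.5) -> ActivityTraces:
    """Full preprocessing chain for one session.

    Neuropil-corrects, estimates F0 (mode-based for multistim sessions,
    pre-stimulus-window mean for plasticity sessions), computes dF/F0,
    thresholds spike events, and applies the per-neuron QC filter.
    """
    Fcorr = neuropil_correct(recording.F, recording.Fneu, neuropil_coeff)
    if mode == "multistim":
        f0 = np.array([estimate_f0_mode(row) for row in Fcorr])
    elif mode == "plasticity":
        f0 = np.array(
            [estimate_f0_window(row, recording.schedule) for row in Fcorr]
        )
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if np.any(f0 <= 0):
        bad = np.flatnonzero(f0 <= 0)
        raise ValueError(f"non-positive F0 for neurons {bad.tolist()}")
    dff = compute_dff(Fcorr, f0)
    events, binary = threshold_events(recording.deconv)
    kept = qc_filter(dff, f0, mode=mode)
    return ActivityTraces(dff=dff, f0=f0, events=events, binary=binary,
                          kept=kept, schedule=recording.schedule)
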