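"""Trial-averaged responses, active-neuron classification, AUC summaries.

A neuron is "active" for a stimulus when its trial-averaged stimulus dF/F0
exceeds a threshold — strictly greater than 5% (high threshold) or than
2 SD of the baseline dF/F0 (low threshold) — AND the per-trial stimulus
means differ from the per-trial means of the gray screen immediately
preceding each presentation (p < 0.05, two-sided paired t test).

The low-threshold criterion is the permissive one: a neuron passing the
high threshold is by definition active at the low threshold as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import StimulusSchedule, frames_for
from .traces import ActivityTraces

__all__ = [
    "TrialAverage",
    "trial_average",
    "plasticity_windows",
    "classify_active",
    "classify_active_plasticity",
    "compute_auc",
    "response_fractions",
    "active_fraction",
]


@dataclass
class TrialAverage:
    """Per-neuron trial-averaged response to one stimulus.

    trace : neurons x epoch_frames mean dF/F0 across trials.
    gray_trace : neurons x epoch_frames trial-averaged trace of the
        equally long gray window immediately preceding each presentation.
    stim_trial_means / gray_trial_means : neurons x trials per-trial means,
        paired for the t test.
    """

    stimulus: str
    trace: np.ndarray
    gray_trace: np.ndarray
    stim_trial_means: np.ndarray
    gray_trial_means: np.ndarray
    n_trials: int
    dt: float


def trial_average(
    dff: np.ndarray, schedule: StimulusSchedule, stimulus: str,
    baseline_s: float = 3.0,
) -> TrialAverage:
    """Average the dF/F0 response to ``stimulus`` across its trials (cycles),
    pairing each trial with the ``baseline_s`` of preceding gray screen."""
    eps = schedule.epochs_of(stimulus)
    if eps.empty:
        raise ValueError(f"stimulus {stimulus!r} absent from schedule")
    n_frames_epoch = int((eps["stop"] - eps["start"]).min())
    stim_traces, gray_traces = [], []
    for _, ep in eps.iterrows():
        s = int(ep["start"])
        stim_traces.append(dff[:, s : s + n_frames_epoch])
        g0, g1 = schedule.preceding_gray_span(s, baseline_s)
        gray_traces.append(dff[:, g0:g1])
    stim = np.stack(stim_traces)  # trials x neurons x frames
    gray = np.stack(gray_traces)
    return TrialAverage(
        stimulus=stimulus,
        trace=stim.mean(axis=0),
        gray_trace=gray.mean(axis=0),
        stim_trial_means=stim.mean(axis=2).T,
        gray_trial_means=gray.mean(axis=2).T,
        n_trials=len(eps),
        dt=schedule.dt,
    )


def _paired_p(stim_means: np.ndarray, gray_means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t test per neuron; returns (p, degenerate_flag).

    Zero-variance pairings make the t statistic undefined: identical trials
    get p = 1 (no difference), a constant nonzero difference gets p = 0
    (classified by threshold only) — both flagged degenerate.
    """
    diff = stim_means - gray_means
    sd = diff.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_rel(stim_means, gray_means, axis=1).pvalue
    p = np.where(degenerate, np.where(np.abs(diff.mean(axis=1)) > 0, 0.0, 1.0), p)
    return p, degenerate


def classify_active(
    ta: TrialAverage,
    mode: str = "high",
    high_threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each neuron's response to one stimulus.

    Returns a DataFrame with per-neuron columns ``mean_dff``, ``p``,
    ``passes_high``, ``passes_low``, ``active`` (at the requested ``mode``'s
    threshold) and ``category`` in {active_high, weak, nonresponsive}.

    The low threshold is 2 SD of the trial-averaged preceding-gray trace
    (frame-wise SD); a neuron passing the high threshold also counts as
    passing the low criterion.
    """
    if mode not in ("high", "low"):
        raise ValueError(f"unknown mode: {mode!r}")
    if ta.n_trials < 2:
        raise ValueError("need at least 2 trials")
    mean_dff = ta.stim_trial_means.mean(axis=1)
    baseline_sd = ta.gray_trace.std(axis=1)
    p, degenerate = _paired_p(ta.stim_trial_means, ta.gray_trial_means)
    sig = p < alpha
    passes_high = mean_dff > high_threshold
    passes_low = passes_high | (mean_dff > 2.0 * baseline_sd)
    active = sig & (passes_high if mode == "high" else passes_low)
    category = np.where(
        sig & passes_high,
        "active_high",
        np.where(sig & passes_low, "weak", "nonresponsive"),
    )
    return pd.DataFrame(
        {
            "mean_dff": mean_dff,
            "p": p,
            "passes_high": passes_high,
            "passes_low": passes_low,
            "active": active,
            "category": category,
            "degenerate_test": degenerate,
        }
    )


def plasticity_windows(schedule: StimulusSchedule, window_s: float = 10.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices of the first ``window_s`` of stimulus and the equally
    long gray window preceding stimulus onset (plasticity sessions)."""
    stim = schedule.epochs[schedule.epochs["kind"] != "gray"]
    if stim.empty:
        raise ValueError("schedule has no stimulus epoch")
    onset = int(stim.iloc[0]["start"])
    n = frames_for(window_s, schedule.frame_rate)
    g0, g1 = schedule.preceding_gray_span(onset, window_s)
    return np.arange(onset, onset + n), np.arange(g0, g1)


def classify_active_plasticity(
    traces: ActivityTraces,
    window_s: float = 10.0,
    high_threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Active classification for single-stimulus plasticity sessions.

    Uses the first ``window_s`` of stimulus against the ``window_s`` of gray
    before onset, pairing frame-wise (there is a single trial).
    """
    stim_fr, gray_fr = plasticity_windows(traces.schedule, window_s)
    stim = traces.dff[:, stim_fr]
    gray = traces.dff[:, gray_fr[: len(stim_fr)]]
    stim = stim[:, : gray.shape[1]]
    mean_dff = stim.mean(axis=1)
    p, degenerate = _paired_p(stim, gray)
    active = (p < alpha) & (mean_dff > high_threshold)
    return pd.DataFrame(
        {"mean_dff": mean_dff, "p": p, "active": active,
         "degenerate_test": degenerate}
    )


def compute_auc(trace: np.ndarray, dt: float) -> np.ndarray | float:
    """Trapezoidal area under a dF/F0 trace (units dF/F0 * s).

    ``trace`` may be 1-D (one neuron) or 2-D (neurons x frames); ``dt`` is
    the frame interval in seconds.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    auc = np.trapezoid(trace, dx=dt, axis=-1)
    return float(auc) if np.ndim(auc) == 0 else auc


def response_fractions(
    window_dff: np.ndarray, thresholds: tuple[float, ...] = (0.15,)
) -> dict[float, float]:
    """Fraction of neurons whose mean window dF/F0 is strictly above each
    threshold (e.g. 0.15 for the "high-responding" 15% cut)."""
    means = np.asarray(window_dff, dtype=float)
    if means.ndim == 2:
        means = means.mean(axis=1)
    if means.size == 0:
        raise ValueError("empty population")
    return {float(t): float(np.mean(means > t)) for t in thresholds}


def active_fraction(active_by_stimulus: np.ndarray) -> float:
    """Fraction of identified neurons active for at least one stimulus.

    ``active_by_stimulus`` is a boolean neurons x stimuli matrix.
    """
    a = np.atleast_2d(np.asarray(active_by_stimulus, dtype=bool))
    if a.size == 0:
        raise ValueError("empty population")
    return float(np.mean(a.any(axis=1)))
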