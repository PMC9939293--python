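"""Synthetic recordings, dendrite tables, and force-plate traces.

Every downstream stage of the pipeline is testable without external data
because this module generates recordings with known ground truth:

* Poisson-spiking neurons whose grating responses follow the von Mises
  orientation-tuning curve ``A * exp(K * (cos(2*(phi - theta)) - 1)) + b``
  and whose natural-image responses are per-image multiplicative gains on the
  baseline rate;
* planted co-firing ensembles (member set, event rate, participation);
* fluorescence built from the spikes through an exponential calcium kernel
  (decay constant ``calcium_tau``) on a per-neuron baseline, contaminated by
  a shared neuropil background and i.i.d. Gaussian noise;
* a "deconvolved" activity matrix equal to the ground-truth spikes plus small
  Gaussian jitter (the pipeline consumes deconvolved activity; it never runs
  a deconvolution algorithm itself);
* bivariate-lognormal dendritic excitatory/inhibitory synapse densities with
  an exact target Pearson correlation;
* force-plate traces whose four corner-sensor forces are the bilinear weights
  of a scripted path, so the centroid formula recovers the path exactly.

All randomness flows from ``numpy.random.default_rng`` seeded from the
config; a fixed seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .schedule import (
    GRAY,
    GRATING_ANGLES_DEG,
    StimulusSchedule,
    _ScheduleBuilder,
    grating_label,
    natimg_label,
)

__all__ = [
    "SynthConfig",
    "TrainingEffect",
    "EnsembleSpec",
    "GroundTruth",
    "Recording",
    "generate_schedule",
    "generate_population",
    "generate_dendrites",
    "generate_forceplate",
    "PLATE_SIDE_CM",
    "SENSOR_XY",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class EnsembleSpec:
    """A planted co-firing ensemble.

    members : neuron indices belonging to the ensemble.
    event_rate : ensemble co-firing events per second.
    participation : probability that a member fires in an event frame.
    duration_frames : mean event duration in frames (geometric).
    """

    members: tuple[int, ...]
    event_rate: float
    participation: float = 1.0
    duration_frames: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must be in [0, 1]")
        if self.event_rate < 0:
            raise ValueError("event_rate must be nonnegative")


@dataclass(frozen=True)
class TrainingEffect:
    """Multiplicative "training" factors applied to a post-training session.

    evoked : scales every stimulus-evoked firing-rate component.
    high_responder : scales the fraction of strongly tuned neurons.
    persistence : scales the mean ensemble-event duration (frames), i.e. how
        long a co-active pattern lingers.
    """

    evoked: float = 1.0
    high_responder: float = 1.0
    persistence: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters of a synthetic imaging session.

    Defaults emulate the acquisition conditions of the study: ~80 neurons
    imaged at 4.22 Hz, GCaMP decay constant 2.0 s, and the multi-stimulus
    session layout (30 s gray, then 8 cycles of four 3-s gratings and two
    3-s natural-image sets, each preceded by 6 s of gray).
    """

    seed: int = 0
    n_neurons: int = 80
    frame_rate: float = 4.22
    schedule_kind: str = "multistim"  # or "plasticity"
    baseline_rate: float = 0.3  # spontaneous events/s
    calcium_tau: float = 2.0  # s
    spike_amp: float = 0.3  # dF/F0 per spike event
    noise_sd: float = 2.0  # fluorescence a.u.
    neuropil_scale: float = 30.0  # neuropil background level, a.u.
    contamination: float = 0.5  # fraction of neuropil mixed into F
    deconv_jitter_sd: float = 0.05
    f0_range: tuple[float, float] = (80.0, 120.0)
    # tuning: fraction of neurons strongly tuned, their rate gain and width
    tuned_fraction: float = 0.5
    tuned_rate: float = 2.0  # events/s at preferred orientation
    untuned_rate: float = 0.2
    kappa_mean: float = 1.5
    tuning_offset: float = 0.0  # additive grating-evoked offset rate b
    # natural images: per-image multiplicative gain on the baseline rate
    ni_gain_sigma: float = 1.0
    # plasticity-session grating orientation (deg)
    plasticity_angle: float = 45.0
    ensemble_spec: tuple[EnsembleSpec, ...] = ()
    tuning_params: pd.DataFrame | None = None  # columns theta, K, A, b
    ni_gains: np.ndarray | None = None  # n_neurons x 20
    training: TrainingEffect | None = None
    n_cycles: int = 8

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.untuned_rate < 0 or self.tuned_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.schedule_kind not in ("multistim", "plasticity"):
            raise ValueError(f"unknown schedule_kind: {self.schedule_kind!r}")

    def with_training(self, effect: TrainingEffect) -> "SynthConfig":
        return replace(self, training=effect)


@dataclass
class Recording:
    """Raw matrices of one imaging session (neurons x frames)."""

    F: np.ndarray
    Fneu: np.ndarray
    deconv: np.ndarray
    schedule: StimulusSchedule

    def __post_init__(self) -> None:
        if not (self.F.shape == self.Fneu.shape == self.deconv.shape):
            raise ValueError("F, Fneu and deconv must share shape")
        if self.F.shape[1] != self.schedule.n_frames:
            raise ValueError("matrices do not cover the schedule frames")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def frame_rate(self) -> float:
        return self.schedule.frame_rate


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    spikes: np.ndarray  # neurons x frames, counts
    tuning_params: pd.DataFrame  # theta, K, A, b per neuron
    ni_gains: np.ndarray  # neurons x 20
    ensemble_members: list[np.ndarray]
    ensemble_event_frames: list[np.ndarray]
    f0_true: np.ndarray


# ---------------------------------------------------------------------------
# schedules


def generate_schedule(config: SynthConfig) -> StimulusSchedule:
    """Build the session's stimulus schedule.

    ``multistim``: 30 s gray, then ``n_cycles`` cycles, each containing the
    four gratings (0/45/90/135 deg, 3 s each) and two natural-image sets
    (3 s each) in per-cycle shuffled order, each preceded by 6 s of gray.

    ``plasticity``: 60 s gray followed by one 100-s grating block.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    b = _ScheduleBuilder(config.frame_rate)
    if config.schedule_kind == "multistim":
        b.add(GRAY, 30.0, "gray", -1)
        stimuli = [("grating", a) for a in GRATING_ANGLES_DEG] + [
            ("natimg", s) for s in (0, 1)
        ]
        for cycle in range(config.n_cycles):
            order = rng.permutation(len(stimuli))
            for idx in order:
                kind, which = stimuli[idx]
                b.add(GRAY, 6.0, "gray", cycle)
                if kind == "grating":
                    b.add(grating_label(which), 3.0, "grating", cycle,
                          angle_deg=float(which))
                else:
                    b.add(natimg_label(which), 3.0, "natimg", cycle,
                          image_set=which)
    elif config.schedule_kind == "plasticity":
        b.add(GRAY, 60.0, "gray", -1)
        b.add(grating_label(config.plasticity_angle), 100.0, "grating", 0,
              angle_deg=float(config.plasticity_angle))
    else:  # pragma: no cover - guarded by SynthConfig
        raise ValueError(f"unknown schedule_kind: {config.schedule_kind!r}")
    return b.build()


# ---------------------------------------------------------------------------
# population recordings


def default_tuning_params(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random per-neuron von Mises tuning parameters.

    A ``tuned_fraction`` of neurons gets rate gain ``tuned_rate`` (the
    "high responders"); the rest get ``untuned_rate``. Preferred orientations
    are uniform on [0, pi); widths K are lognormal around ``kappa_mean``.
    """
    n = config.n_neurons
    frac = config.tuned_fraction
    if config.training is not None:
        frac = min(1.0, frac * config.training.high_responder)
    n_tuned = int(round(frac * n))
    A = np.full(n, config.untuned_rate)
    tuned_idx = rng.choice(n, size=n_tuned, replace=False)
    A[tuned_idx] = config.tuned_rate
    theta = rng.uniform(0.0, np.pi, size=n)
    K = np.exp(rng.normal(np.log(config.kappa_mean), 0.3, size=n))
    b = np.full(n, config.tuning_offset)
    return pd.DataFrame({"theta": theta, "K": K, "A": A, "b": b})


def von_mises_rate(phi: np.ndarray, theta: float, K: float, A: float, b: float) -> np.ndarray:
    """Orientation-tuned firing rate A*exp(K*(cos(2*(phi-theta))-1)) + b."""
    return A * np.exp(K * (np.cos(2.0 * (np.asarray(phi) - theta)) - 1.0)) + b


def _ensemble_spikes(
    spec: EnsembleSpec,
    n_neurons: int,
    n_frames: int,
    frame_rate: float,
    rng: np.random.Generator,
    persistence: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spikes contributed by one planted ensemble and its event frames."""
    spikes = np.zeros((n_neurons, n_frames), dtype=np.int64)
    p_event = min(1.0, spec.event_rate / frame_rate)
    starts = np.flatnonzero(rng.random(n_frames) < p_event)
    dur_mean = max(1.0, spec.duration_frames * persistence)
    event_frames: set[int] = set()
    for s in starts:
        dur = rng.geometric(1.0 / dur_mean) if dur_mean > 1.0 else 1
        event_frames.update(range(s, min(s + dur, n_frames)))
    frames = np.array(sorted(event_frames), dtype=int)
    members = np.asarray(spec.members, dtype=int)
    for t in frames:
        fire = rng.random(members.size) < spec.participation
        spikes[members[fire], t] += 1
    return spikes, frames


def generate_population(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one imaging session and return it with its ground truth."""
    root = np.random.SeedSequence([int(config.seed), 17])
    rng_params, rng_spikes, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    schedule = generate_schedule(config)
    n, T = config.n_neurons, schedule.n_frames
    fr = schedule.frame_rate

    tuning = (
        config.tuning_params
        if config.tuning_params is not None
        else default_tuning_params(config, rng_params)
    )
    if not np.isfinite(tuning[["theta", "K", "A", "b"]].to_numpy()).all():
        raise ValueError("non-finite tuning parameters")
    ni_gains = (
        np.asarray(config.ni_gains, dtype=float)
        if config.ni_gains is not None
        else np.exp(rng_params.normal(0.0, config.ni_gain_sigma, size=(n, 20)))
    )
    evoked_scale = config.training.evoked if config.training is not None else 1.0
    persistence = config.training.persistence if config.training is not None else 1.0

    # per-frame firing rates (events/s)
    rates = np.full((n, T), float(config.baseline_rate))
    for _, ep in schedule.epochs.iterrows():
        sl = slice(int(ep["start"]), int(ep["stop"]))
        if ep["kind"] == "grating":
            phi = np.deg2rad(ep["angle_deg"])
            evoked = von_mises_rate(
                phi, tuning["theta"].to_numpy(), tuning["K"].to_numpy(),
                tuning["A"].to_numpy(), tuning["b"].to_numpy()
            )
            rates[:, sl] += evoked_scale * evoked[:, None]
        elif ep["kind"] == "natimg":
            imgs = schedule.image_index[sl]
            gain = ni_gains[:, imgs]  # n x epoch_frames
            rates[:, sl] += evoked_scale * config.baseline_rate * (gain - 1.0)
    rates = np.clip(rates, 0.0, None)
    if not np.isfinite(rates).all():
        raise ValueError("non-finite firing rates")

    spikes = rng_spikes.poisson(rates / fr).astype(np.int64)
    members_list, events_list = [], []
    for spec in config.ensemble_spec:
        es, frames = _ensemble_spikes(spec, n, T, fr, rng_spikes, persistence)
        spikes += es
        members_list.append(np.asarray(spec.members, dtype=int))
        events_list.append(frames)

    # calcium: exact exponential filter c[t] = decay * c[t-1] + spikes[t]
    decay = np.exp(-1.0 / (config.calcium_tau * fr))
    c = np.empty_like(spikes, dtype=float)
    c[:, 0] = spikes[:, 0]
    for t in range(1, T):
        c[:, t] = decay * c[:, t - 1] + spikes[:, t]

    f0_true = rng_noise.uniform(*config.f0_range, size=n)
    # shared slow neuropil background + per-channel noise
    slow = gaussian_filter1d(rng_noise.normal(0.0, 1.0, size=T), sigma=20.0)
    slow = 1.0 + 0.1 * slow / max(slow.std(), 1e-12)
    npil = config.neuropil_scale * slow[None, :] * np.ones((n, 1))
    Fneu = npil + rng_noise.normal(0.0, config.noise_sd, size=(n, T))
    F = (
        f0_true[:, None] * (1.0 + config.spike_amp * c)
        + config.contamination * npil
        + rng_noise.normal(0.0, config.noise_sd, size=(n, T))
    )
    deconv = spikes + (
        rng_noise.normal(0.0, config.deconv_jitter_sd, size=(n, T))
        if config.deconv_jitter_sd > 0
        else 0.0
    )
    deconv = np.clip(deconv, 0.0, None)

    rec = Recording(F=F, Fneu=Fneu, deconv=deconv, schedule=schedule)
    truth = GroundTruth(
        spikes=spikes,
        tuning_params=tuning,
        ni_gains=ni_gains,
        ensemble_members=members_list,
        ensemble_event_frames=events_list,
        f0_true=f0_true,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# dendrite tables


def generate_dendrites(
    n_dendrites: int = 100,
    target_r: float = 0.43,
    mean_e_per_100um: float = 50.0,
    mean_i_per_100um: float = 25.0,
    sigma_log: float = 0.25,
    mean_length_um: float = 60.0,
    compartment: str = "apical",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-dendrite synapse table with a target E/I density correlation.

    Densities are bivariate lognormal. The target Pearson correlation applies
    on the density (lognormal) scale; the underlying normal correlation is
    obtained from the exact lognormal moment identity
    ``r = (exp(rho*s1*s2) - 1) / sqrt((exp(s1^2)-1)*(exp(s2^2)-1))``.

    Counts are rounded ``density x length``; the excitatory count is split
    into PSD95+ spines and dually innervated spines (DIS), the inhibitory
    count into shaft gephyrin and the same DIS.
    """
    if not -1.0 < target_r < 1.0:
        raise ValueError("target correlation must be in (-1, 1)")
    if n_dendrites < 3:
        raise ValueError("need at least 3 dendrites")
    s = sigma_log
    denom = np.sqrt((np.exp(s**2) - 1.0) ** 2)
    rho = np.log(1.0 + target_r * denom) / (s * s)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("target correlation not attainable at this sigma_log")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    cov = np.array([[s * s, rho * s * s], [rho * s * s, s * s]])
    logd = rng.multivariate_normal(
        [np.log(mean_e_per_100um), np.log(mean_i_per_100um)], cov, size=n_dendrites
    )
    dens = np.exp(logd)  # per 100 um
    length = np.exp(rng.normal(np.log(mean_length_um), 0.3, size=n_dendrites))
    e_counts = np.rint(dens[:, 0] / 100.0 * length).astype(int)
    i_counts = np.rint(dens[:, 1] / 100.0 * length).astype(int)
    # dually innervated spines: ~18% of excitatory, capped by inhibitory count
    dis = np.minimum(np.rint(0.18 * e_counts).astype(int), i_counts)
    return pd.DataFrame(
        {
            "dendrite_id": np.arange(n_dendrites),
            "cell_id": np.arange(n_dendrites) // 4,
            "compartment": compartment,
            "length_um": length,
            "psd95_spines": e_counts - dis,
            "psd95_negative_spines": np.rint(0.2 * (e_counts - dis)).astype(int),
            "dual_innervated_spines": dis,
            "shaft_gephyrin": i_counts - dis,
            "session_id": 0,
        }
    )


# ---------------------------------------------------------------------------
# force plate


PLATE_SIDE_CM = 42.0
#: corner sensor coordinates (cm), sensors 1..4 counter-clockwise from origin
SENSOR_XY = np.array(
    [[0.0, 0.0], [PLATE_SIDE_CM, 0.0], [PLATE_SIDE_CM, PLATE_SIDE_CM], [0.0, PLATE_SIDE_CM]]
)


@dataclass
class ForcePlateTrace:
    """Four corner-sensor force channels sampled at ``rate_hz``."""

    forces: np.ndarray  # samples x 4, a.u.
    rate_hz: float = 100.0
    stimulus_side: str = "right"

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 4:
            raise ValueError("forces must be samples x 4")
        if np.any(self.forces < 0):
            raise ValueError("forces must be nonnegative")


def generate_forceplate(
    waypoints_cm: np.ndarray,
    n_samples: int | None = None,
    total_force: float = 1.0,
    rate_hz: float = 100.0,
    stimulus_side: str = "right",
) -> ForcePlateTrace:
    """Forces of a scripted path by bilinear weight distribution.

    The animal's weight at position (x, y) is split over the four corner
    sensors with bilinear weights, so the force-weighted centroid of the
    sensor coordinates recovers (x, y) exactly (machine precision). Waypoints
    are linearly interpolated to ``n_samples`` positions (default: one sample
    per waypoint).
    """
    wp = np.atleast_2d(np.asarray(waypoints_cm, dtype=float))
    if np.any(wp < 0) or np.any(wp > PLATE_SIDE_CM):
        raise ValueError("waypoints must lie inside the 42-cm plate")
    if n_samples is None or n_samples == len(wp):
        path = wp
    else:
        s = np.linspace(0.0, 1.0, len(wp))
        si = np.linspace(0.0, 1.0, n_samples)
        path = np.column_stack([np.interp(si, s, wp[:, 0]), np.interp(si, s, wp[:, 1])])
    u = path[:, 0] / PLATE_SIDE_CM
    v = path[:, 1] / PLATE_SIDE_CM
    # weights matched to SENSOR_XY order
    w = np.column_stack([(1 - u) * (1 - v), u * (1 - v), u * v, (1 - u) * v])
    return ForcePlateTrace(forces=total_force * w, rate_hz=rate_hz,
                           stimulus_side=stimulus_side)
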