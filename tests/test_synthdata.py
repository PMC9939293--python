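"""Generator tests: schedules, spike statistics, ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popfam import (
    EnsembleSpec,
    SynthConfig,
    generate_dendrites,
    generate_forceplate,
    generate_population,
    generate_schedule,
)
from popfam.behavior import forces_to_position
from popfam.schedule import GRAY, frames_for
from popfam.synapses import ei_correlation
from popfam.synthdata import von_mises_rate


class TestSchedule:
    @pytest.mark.parametrize(
        "duration,rate,expected",
        [(3.0, 4.22, 13), (3.0, 1.0, 3), (6.0, 4.22, 26), (30.0, 4.22, 127),
         (10.0, 4.22, 43)],
    )
    def test_frame_count_ceiling_convention(self, duration, rate, expected):
        assert frames_for(duration, rate) == expected

    def test_multistim_structure(self):
        sch = generate_schedule(SynthConfig(seed=4))
        # every frame carries exactly one label and epochs tile the session
        assert sch.labels.size == sch.epochs["stop"].max()
        spans = sch.epochs[["start", "stop"]].to_numpy()
        assert (spans[1:, 0] == spans[:-1, 1]).all()
        # per-cycle label multiset identical across cycles
        per_cycle = [
            sorted(sch.epochs.query("cycle == @c and kind != 'gray'")["label"])
            for c in range(8)
        ]
        assert all(pc == per_cycle[0] for pc in per_cycle)
        assert len(per_cycle[0]) == 6
        # 3-s stimuli span 13 frames each at 4.22 Hz
        stim = sch.epochs.query("kind != 'gray'")
        assert ((stim["stop"] - stim["start"]) == 13).all()

    def test_shuffled_order_differs_between_cycles(self):
        sch = generate_schedule(SynthConfig(seed=4))
        orders = [
            tuple(sch.epochs.query("cycle == @c and kind != 'gray'")["label"])
            for c in range(8)
        ]
        assert len(set(orders)) > 1

    def test_plasticity_layout(self):
        sch = generate_schedule(SynthConfig(seed=1, schedule_kind="plasticity"))
        assert list(sch.epochs["kind"]) == ["gray", "grating"]
        assert sch.epochs.iloc[0]["stop"] == frames_for(60, 4.22)
        n_stim = sch.epochs.iloc[1]["stop"] - sch.epochs.iloc[1]["start"]
        assert n_stim == frames_for(100, 4.22)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="schedule_kind"):
            SynthConfig(schedule_kind="bogus")


class TestPopulation:
    def test_same_seed_is_byte_identical(self):
        cfg = SynthConfig(seed=9, n_neurons=12)
        r1, t1 = generate_population(cfg)
        r2, t2 = generate_population(cfg)
        for a, b in ((r1.F, r2.F), (r1.Fneu, r2.Fneu), (r1.deconv, r2.deconv),
                     (t1.spikes, t2.spikes)):
            assert a.tobytes() == b.tobytes()

    def test_evoked_counts_rank_as_von_mises_rates(self):
        # one strongly tuned neuron, no noise/ensembles: grating spike counts
        # rank-order exactly as the tuning-curve rates
        theta = np.deg2rad(30.0)
        tuning = pd.DataFrame({"theta": [theta], "K": [2.0], "A": [60.0], "b": [0.0]})
        cfg = SynthConfig(seed=2, n_neurons=1, baseline_rate=0.0, noise_sd=0.0,
                          deconv_jitter_sd=0.0, tuning_params=tuning,
                          ni_gains=np.ones((1, 20)))
        rec, truth = generate_population(cfg)
        sch = rec.schedule
        counts, rates = [], []
        for ang in (0, 45, 90, 135):
            fr = sch.frames_of(f"grating_{ang}")
            counts.append(truth.spikes[0, fr].sum())
            rates.append(von_mises_rate(np.deg2rad(ang), theta, 2.0, 60.0, 0.0))
        assert list(np.argsort(counts)) == list(np.argsort(rates))

    def test_mean_rate_within_3se(self):
        cfg = SynthConfig(seed=5, n_neurons=50, baseline_rate=0.4,
                          tuned_rate=0.0, untuned_rate=0.0,
                          ni_gains=np.ones((50, 20)))
        rec, truth = generate_population(cfg)
        T = rec.n_frames
        lam = 0.4 / cfg.frame_rate
        total = truth.spikes.sum()
        se = np.sqrt(50 * T * lam)
        assert abs(total - 50 * T * lam) < 3 * se

    def test_planted_ensemble_coactivation(self):
        members = tuple(range(10))
        spec = EnsembleSpec(members=members, event_rate=0.2, participation=1.0)
        cfg = SynthConfig(seed=6, n_neurons=20, baseline_rate=0.0,
                          tuned_rate=0.0, untuned_rate=0.0,
                          ensemble_spec=(spec,), ni_gains=np.ones((20, 20)))
        rec, truth = generate_population(cfg)
        frames = truth.ensemble_event_frames[0]
        assert (truth.spikes[np.ix_(members, frames)] >= 1).all()
        # empirical event rate within 3 binomial SDs of expectation
        T = rec.n_frames
        p = 0.2 / cfg.frame_rate
        assert abs(frames.size - T * p) < 3 * np.sqrt(T * p * (1 - p))

    def test_calcium_kernel_time_constant(self):
        # the fluorescence of a single isolated spike decays with the
        # configured calcium_tau (fitted from the generated trace)
        tuning = pd.DataFrame({"theta": [0.0], "K": [1.0], "A": [0.0], "b": [0.0]})
        spec = EnsembleSpec(members=(0,), event_rate=0.004, participation=1.0)
        cfg = SynthConfig(seed=3, n_neurons=1, baseline_rate=0.0, noise_sd=0.0,
                          neuropil_scale=0.0, deconv_jitter_sd=0.0,
                          tuning_params=tuning, ni_gains=np.ones((1, 20)),
                          ensemble_spec=(spec,), calcium_tau=2.0)
        rec, truth = generate_population(cfg)
        spikes = truth.spikes[0]
        events = np.flatnonzero(spikes)
        # pick an event with a clean 50-frame decay window after it
        isolated = [
            e for e in events
            if e + 50 < rec.n_frames and spikes[e + 1 : e + 51].sum() == 0
        ]
        assert isolated, "generator produced no isolated event"
        e = isolated[0]
        f0 = truth.f0_true[0]
        dff = (rec.F[0] - f0) / f0  # noise-free: dff = amp * kernel
        tail = dff[e : e + 40]
        t = np.arange(tail.size) / cfg.frame_rate
        slope = np.polyfit(t, np.log(tail), 1)[0]
        assert abs(-1.0 / slope - cfg.calcium_tau) / cfg.calcium_tau < 0.10

    def test_nonfinite_parameters_rejected(self):
        tuning = pd.DataFrame({"theta": [np.nan], "K": [1.0], "A": [1.0], "b": [0.0]})
        cfg = SynthConfig(seed=0, n_neurons=1, tuning_params=tuning)
        with pytest.raises(ValueError, match="non-finite"):
            generate_population(cfg)


class TestDendrites:
    def test_target_correlation_recovered(self):
        table = generate_dendrites(n_dendrites=2000, target_r=0.43, seed=1)
        r, _, n = ei_correlation(table)
        assert n == 2000
        assert abs(r - 0.43) < 0.05

    def test_null_correlation(self):
        table = generate_dendrites(n_dendrites=2000, target_r=0.0, seed=2)
        r, _, _ = ei_correlation(table)
        assert abs(r) < 3 / np.sqrt(2000)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            generate_dendrites(target_r=1.0)
        with pytest.raises(ValueError):
            generate_dendrites(n_dendrites=2)


class TestForcePlate:
    def test_corner_and_center_geometry(self):
        tr = generate_forceplate(np.array([[0.0, 0.0], [21.0, 21.0]]))
        assert np.allclose(tr.forces[0], [1, 0, 0, 0])
        assert np.allclose(tr.forces[1], 0.25)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        wp = rng.uniform(1, 41, size=(20, 2))
        tr = generate_forceplate(wp, n_samples=500)
        s = np.linspace(0, 1, 20)
        si = np.linspace(0, 1, 500)
        path = np.column_stack([np.interp(si, s, wp[:, 0]), np.interp(si, s, wp[:, 1])])
        rec = forces_to_position(tr, smooth=False)
        assert np.abs(rec - path).max() < 1e-9

    def test_waypoints_outside_plate_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            generate_forceplate(np.array([[50.0, 10.0]]))
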