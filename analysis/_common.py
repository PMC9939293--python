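"""Shared demo-session definitions for the numbered analysis scripts.

The demo multi-stimulus session: 80 neurons at 4.22 Hz, half of them
orientation tuned, with two planted 18-neuron ensembles whose co-firing
events dominate their frames (as stimulus-evoked coactivations do). Every
script regenerates it deterministically if the cached container is absent,
so each script runs standalone.
"""

from pathlib import Path

from popfam import EnsembleSpec, SynthConfig, generate_population
from popfam.io import read_recording, write_recording

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

DEMO_SEED = 42

DEMO_ENSEMBLES = (
    EnsembleSpec(members=tuple(range(18)), event_rate=0.15, participation=0.95),
    EnsembleSpec(members=tuple(range(18, 36)), event_rate=0.15, participation=0.95),
)


def demo_config() -> SynthConfig:
    return SynthConfig(
        seed=DEMO_SEED,
        n_neurons=80,
        baseline_rate=0.2,
        tuned_rate=1.5,
        ensemble_spec=DEMO_ENSEMBLES,
    )


def demo_recording():
    """Cached (Recording, GroundTruth) of the demo session."""
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    path = SCRATCH / "multistim_demo.h5"
    rec, truth = generate_population(demo_config())
    if not path.exists():
        write_recording(path, rec, truth)
    return rec, truth
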