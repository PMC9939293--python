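"""Generate the demo imaging session and verify its ground truth.

Writes the HDF5 container to scratch/ and a session overview to results/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, SCRATCH, demo_config, demo_recording


def main() -> None:
    cfg = demo_config()
    rec, truth = demo_recording()
    sch = rec.schedule
    stim_epochs = sch.epochs[sch.epochs["kind"] != "gray"]
    overview = {
        "n_neurons": rec.n_neurons,
        "n_frames": rec.n_frames,
        "frame_rate_hz": sch.frame_rate,
        "duration_s": rec.n_frames / sch.frame_rate,
        "n_cycles": int(stim_epochs["cycle"].max()) + 1,
        "frames_per_stimulus": int(
            (stim_epochs["stop"] - stim_epochs["start"]).iloc[0]
        ),
        "stimuli": sorted(sch.stimulus_labels()),
        "planted_ensembles": [
            {"n_members": len(s.members), "event_rate_hz": s.event_rate,
             "participation": s.participation}
            for s in cfg.ensemble_spec
        ],
        "total_ground_truth_spikes": int(truth.spikes.sum()),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "session_overview.json").write_text(json.dumps(overview, indent=2))
    print(f"Simulated {rec.n_neurons} neurons x {rec.n_frames} frames "
          f"({overview['duration_s']:.0f} s at {sch.frame_rate} Hz).")
    print(f"Each 3-s stimulus spans {overview['frames_per_stimulus']} frames; "
          f"{overview['n_cycles']} cycles of 6 stimuli.")
    print(f"Planted {len(cfg.ensemble_spec)} ensembles of "
          f"{[len(s.members) for s in cfg.ensemble_spec]} neurons.")
    print(f"Container: {SCRATCH / 'multistim_demo.h5'}")
    print(f"Overview: {RESULTS / 'session_overview.json'}")


if __name__ == "__main__":
    main()
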