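"""Preprocess the demo session: neuropil correction, F0, dF/F0, events, QC.

Reports how close the mode-based F0 lands to the generator's true baseline
and what fraction of neurons survive the 10%-peak quality filter.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, demo_recording

from popfam import preprocess


def main() -> None:
    rec, truth = demo_recording()
    act = preprocess(rec, mode="multistim")
    rel_f0 = (act.f0 - truth.f0_true) / truth.f0_true
    table = pd.DataFrame(
        {
            "f0": act.f0,
            "f0_true": truth.f0_true,
            "f0_relative_error": rel_f0,
            "max_dff": act.dff.max(axis=1),
            "event_rate_hz": act.binary.mean(axis=1) * rec.frame_rate,
            "kept": act.kept,
        }
    )
    table.to_csv(RESULTS / "preprocess_neurons.csv", index_label="neuron")
    summary = {
        "kept_fraction": float(act.kept.mean()),
        "median_f0_relative_error": float(np.median(rel_f0)),
        "mean_event_rate_hz": float(table["event_rate_hz"].mean()),
        "binary_rate": float(act.binary.mean()),
    }
    (RESULTS / "preprocess_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"Kept {int(act.kept.sum())}/{act.n_neurons} neurons "
          f"(>10% dF/F0 peak filter).")
    print(f"Mode-based F0 sits {100 * summary['median_f0_relative_error']:.1f}% "
          f"above the true baseline (median) - ongoing activity shifts the "
          f"fluorescence density upward slightly.")
    print(f"Mean thresholded event rate: {summary['mean_event_rate_hz']:.2f} "
          f"events/s per neuron.")


if __name__ == "__main__":
    main()
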