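"""HDF5 containers and delimited tables for recordings and results.

A recording container holds ``/F``, ``/Fneu``, ``/deconv`` (neurons x
frames), the schedule under ``/schedule`` (per-frame labels, epoch table
columns, frame rate) and, when present, the generator's ground truth under
``/truth/*``. Delimited tables are comma-separated with a header row.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .schedule import StimulusSchedule
from .synthdata import GroundTruth, Recording

__all__ = ["write_recording", "read_recording", "read_forces_csv"]

_EPOCH_COLS = ("label", "kind", "cycle", "start", "stop", "duration_s", "angle_deg")


def _write_schedule(grp: h5py.Group, schedule: StimulusSchedule) -> None:
    grp.create_dataset("labels", data=np.array(schedule.labels, dtype="S32"))
    grp.create_dataset("image_index", data=schedule.image_index)
    grp.attrs["frame_rate"] = schedule.frame_rate
    ep = grp.create_group("epochs")
    for col in _EPOCH_COLS:
        vals = schedule.epochs[col].to_numpy()
        if vals.dtype == object:
            vals = vals.astype("S32")
        ep.create_dataset(col, data=vals)


def _read_schedule(grp: h5py.Group) -> StimulusSchedule:
    labels = grp["labels"][()].astype(str)
    epochs = pd.DataFrame(
        {
            col: (
                grp["epochs"][col][()].astype(str)
                if grp["epochs"][col].dtype.kind == "S"
                else grp["epochs"][col][()]
            )
            for col in _EPOCH_COLS
        }
    )
    return StimulusSchedule(
        labels=labels.astype(object),
        epochs=epochs,
        frame_rate=float(grp.attrs["frame_rate"]),
        image_index=grp["image_index"][()],
    )


def write_recording(path: str | Path, recording: Recording,
                    truth: GroundTruth | None = None) -> None:
    """Write a recording (and optional ground truth) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=recording.F)
        f.create_dataset("Fneu", data=recording.Fneu)
        f.create_dataset("deconv", data=recording.deconv)
        _write_schedule(f.create_group("schedule"), recording.schedule)
        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("spikes", data=truth.spikes)
            tg.create_dataset("ni_gains", data=truth.ni_gains)
            tg.create_dataset("f0_true", data=truth.f0_true)
            for col in ("theta", "K", "A", "b"):
                tg.create_dataset(f"tuning_{col}", data=truth.tuning_params[col].to_numpy())
            for j, (mem, ev) in enumerate(
                zip(truth.ensemble_members, truth.ensemble_event_frames)
            ):
                tg.create_dataset(f"ensemble_{j}_members", data=mem)
                tg.create_dataset(f"ensemble_{j}_events", data=ev)


def read_recording(path: str | Path) -> Recording:
    """Load and validate a recording container."""
    with h5py.File(path, "r") as f:
        for name in ("F", "Fneu", "deconv", "schedule"):
            if name not in f:
                raise ValueError(f"missing dataset {name!r} in {path}")
        F = f["F"][()]
        Fneu = f["Fneu"][()]
        deconv = f["deconv"][()]
        schedule = _read_schedule(f["schedule"])
    for name, mat in (("F", F), ("Fneu", Fneu), ("deconv", deconv)):
        if mat.shape != F.shape:
            raise ValueError(f"dataset {name!r} shape {mat.shape} != F {F.shape}")
        if not np.isfinite(mat).all():
            raise ValueError(f"dataset {name!r} contains non-finite values")
    if F.shape[1] != schedule.n_frames:
        raise ValueError(
            f"schedule covers {schedule.n_frames} frames but F has {F.shape[1]}"
        )
    return Recording(F=F, Fneu=Fneu, deconv=deconv, schedule=schedule)


def read_forces_csv(path: str | Path) -> np.ndarray:
    """Read a 4-column force table (f1..f4, header row) as samples x 4."""
    df = pd.read_csv(path)
    if df.shape[1] != 4:
        raise ValueError(f"expected 4 force columns, got {df.shape[1]}")
    return df.to_numpy(dtype=float)
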