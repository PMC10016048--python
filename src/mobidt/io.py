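"""Readers and writers for the pipeline's columnar and HDF5 dialects.

Events: CSV with columns block, trial_idx, onset_ms, trial_type, image_id,
motor_condition, response_ms.  Gait: CSV per foot with t, X, Y, Z (meters).
Epochs: HDF5 with datasets data[epoch, channel, time] (microvolts), channel
labels, positions, time vector (ms) and condition attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import EpochSet, GaitTrace

EVENT_COLUMNS = [
    "block", "trial_idx", "onset_ms", "trial_type",
    "image_id", "motor_condition", "response_ms",
]


def write_events_csv(path, trials: pd.DataFrame) -> None:
    trials.reindex(columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"trial_type": str, "motor_condition": str})


def write_gait_csv(path, trace: GaitTrace) -> None:
    pd.DataFrame(
        {"t": trace.t, "X": trace.xyz[:, 0], "Y": trace.xyz[:, 1], "Z": trace.xyz[:, 2]}
    ).to_csv(path, index=False)


def read_gait_csv(path, foot: str, sample_rate: float | None = None) -> GaitTrace:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(float)
    if sample_rate is None:
        sample_rate = 1.0 / np.median(np.diff(t))
    return GaitTrace(
        foot=foot,
        sample_rate=float(sample_rate),
        t=t,
        xyz=df[["X", "Y", "Z"]].to_numpy(float),
    )


def write_epochs_h5(path, epochs: EpochSet) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, compression="gzip")
        fh.create_dataset("ch_names", data=np.array(epochs.ch_names, dtype="S"))
        fh.create_dataset("positions", data=epochs.positions)
        fh.create_dataset("times_ms", data=epochs.times_ms)
        fh.attrs["sfreq"] = epochs.sfreq
        fh.attrs["lock"] = epochs.lock
        fh.attrs["cognitive"] = epochs.cognitive
        fh.attrs["motor"] = epochs.motor


def read_epochs_h5(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as fh:
        return EpochSet(
            data=fh["data"][()],
            ch_names=[s.decode() for s in fh["ch_names"][()]],
            positions=fh["positions"][()],
            sfreq=float(fh.attrs["sfreq"]),
            times_ms=fh["times_ms"][()],
            lock=str(fh.attrs["lock"]),
            cognitive=str(fh.attrs["cognitive"]),
            motor=str(fh.attrs["motor"]),
        )
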