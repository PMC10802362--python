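"""HDF5 recording container and JSON sensor-geometry sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import SensorArray
from .synthcohort import Recording

__all__ = ["save_recording", "load_recording", "save_pseudo_t_image",
           "save_virtual_electrode", "save_connectome", "save_burst_raster"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".sensors.json")


def save_recording(rec: Recording, path) -> None:
    """Write a recording to ``<path>`` (HDF5) + ``<path>.sensors.json``.

    Layout: ``/data`` (channels x samples, float64 tesla), ``/fs``,
    ``/trials`` (onset_sample, condition), flag sets as attributes.
    """
    path = Path(path)
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("data", data=rec.data)
        d.attrs["units"] = "T"
        fh.create_dataset("fs", data=float(rec.fs))
        trials = fh.create_group("trials")
        trials.create_dataset(
            "onset_sample",
            data=rec.trial_table["onset_sample"].to_numpy(dtype=np.int64))
        trials.create_dataset(
            "condition",
            data=np.array(rec.trial_table["condition"], dtype="S16"))
        fh.attrs["bad_channels"] = sorted(int(i) for i in rec.bad_channels)
        fh.attrs["bad_trials"] = sorted(int(i) for i in rec.bad_trials)

    arr = rec.array
    sidecar = {
        "positions_m": arr.sensor_positions.tolist(),
        "axes": arr.sensor_axes.tolist(),
        "channel_labels": list(arr.channel_labels),
        "scalp_offset_m": arr.scalp_offset,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)


def load_recording(path) -> Recording:
    """Read a recording written by :func:`save_recording`."""
    path = Path(path)
    with open(_sidecar_path(path)) as fh:
        sc = json.load(fh)
    array = SensorArray(np.asarray(sc["positions_m"]),
                        np.asarray(sc["axes"]),
                        tuple(sc["channel_labels"]),
                        float(sc["scalp_offset_m"]))
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        fs = float(fh["fs"][()])
        table = pd.DataFrame({
            "onset_sample": fh["trials/onset_sample"][()],
            "condition": [c.decode() for c in fh["trials/condition"][()]],
        })
        bad_ch = set(int(i) for i in fh.attrs.get("bad_channels", []))
        bad_tr = set(int(i) for i in fh.attrs.get("bad_trials", []))
    return Recording(data, fs, table, array, bad_ch, bad_tr)


def save_pseudo_t_image(image, path) -> None:
    """Write a pseudo-T volume: voxel grid (m), spacing and values."""
    with h5py.File(Path(path), "w") as fh:
        fh.create_dataset("grid", data=image.grid)
        fh.create_dataset("values", data=image.values)
        fh.create_dataset("spacing", data=float(image.spacing))
        fh["grid"].attrs["units"] = "m"


def save_virtual_electrode(ve, path) -> None:
    """Write a virtual-electrode time series with its location metadata."""
    with h5py.File(Path(path), "w") as fh:
        d = fh.create_dataset("timecourse", data=ve.timecourse)
        d.attrs["units"] = "A m (arbitrary scale)"
        fh.create_dataset("fs", data=float(ve.fs))
        fh.create_dataset("location", data=np.asarray(ve.location))
        fh.create_dataset("band", data=np.asarray(ve.band, dtype=float))
        fh.attrs["voxel_index"] = int(ve.voxel_index)


def save_connectome(matrix, labels, path) -> None:
    """Write a labelled connectome matrix as CSV."""
    frame = pd.DataFrame(np.asarray(matrix), index=list(labels),
                         columns=list(labels))
    frame.to_csv(Path(path), float_format="%.8g", lineterminator="\n")


def save_burst_raster(posterior, burst_state: int, trial_table, rec_fs: float,
                      path) -> None:
    """Write the trial x time binary burst raster for one state as CSV.

    Rows are trials, columns samples at the posterior's rate; samples not
    covered by the embedding are left empty.
    """
    binary = posterior.binary()[:, burst_state].astype(float)
    full = posterior.full_length(binary)
    ratio = posterior.fs / rec_fs
    onsets = np.sort(trial_table["onset_sample"].to_numpy())
    tl = int(np.floor(np.min(np.diff(onsets)) * ratio)) if onsets.size > 1 \
        else full.size
    rows = []
    for o in onsets:
        lo = int(round(o * ratio))
        if lo + tl <= full.size:
            rows.append(full[lo:lo + tl])
    frame = pd.DataFrame(np.asarray(rows))
    frame.index.name = "trial"
    frame.to_csv(Path(path), float_format="%.0f", lineterminator="\n")
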