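"""Recording container and label-table I/O.

Recordings are stored one per HDF5 group with float64 datasets ``con`` and
``rar`` (epochs x samples, µV) and the stimulus/recording metadata as group
attributes.  Labels travel as plain CSV with columns
``recording_id,rater_id,round,response_present``.
"""

from __future__ import annotations

import os
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .types import EpochMatrix, LabelRecord, Polarity, Recording, StimulusSpec

__all__ = [
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
]

_STIMULUS_PREFIX = "stimulus_"
_KNOWN_ATTRS = ("recording_id", "electrode", "timing", "ground_truth", "sampling_rate")


def write_recording(rec: Recording, path: str | os.PathLike, *,
                    group: str = "/", overwrite: bool = False) -> None:
    """Write a :class:`Recording` to an HDF5 file.

    Raises ``FileExistsError`` if ``path`` exists and ``overwrite`` is False.
    Voltages are stored as float64 and round-trip bit-identically.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite and group == "/":
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    mode = "w" if (group == "/" or not os.path.exists(path)) else "a"
    with h5py.File(path, mode) as f:
        g = f if group == "/" else f.require_group(group)
        g.create_dataset("con", data=rec.con.samples, dtype=np.float64)
        g.create_dataset("rar", data=rec.rar.samples, dtype=np.float64)
        g.attrs["sampling_rate"] = float(rec.sampling_rate)
        g.attrs["recording_id"] = rec.recording_id
        g.attrs["electrode"] = int(rec.electrode)
        g.attrs["timing"] = rec.timing
        if rec.ground_truth is not None:
            g.attrs["ground_truth"] = bool(rec.ground_truth)
        for k, v in rec.stimulus.to_attrs().items():
            g.attrs[_STIMULUS_PREFIX + k] = v
        for k, v in rec.extra_attrs.items():
            if k not in g.attrs:
                g.attrs[k] = v


def read_recording(path: str | os.PathLike, *, group: str = "/") -> Recording:
    """Read a :class:`Recording` written by :func:`write_recording`.

    Unknown extra attributes are preserved in ``Recording.extra_attrs``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        g = f if group == "/" else f[group]
        for name in ("con", "rar"):
            if name not in g:
                raise ValueError(f"{path}: missing polarity dataset {name!r}")
        con = np.asarray(g["con"], dtype=np.float64)
        rar = np.asarray(g["rar"], dtype=np.float64)
        attrs = dict(g.attrs)
    if con.shape != rar.shape:
        raise ValueError(f"{path}: CON shape {con.shape} != RAR shape {rar.shape}")
    fs = float(attrs.pop("sampling_rate"))
    stim_attrs = {
        k[len(_STIMULUS_PREFIX):]: v
        for k, v in attrs.items()
        if k.startswith(_STIMULUS_PREFIX)
    }
    if "frequency" in stim_attrs:
        stim_attrs["frequency"] = int(stim_attrs["frequency"])
    stimulus = StimulusSpec.from_attrs(stim_attrs)
    gt = attrs.get("ground_truth", None)
    extra = {
        k: v for k, v in attrs.items()
        if not k.startswith(_STIMULUS_PREFIX) and k not in _KNOWN_ATTRS
    }
    return Recording(
        con=EpochMatrix(con, fs, Polarity.CON),
        rar=EpochMatrix(rar, fs, Polarity.RAR),
        stimulus=stimulus,
        recording_id=str(attrs.get("recording_id", "")),
        electrode=int(attrs.get("electrode", 1)),
        timing=str(attrs.get("timing", "intraoperative")),
        ground_truth=None if gt is None else bool(gt),
        extra_attrs=extra,
    )


def write_labels(labels: Iterable[LabelRecord] | pd.DataFrame,
                 path: str | os.PathLike) -> None:
    """Write label records to CSV (one row per recording x rater x round)."""
    if isinstance(labels, pd.DataFrame):
        df = labels[["recording_id", "rater_id", "round", "response_present"]]
    else:
        df = pd.DataFrame(
            [(l.recording_id, l.rater_id, l.round, l.response_present) for l in labels],
            columns=["recording_id", "rater_id", "round", "response_present"],
        )
    df.to_csv(path, index=False)


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read a label CSV; validates one label per (recording, rater, round)."""
    df = pd.read_csv(
        path,
        dtype={"recording_id": str, "rater_id": str, "round": int, "response_present": bool},
    )
    required = {"recording_id", "rater_id", "round", "response_present"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label file missing columns: {sorted(missing)}")
    if not df["round"].isin((1, 2)).all():
        raise ValueError("label rounds must be 1 or 2")
    dup = df.duplicated(["recording_id", "rater_id", "round"])
    if dup.any():
        raise ValueError("duplicate (recording_id, rater_id, round) label entries")
    return df
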