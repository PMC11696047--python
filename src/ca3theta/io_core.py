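"""Reading and writing session bundles.

Two equivalent on-disk formats:

``csv-bundle``
    A directory of typed tables -- ``meta.yaml`` (ids, labels, sampling
    rates), ``spikes.csv`` (unit_id, t), ``tracking.csv`` (t, x, y),
    ``trials.csv`` (t_start, t_end) and ``lfp.npz`` (one array per channel).
    Chosen for inspectability; everything except the LFP is plain text.

``hdf5``
    A single HDF5 file with the same content, for large LFP payloads.

Both round-trip bit-exactly: floats written to CSV use Python's shortest
round-trip repr, and npz/HDF5 store raw float64.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
import yaml

from .session import (
    FormatError,
    LfpChannel,
    Session,
    SpikeUnit,
    TrackingSeries,
)

__all__ = ["read_session", "write_session"]

_FORMATS = ("csv-bundle", "hdf5")


def write_session(session: Session, path: str, format: str = "csv-bundle") -> None:
    """Write ``session`` to ``path`` in the given format (validates first)."""
    session.validate()
    if format == "csv-bundle":
        _write_bundle(session, path)
    elif format == "hdf5":
        _write_hdf5(session, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def read_session(path: str, format: str = "csv-bundle") -> Session:
    """Read a session from ``path``; the result satisfies all invariants."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "csv-bundle":
        session = _read_bundle(path)
    elif format == "hdf5":
        session = _read_hdf5(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    session.validate()
    return session


# ---------------------------------------------------------------- csv bundle


def _write_bundle(session: Session, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "group_label": session.group_label,
        "tracking": {"frame_rate": float(session.tracking.frame_rate)},
        "units": [u.unit_id for u in session.units],
        "lfp": [
            {"channel_id": c.channel_id, "fs": float(c.fs), "t0": float(c.t0)}
            for c in session.lfp
        ],
        "meta": session.meta,
    }
    with open(os.path.join(path, "meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)

    rows = [
        pd.DataFrame({"unit_id": u.unit_id, "t": u.spike_times})
        for u in session.units
    ]
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame({"unit_id": pd.Series(dtype=str), "t": pd.Series(dtype=float)})
    )
    spikes.to_csv(os.path.join(path, "spikes.csv"), index=False)

    pd.DataFrame(
        {"t": session.tracking.t, "x": session.tracking.x, "y": session.tracking.y}
    ).to_csv(os.path.join(path, "tracking.csv"), index=False)

    pd.DataFrame(session.trials, columns=["t_start", "t_end"]).to_csv(
        os.path.join(path, "trials.csv"), index=False
    )

    np.savez(
        os.path.join(path, "lfp.npz"),
        **{c.channel_id: c.samples for c in session.lfp},
    )


def _require(path: str, name: str) -> str:
    full = os.path.join(path, name)
    if not os.path.exists(full):
        raise FormatError(f"session bundle at {path!r} is missing required table {name!r}")
    return full


def _read_bundle(path: str) -> Session:
    with open(_require(path, "meta.yaml")) as fh:
        meta = yaml.safe_load(fh)

    # round_trip parsing keeps the shortest-repr floats bit-exact
    spikes = pd.read_csv(
        _require(path, "spikes.csv"),
        dtype={"unit_id": str, "t": float},
        float_precision="round_trip",
    )
    tracking = pd.read_csv(_require(path, "tracking.csv"), float_precision="round_trip")
    trials = pd.read_csv(_require(path, "trials.csv"), float_precision="round_trip")
    lfp_file = _require(path, "lfp.npz")

    units = []
    grouped = {k: g["t"].to_numpy() for k, g in spikes.groupby("unit_id")}
    for uid in meta.get("units", sorted(grouped)):
        units.append(SpikeUnit(str(uid), grouped.get(str(uid), np.empty(0))))

    with np.load(lfp_file) as npz:
        lfp = [
            LfpChannel(
                entry["channel_id"],
                float(entry["fs"]),
                npz[entry["channel_id"]],
                t0=float(entry.get("t0", 0.0)),
            )
            for entry in meta.get("lfp", [])
        ]

    return Session(
        session_id=str(meta["session_id"]),
        units=units,
        tracking=TrackingSeries(
            tracking["t"].to_numpy(),
            tracking["x"].to_numpy(),
            tracking["y"].to_numpy(),
            frame_rate=float(meta["tracking"]["frame_rate"]),
        ),
        lfp=lfp,
        trials=list(zip(trials["t_start"], trials["t_end"])),
        group_label=str(meta.get("group_label", "SYNTH")),
        meta=meta.get("meta", {}) or {},
    )


# --------------------------------------------------------------------- hdf5


def _write_hdf5(session: Session, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["group_label"] = session.group_label
        gu = f.create_group("units")
        for u in session.units:
            gu.create_dataset(u.unit_id, data=u.spike_times)
        gt = f.create_group("tracking")
        gt.attrs["frame_rate"] = session.tracking.frame_rate
        gt.create_dataset("t", data=session.tracking.t)
        gt.create_dataset("x", data=session.tracking.x)
        gt.create_dataset("y", data=session.tracking.y)
        gl = f.create_group("lfp")
        for c in session.lfp:
            d = gl.create_dataset(c.channel_id, data=c.samples)
            d.attrs["fs"] = c.fs
            d.attrs["t0"] = c.t0
        f.create_dataset(
            "trials", data=np.asarray(session.trials, dtype=float).reshape(-1, 2)
        )


def _read_hdf5(path: str) -> Session:
    with h5py.File(path, "r") as f:
        for name in ("units", "tracking", "lfp", "trials"):
            if name not in f:
                raise FormatError(f"hdf5 session {path!r} is missing required table {name!r}")
        units = [SpikeUnit(uid, f["units"][uid][()]) for uid in f["units"]]
        gt = f["tracking"]
        tracking = TrackingSeries(
            gt["t"][()], gt["x"][()], gt["y"][()], frame_rate=float(gt.attrs["frame_rate"])
        )
        lfp = [
            LfpChannel(
                cid,
                float(f["lfp"][cid].attrs["fs"]),
                f["lfp"][cid][()],
                t0=float(f["lfp"][cid].attrs.get("t0", 0.0)),
            )
            for cid in f["lfp"]
        ]
        trials = [tuple(row) for row in f["trials"][()]]
        return Session(
            session_id=str(f.attrs["session_id"]),
            units=units,
            tracking=tracking,
            lfp=lfp,
            trials=trials,
            group_label=str(f.attrs["group_label"]),
        )
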