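"""Session-bundle persistence.

A session is stored as a directory holding one HDF5 file for the matrices
(``session.h5``: /traces, optional /neuropil, /behavior/xy, optional
/dropped_frame_mask; frame rates and ids as attributes) plus human-editable
CSV sidecars for the event table (``events.csv``) and neuron metadata
(``neurons.csv``).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    BehaviorTrack,
    EventTable,
    FormatError,
    NeuronRecord,
    SessionBundle,
)

H5_NAME = "session.h5"
EVENTS_NAME = "events.csv"
NEURONS_NAME = "neurons.csv"


def write_session_bundle(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a bundle to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / H5_NAME, "w") as f:
        f.create_dataset("traces", data=bundle.traces)
        if bundle.neuropil is not None:
            f.create_dataset("neuropil", data=bundle.neuropil)
        if bundle.dropped_frame_mask is not None:
            f.create_dataset("dropped_frame_mask", data=bundle.dropped_frame_mask)
        f.attrs["frame_rate_hz"] = bundle.frame_rate_hz
        f.attrs["animal_id"] = bundle.animal_id
        f.attrs["session_id"] = bundle.session_id
        if bundle.behavior is not None:
            g = f.create_group("behavior")
            g.create_dataset("xy", data=bundle.behavior.xy)
            g.attrs["frame_rate_hz"] = bundle.behavior.frame_rate_hz
            g.attrs["bodypoint"] = bundle.behavior.bodypoint
    # %.17g keeps float64 round-trips bitwise exact through the CSV sidecars
    bundle.events.df.to_csv(path / EVENTS_NAME, index=False, float_format="%.17g")
    pd.DataFrame(
        [
            dict(
                neuron_id=n.neuron_id,
                ap_mm=n.ap_mm,
                ml_mm=n.ml_mm,
                dv_mm=n.dv_mm,
                subtype=n.subtype,
            )
            for n in bundle.neurons
        ]
    ).to_csv(path / NEURONS_NAME, index=False, float_format="%.17g")
    return path


def read_session_bundle(path: str | Path) -> SessionBundle:
    """Read and validate a bundle written by :func:`write_session_bundle`."""
    path = Path(path)
    h5_path = path / H5_NAME
    if not h5_path.exists():
        raise FormatError(f"no {H5_NAME} under {path}")
    ev_path = path / EVENTS_NAME
    if not ev_path.exists():
        raise FormatError(f"no {EVENTS_NAME} under {path}")
    with h5py.File(h5_path, "r") as f:
        if "traces" not in f:
            raise FormatError(f"{h5_path} lacks a /traces matrix")
        traces = f["traces"][()]
        neuropil = f["neuropil"][()] if "neuropil" in f else None
        mask = (
            f["dropped_frame_mask"][()].astype(bool)
            if "dropped_frame_mask" in f
            else None
        )
        rate = float(f.attrs["frame_rate_hz"])
        animal = str(f.attrs.get("animal_id", "animal0"))
        session = str(f.attrs.get("session_id", "session0"))
        behavior = None
        if "behavior" in f:
            g = f["behavior"]
            behavior = BehaviorTrack(
                xy=g["xy"][()],
                frame_rate_hz=float(g.attrs["frame_rate_hz"]),
                bodypoint=str(g.attrs.get("bodypoint", "center")),
            )
    # round_trip parsing keeps float64 values bitwise identical
    events = EventTable(pd.read_csv(ev_path, float_precision="round_trip"))
    neurons = []
    n_path = path / NEURONS_NAME
    if n_path.exists():
        for _, row in pd.read_csv(
            n_path, float_precision="round_trip"
        ).iterrows():
            neurons.append(
                NeuronRecord(
                    neuron_id=str(row["neuron_id"]),
                    ap_mm=float(row["ap_mm"]),
                    ml_mm=float(row["ml_mm"]),
                    dv_mm=float(row["dv_mm"]),
                    subtype=str(row["subtype"]),
                )
            )
    return SessionBundle(
        traces=np.asarray(traces),
        frame_rate_hz=rate,
        events=events,
        neuropil=neuropil,
        behavior=behavior,
        neurons=neurons,
        animal_id=animal,
        session_id=session,
        dropped_frame_mask=mask,
    )
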