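"""On-disk formats: the HDF5 epochs container, TSV sidecars, EDF/BDF input.

The package's native container is a small HDF5 layout:

    /data            float64 (n_trials, n_channels, n_samples), µV
    /times           float64 (n_samples,), ms relative to stimulus onset
    /channel_names   UTF-8 strings
    attrs: fs        sampling rate, Hz
    /trial_meta/<col>  one dataset per metadata column

Continuous recordings are stored the same way with a single pseudo-trial.
Events and thought probes travel as TSV. EDF/BDF recordings (BioSemi
exports) are read through MNE; no EDF writer is bundled.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, ProbeResponse, probes_to_frame

__all__ = [
    "save_epochs",
    "load_epochs",
    "write_events_tsv",
    "read_events_tsv",
    "write_probes_tsv",
    "read_probes_tsv",
    "read_raw_edf",
    "save_session",
]


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an :class:`EpochSet` to the package HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times", data=epochs.times)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["fs"] = epochs.fs
        grp = f.create_group("trial_meta")
        for col in epochs.trial_meta.columns:
            values = epochs.trial_meta[col].to_numpy()
            if values.dtype == object:
                values = np.array([str(v) for v in values], dtype=h5py.string_dtype())
            grp.create_dataset(col, data=values)
        grp.attrs["columns"] = json.dumps(list(epochs.trial_meta.columns))


def load_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet` back from the HDF5 container."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        channel_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f["channel_names"][()]
        ]
        fs = float(f.attrs["fs"])
        meta = {}
        grp = f["trial_meta"]
        order = json.loads(grp.attrs["columns"])
        for col in order:
            vals = grp[col][()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array(
                    [v.decode() if isinstance(v, bytes) else str(v) for v in vals]
                )
            meta[col] = vals
    return EpochSet(
        data=data,
        times=times,
        fs=fs,
        channel_names=channel_names,
        trial_meta=pd.DataFrame(meta),
    )


def write_events_tsv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_probes_tsv(path, probes: Sequence[ProbeResponse]) -> None:
    probes_to_frame(probes).to_csv(path, sep="\t", index=False)


def read_probes_tsv(path) -> List[ProbeResponse]:
    df = pd.read_csv(path, sep="\t")

    def _opt(v):
        return None if pd.isna(v) else int(v)

    return [
        ProbeResponse(
            probe_index=int(r["probe_index"]),
            after_trial=int(r["after_trial"]),
            content_option=int(r["content_option"]),
            stickiness=_opt(r.get("stickiness")),
            self_focus=_opt(r.get("self_focus")),
            valence=_opt(r.get("valence")),
        )
        for _, r in df.iterrows()
    ]


def read_raw_edf(path) -> Tuple[np.ndarray, float, List[str]]:
    """Read an EDF/BDF recording; returns (µV array ch×samples, fs, names)."""
    import mne

    path = Path(path)
    reader = (
        mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    )
    raw = reader(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def save_session(out_dir, session) -> None:
    """Persist a simulated session: HDF5 recording + events/probes/behavior TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = EpochSet(
        data=session.recording[None, :, :],
        times=np.arange(session.recording.shape[1]) * 1000.0 / session.fs,
        fs=session.fs,
        channel_names=session.channel_names,
        trial_meta=pd.DataFrame({"trial_index": [0]}),
    )
    save_epochs(out / "recording.h5", rec)
    write_events_tsv(out / "events.tsv", session.events)
    write_probes_tsv(out / "probes.tsv", session.probes)
    session.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    session.true_states.to_csv(out / "true_states.tsv", sep="\t", index=False)
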