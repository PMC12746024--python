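"""File I/O: HDF5 containers for continuous and epoched EEG, TSV event tables.

Continuous recordings travel in a small self-describing HDF5 layout
(``data`` in microvolts, channel names, montage coordinates, sampling rate,
subject metadata).  Events are tab-separated text with columns
``onset_sample`` and ``label`` so they stay diffable and tool-agnostic.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, ContinuousRecording, EventSequence
from .montage import ElectrodeMontage, build_default_montage

__all__ = [
    "write_recording", "read_recording", "write_events", "read_events",
    "save_epochs", "load_epochs",
]


def write_recording(rec: ContinuousRecording, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", shuffle=True)
        f.attrs["sampling_rate"] = float(rec.sampling_rate)
        f.attrs["channel_names"] = json.dumps(list(rec.montage.channel_names))
        f.attrs["reference_label"] = rec.montage.reference_label
        f.create_dataset("montage_coordinates", data=rec.montage.coordinates)
        f.attrs["metadata"] = json.dumps(rec.metadata, sort_keys=True)


def write_events(events: EventSequence, path: str | Path) -> None:
    df = pd.DataFrame({"onset_sample": events.onsets, "label": events.labels})
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventSequence:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_sample", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"events file must have columns {sorted(required)}")
    return EventSequence(df["onset_sample"].to_numpy(), df["label"].to_numpy())


def read_recording(
    path: str | Path,
    events_path: str | Path | None = None,
    montage: ElectrodeMontage | None = None,
) -> tuple[ContinuousRecording, EventSequence | None]:
    """Read a recording (and optionally its events), validated against the montage.

    Channels are reordered to match the montage; a missing channel or an
    event beyond the end of the recording is fatal.
    """
    if montage is None:
        montage = build_default_montage()
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"], dtype=float)
        rate = float(f.attrs["sampling_rate"])
        names = json.loads(f.attrs["channel_names"])
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    missing = [c for c in montage.channel_names if c not in names]
    if missing:
        raise ValueError(f"recording {path.name} is missing channel(s): {missing}")
    order = [names.index(c) for c in montage.channel_names]
    rec = ContinuousRecording(data[order], rate, montage, metadata)
    events = None
    if events_path is not None:
        events = read_events(events_path)
        if len(events) and events.onsets[-1] >= rec.n_samples:
            raise ValueError(
                f"event onset {int(events.onsets[-1])} beyond recording end "
                f"({rec.n_samples} samples)"
            )
        if len(events) and events.onsets[0] < 0:
            raise ValueError("negative event onset")
    return rec, events


def save_epochs(epochs: EpochSet, path: str | Path, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", shuffle=True)
        f.create_dataset("trial_onsets", data=epochs.trial_onsets)
        f.create_dataset("trial_labels",
                         data=np.array([str(x) for x in epochs.trial_labels], dtype="S16"))
        f.create_dataset("rejection_mask", data=epochs.rejection_mask)
        f.create_dataset("rejection_reason",
                         data=np.array([str(x) for x in epochs.rejection_reason], dtype="S16"))
        f.attrs["window_ms"] = list(epochs.window_ms)
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["channel_names"] = json.dumps(list(epochs.channel_names))
        f.attrs["metadata"] = json.dumps(metadata or {}, sort_keys=True)


def load_epochs(path: str | Path) -> tuple[EpochSet, dict]:
    with h5py.File(path, "r") as f:
        epochs = EpochSet(
            data=np.asarray(f["data"], dtype=float),
            window_ms=tuple(f.attrs["window_ms"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            trial_labels=np.array([s.decode() for s in f["trial_labels"]], dtype=object),
            trial_onsets=np.asarray(f["trial_onsets"], dtype=int),
            channel_names=tuple(json.loads(f.attrs["channel_names"])),
            rejection_mask=np.asarray(f["rejection_mask"], dtype=bool),
            rejection_reason=np.array([s.decode() for s in f["rejection_reason"]],
                                      dtype=object),
        )
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return epochs, metadata
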