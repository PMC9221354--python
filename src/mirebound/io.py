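"""Readers and writers for the supported on-disk formats.

* the *sidecar* epoch format: a ``.npy`` array (trials x channels x samples)
  next to a ``.json`` file carrying fs, channel labels, time axis and trial
  labels;
* BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``) via MNE;
* CSV exports of markers, ERD/ERS traces and follow-up summary tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, ERDSTrace, Recording
from .rebound import FollowUpSummary

__all__ = [
    "save_epochs",
    "load_epochs",
    "read_brainvision",
    "write_markers_csv",
    "erds_to_frame",
    "write_erds_csv",
    "write_summary_csv",
]


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet in the sidecar format; returns the ``.npy`` path."""
    stem = Path(path).with_suffix("")
    npy = stem.with_suffix(".npy")
    np.save(npy, epochs.data)
    meta = {
        "fs": epochs.fs,
        "channel_labels": list(epochs.channel_labels),
        "time_axis": [float(t) for t in epochs.time_axis],
        "labels": epochs.labels.to_dict(orient="list"),
        "label_columns": list(epochs.labels.columns),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return npy


def load_epochs(path: str | Path) -> EpochSet:
    stem = Path(path).with_suffix("")
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    labels = pd.DataFrame(meta["labels"])
    if "label_columns" in meta:
        labels = labels[meta["label_columns"]]
    return EpochSet(
        data=data,
        fs=meta["fs"],
        channel_labels=meta["channel_labels"],
        time_axis=np.asarray(meta["time_axis"]),
        labels=labels,
    )


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording` (via MNE)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    events = []
    for ann in raw.annotations:
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= sample < raw.n_times:
            events.append((sample, str(ann["description"])))
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def write_markers_csv(rec: Recording, path: str | Path) -> None:
    pd.DataFrame(rec.events, columns=["sample_index", "label"]).to_csv(
        path, index=False
    )


def erds_to_frame(trace: ERDSTrace) -> pd.DataFrame:
    """Long-format table: time, channel, value, significant."""
    rows = []
    sig = trace.significance
    for ci, ch in enumerate(trace.channel_labels):
        rows.append(
            pd.DataFrame(
                {
                    "time_s": trace.time_axis,
                    "channel": ch,
                    "value_pct": trace.values[ci],
                    "significant": sig[ci] if sig is not None else False,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_erds_csv(trace: ERDSTrace, path: str | Path) -> None:
    erds_to_frame(trace).to_csv(path, index=False, float_format="%.6f")


def write_summary_csv(summary: FollowUpSummary, path: str | Path) -> None:
    """Key/percentage table with a mean +/- SD footer row."""
    df = summary.to_frame().reset_index()
    footer = pd.DataFrame(
        {summary.by: ["mean", "sd"], "percentage": [summary.mean, summary.sd]}
    )
    pd.concat([df, footer], ignore_index=True).to_csv(
        path, index=False, float_format="%.4f"
    )
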