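"""Readers and writers for the pipeline's exchange formats.

Recordings travel as a delimited text matrix (electrodes x samples) plus a
YAML sidecar carrying the sampling rate, channel labels and referencing
state; EDF/BDF files are read through MNE.  Templates, segmentations,
ground truth and parameter tables are plain TSV.  Channel order is
preserved end-to-end.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backfit import Segmentation
from .clustering import TemplateSet
from .preprocess import EEGRecording

_SIDECAR_SUFFIX = ".yaml"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDECAR_SUFFIX)


def save_recording(rec: EEGRecording, path, extra: dict | None = None) -> None:
    """Write a recording as TSV matrix + YAML sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t")
    meta = {
        "sampling_rate": float(rec.sfreq),
        "channels": list(rec.ch_names),
        "reference": rec.reference,
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_recording(path) -> EEGRecording:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    return EEGRecording(
        data=data,
        sfreq=meta["sampling_rate"],
        ch_names=list(meta["channels"]),
        reference=meta.get("reference", "raw"),
    )


def read_edf(path) -> EEGRecording:
    """Read an EDF/BDF file into an EEGRecording (potentials in microvolts)."""
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,
        sfreq=raw.info["sfreq"],
        ch_names=list(raw.ch_names),
        reference="raw",
    )


def save_templates(ts: TemplateSet, path, extra: dict | None = None) -> None:
    """Templates as TSV (electrode x class) + sidecar (labels, level, ...)."""
    path = Path(path)
    df = pd.DataFrame(ts.maps.T, columns=[str(l) for l in ts.labels])
    df.to_csv(path, sep="\t", index=False)
    meta = {"labels": [str(l) for l in ts.labels], "level": ts.level}
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_templates(path) -> TemplateSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    return TemplateSet(maps=df.to_numpy().T, labels=list(meta["labels"]), level=meta["level"])


def save_segmentation(seg: Segmentation, path) -> None:
    pd.DataFrame({"sample": np.arange(seg.n_samples), "label": seg.labels}).to_csv(
        path, sep="\t", index=False
    )
    _sidecar_path(Path(path)).write_text(
        yaml.safe_dump({"sampling_rate": float(seg.sfreq), "k": int(seg.k)})
    )


def load_segmentation(path) -> Segmentation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    return Segmentation(
        labels=df["label"].to_numpy(int), sfreq=meta["sampling_rate"], k=meta["k"]
    )


def save_ground_truth(truth, path) -> None:
    truth.segment_table.to_csv(path, sep="\t", index=False)


def load_ground_truth(path):
    from .synthetic import GroundTruth

    table = pd.read_csv(path, sep="\t")
    labels = np.empty(int(table["length"].sum()), dtype=int)
    for _, row in table.iterrows():
        s = int(row["start_sample"])
        labels[s : s + int(row["length"])] = int(row["class"])
    return GroundTruth(labels=labels, segment_table=table)


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
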