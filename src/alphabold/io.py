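"""File formats: BrainVision EEG triplets, NIfTI images, TSV/JSON tables.

EEG is exchanged as a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32,
multiplexed, µV) with scanner volume triggers stored as markers of type
"Scanner". Writing is implemented here (the format is a small INI header
plus raw binary); reading goes through MNE.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import ArtifactMask, EEGRecording
from .fmri import BOLDSeries

# ---------------------------------------------------------------------------
# BrainVision


def write_brainvision(rec: EEGRecording, basepath: str | Path) -> Path:
    """Write an EEG recording as a BrainVision triplet; returns the .vhdr path."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    interval_us = 1e6 / rec.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (t, typ, label) in enumerate(rec.markers, start=2):
        pos = int(round(t * rec.fs)) + 1  # 1-based sample position
        mlines.append(f"Mk{k}={typ},{label},{pos},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_brainvision(vhdr_path: str | Path) -> EEGRecording:
    """Read a BrainVision triplet back into an :class:`EEGRecording` (µV)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True,
                                      verbose="error")
    data = raw.get_data() * 1e6  # MNE works in volts
    markers = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment"):
            continue
        typ, _, label = desc.partition("/")
        markers.append((float(ann["onset"]), typ, label))
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names), markers=markers)


# ---------------------------------------------------------------------------
# NIfTI


def write_nifti(bold_or_map, path: str | Path, affine: np.ndarray | None = None):
    """Write a BOLDSeries or a plain 3D/4D array as NIfTI-1."""
    import nibabel as nib

    if isinstance(bold_or_map, BOLDSeries):
        data = bold_or_map.data
        affine = bold_or_map.affine
    else:
        data = np.asarray(bold_or_map, dtype=float)
        if affine is None:
            affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return Path(path)


def read_nifti_bold(path: str | Path, tr: float, t0: float = 0.0) -> BOLDSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    voxel = float(img.header.get_zooms()[0])
    onsets = t0 + np.arange(data.shape[3]) * tr
    return BOLDSeries(data=data, voxel_size=voxel, tr=tr,
                      volume_onsets=onsets, affine=np.asarray(img.affine))


def read_nifti_map(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


# ---------------------------------------------------------------------------
# tables / sidecars


def write_artifact_mask(mask: ArtifactMask, path: str | Path) -> Path:
    rows = [dict(onset=s, duration=e - s, flagged=int(f))
            for (s, e), f in zip(mask.intervals, mask.flags)]
    df = pd.DataFrame(rows, columns=["onset", "duration", "flagged"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_artifact_mask(path: str | Path, duration: float) -> ArtifactMask:
    df = pd.read_csv(path, sep="\t")
    intervals = [(r.onset, r.onset + r.duration) for r in df.itertuples()]
    flags = [bool(r.flagged) for r in df.itertuples()]
    return ArtifactMask(intervals, duration, flags)


def write_regressor_tsv(regressors: list, path: str | Path) -> Path:
    cols = {"onset_s": regressors[0].volume_onsets}
    for r in regressors:
        cols[r.label] = r.values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")
    return Path(path)


def write_json(obj: dict, path: str | Path) -> Path:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return Path(path)
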