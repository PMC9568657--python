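"""Readers and writers for the formats the pipeline touches.

Covers BrainVision Core Data Format triplets (.vhdr/.vmrk/.eeg), a
single-file HDF5 "dyad fixture" container used by the test-suite and the
simulator, lead-field containers (channels x 3*n_dipoles gain matrices),
and delimited ROI tables (name, x, y, z in MNI mm).

Conventions fixed here and used globally: sample indices are 0-based and
time windows are half-open ``[start, end)``; all potentials are in µV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "DyadRecording",
    "LeadField",
    "ROISet",
    "read_brainvision",
    "write_brainvision",
    "read_fixture",
    "write_fixture",
    "read_leadfield",
    "write_leadfield",
    "read_roi_table",
    "default_roi_table",
]


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in µV.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered 10-10 labels, unique.
    markers : list of (int, str)
        ``(sample_index, condition_label)`` event markers, 0-based.
    subject_id : str
    reference_label : str
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    markers: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = ""
    reference_label: str = "linked-mastoid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        n = self.data.shape[1]
        self.markers = [(int(s), str(lab)) for s, lab in self.markers]
        for s, _ in self.markers:
            if not 0 <= s < n:
                raise ValueError(f"marker sample {s} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick_channels(self, names: list[str]) -> "Recording":
        """Return a copy restricted to ``names`` (markers unchanged)."""
        idx = [self.channel_names.index(nm) for nm in names]
        return replace(
            self,
            data=self.data[idx].copy(),
            channel_names=list(names),
            markers=list(self.markers),
        )


@dataclass
class DyadRecording:
    """Two hardware-synchronized recordings sharing one marker table."""

    receiver: Recording
    observer: Recording

    def __post_init__(self) -> None:
        if self.receiver.fs != self.observer.fs:
            raise ValueError(
                f"dyad sampling rates differ: {self.receiver.fs} vs {self.observer.fs}"
            )
        if self.receiver.n_samples != self.observer.n_samples:
            raise ValueError(
                "dyad sample counts differ: "
                f"{self.receiver.n_samples} vs {self.observer.n_samples}"
            )
        if self.receiver.markers != self.observer.markers:
            raise ValueError("dyad marker tables differ")

    @property
    def fs(self) -> float:
        return self.receiver.fs

    @property
    def markers(self) -> list[tuple[int, str]]:
        return self.receiver.markers


@dataclass
class LeadField:
    """Forward operator mapping dipole moments to scalp potentials.

    ``matrix`` has shape (n_channels, 3 * n_dipoles); the three columns of
    dipole *i* are the gains of its x/y/z moment components.
    """

    matrix: np.ndarray
    dipole_positions: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.dipole_positions = np.asarray(self.dipole_positions, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("lead field matrix must be 2-D")
        if self.matrix.shape[1] % 3 != 0:
            raise ValueError(
                f"lead field column count {self.matrix.shape[1]} not divisible by 3"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead field contains non-finite entries")
        if len(self.channel_names) != self.matrix.shape[0]:
            raise ValueError("channel_names must align with matrix rows")
        if self.dipole_positions.shape != (self.n_dipoles, 3):
            raise ValueError(
                f"dipole_positions shape {self.dipole_positions.shape} "
                f"inconsistent with {self.n_dipoles} dipoles"
            )

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.matrix.shape[1] // 3


@dataclass
class ROISet:
    """Named cortical regions of interest with MNI centroids (mm)."""

    names: list[str]
    centroids: np.ndarray
    assigned_dipole_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(set(self.names)) != len(self.names):
            dup = [n for n in self.names if self.names.count(n) > 1]
            raise ValueError(f"duplicate ROI names: {sorted(set(dup))}")
        if self.centroids.shape != (len(self.names), 3):
            raise ValueError("centroids must be (n_rois, 3)")

    def __len__(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# BrainVision


def read_brainvision(header_path: str | os.PathLike) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording`.

    Supports the INT16 and IEEE_FLOAT_32 binary formats in MULTIPLEXED or
    VECTORIZED orientation. Potentials are returned in µV after applying
    per-channel resolutions; markers are taken from ``Stimulus`` entries of
    the .vmrk file with 0-based sample indices.
    """
    import mne

    header_path = os.fspath(header_path)
    if not os.path.exists(header_path):
        raise FileNotFoundError(header_path)
    _check_companions(header_path)
    raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads Volts
    markers: list[tuple[int, str]] = []
    for ann in raw.annotations:
        desc = str(ann["description"])
        if desc.startswith("Stimulus"):
            label = desc.split("/", 1)[1].strip() if "/" in desc else desc
            markers.append((int(round(ann["onset"] * raw.info["sfreq"])), label))
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        markers=markers,
        subject_id=os.path.splitext(os.path.basename(header_path))[0],
    )


def _check_companions(header_path: str) -> None:
    root = os.path.splitext(header_path)[0]
    with open(header_path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    for key, ext in (("DataFile", ".eeg"), ("MarkerFile", ".vmrk")):
        name = None
        for line in text.splitlines():
            if line.startswith(key + "="):
                name = line.split("=", 1)[1].strip()
        path = (
            os.path.join(os.path.dirname(header_path), name)
            if name
            else root + ext
        )
        if not os.path.exists(path):
            raise FileNotFoundError(f"BrainVision companion file missing: {path}")
    fmt = None
    for line in text.splitlines():
        if line.startswith("BinaryFormat="):
            fmt = line.split("=", 1)[1].strip()
    if fmt is not None and fmt not in ("INT_16", "IEEE_FLOAT_32"):
        raise ValueError(f"unsupported BrainVision binary format: {fmt}")


def write_brainvision(
    rec: Recording,
    header_path: str | os.PathLike,
    binary_format: str = "IEEE_FLOAT_32",
    orientation: str = "MULTIPLEXED",
    resolution: float = 0.1,
) -> None:
    """Write a minimal BrainVision triplet (fixture/export support).

    ``resolution`` (µV per bit) only applies to INT_16; stored integer
    values are ``round(x / resolution)``.
    """
    header_path = os.fspath(header_path)
    root, ext = os.path.splitext(header_path)
    if ext != ".vhdr":
        raise ValueError("header_path must end in .vhdr")
    if binary_format not in ("INT_16", "IEEE_FLOAT_32"):
        raise ValueError(f"unsupported binary format: {binary_format}")
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise ValueError(f"unsupported orientation: {orientation}")
    base = os.path.basename(root)
    eeg_name, vmrk_name = base + ".eeg", base + ".vmrk"

    if binary_format == "INT_16":
        stored = np.round(rec.data / resolution).astype("<i2")
        res_line = resolution
    else:
        stored = rec.data.astype("<f4")
        res_line = 1.0
    arr = stored.T if orientation == "MULTIPLEXED" else stored
    arr.tofile(root + ".eeg")

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.fs:g}",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={name},,{res_line:g},µV")
    with open(header_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (sample, label) in enumerate(rec.markers, start=2):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{k}=Stimulus,{label},{sample + 1},1,0")
    with open(root + ".vmrk", "w", encoding="utf-8") as fh:
        fh.write("\n".join(mlines) + "\n")


# ---------------------------------------------------------------------------
# Dyad fixture container (HDF5)


def write_fixture(dyad: DyadRecording, path: str | os.PathLike) -> None:
    """Write a dyad to a single HDF5 container (units attribute 'µV')."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "hypercoh-dyad-fixture"
        f.attrs["units"] = "µV"
        f.attrs["fs"] = dyad.fs
        samples = np.array([s for s, _ in dyad.markers], dtype=np.int64)
        labels = np.array([lab for _, lab in dyad.markers], dtype=object)
        f.create_dataset("marker_samples", data=samples)
        f.create_dataset(
            "marker_labels", data=labels, dtype=h5py.string_dtype("utf-8")
        )
        for role, rec in (("receiver", dyad.receiver), ("observer", dyad.observer)):
            g = f.create_group(role)
            g.create_dataset("data", data=rec.data)
            g.create_dataset(
                "channel_names",
                data=np.array(rec.channel_names, dtype=object),
                dtype=h5py.string_dtype("utf-8"),
            )
            g.attrs["subject_id"] = rec.subject_id
            g.attrs["reference_label"] = rec.reference_label


def read_fixture(path: str | os.PathLike) -> DyadRecording:
    """Read a dyad fixture container; bit-exact round-trip with write_fixture."""
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        samples = f["marker_samples"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["marker_labels"][()]]
        markers = list(zip((int(s) for s in samples), labels))
        recs = {}
        for role in ("receiver", "observer"):
            g = f[role]
            names = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in g["channel_names"][()]
            ]
            recs[role] = Recording(
                data=g["data"][()],
                fs=fs,
                channel_names=names,
                markers=markers,
                subject_id=str(g.attrs.get("subject_id", "")),
                reference_label=str(g.attrs.get("reference_label", "")),
            )
    return DyadRecording(receiver=recs["receiver"], observer=recs["observer"])


# ---------------------------------------------------------------------------
# Lead field + ROI table


def write_leadfield(lf: LeadField, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "hypercoh-leadfield"
        f.create_dataset("matrix", data=lf.matrix)
        f.create_dataset("dipole_positions", data=lf.dipole_positions)
        f.create_dataset(
            "channel_names",
            data=np.array(lf.channel_names, dtype=object),
            dtype=h5py.string_dtype("utf-8"),
        )


def read_leadfield(path: str | os.PathLike) -> LeadField:
    with h5py.File(path, "r") as f:
        names = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f["channel_names"][()]
        ]
        return LeadField(
            matrix=f["matrix"][()],
            dipole_positions=f["dipole_positions"][()],
            channel_names=names,
        )


def read_roi_table(path: str | os.PathLike) -> ROISet:
    """Read a delimited ROI table with columns name, x, y, z (MNI mm)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    required = {"name", "x", "y", "z"}
    if not required.issubset(cols):
        raise ValueError(f"ROI table must have columns {sorted(required)}, got {cols}")
    names = [str(n).strip() for n in df["name"]]
    return ROISet(names=names, centroids=df[["x", "y", "z"]].to_numpy(float))


# Default 11-region configuration, seeded from the cortical systems implicated
# in positive and negative vicarious experience. Centroids are editable
# placeholders (approximate literature MNI coordinates) and should be replaced
# with study-specific values when available.
_DEFAULT_ROIS = [
    ("MPFC", (0.0, 50.0, 20.0)),
    ("aMCC", (0.0, 20.0, 35.0)),
    ("sgACC", (0.0, 25.0, -10.0)),
    ("TPJ_R", (52.0, -54.0, 24.0)),
    ("pSTS_R", (54.0, -40.0, 8.0)),
    ("TempPole_R", (42.0, 14.0, -30.0)),
    ("Precuneus", (0.0, -60.0, 40.0)),
    ("SMG_R", (58.0, -38.0, 34.0)),
    ("DLPFC_R", (42.0, 32.0, 30.0)),
    ("AI_R", (38.0, 16.0, -2.0)),
    ("VStriatum_R", (10.0, 10.0, -8.0)),
]


def default_roi_table() -> ROISet:
    """The package's default 11-ROI configuration (see module docstring)."""
    names = [n for n, _ in _DEFAULT_ROIS]
    cents = np.array([c for _, c in _DEFAULT_ROIS])
    return ROISet(names=names, centroids=cents)
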