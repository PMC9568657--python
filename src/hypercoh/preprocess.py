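"""Continuous dyadic EEG -> artifact-clean, baseline-corrected epoch pairs.

Fixed pipeline order: band-pass filter -> ocular decontamination -> epoch +
baseline correction -> amplitude rejection -> dyad intersection. Rejection
never modifies data values, only the keep mask, and trials are flagged
(never silently dropped) so per-condition surviving counts can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io import DyadRecording, Recording

__all__ = [
    "EpochSet",
    "bandpass",
    "remove_eog",
    "epoch",
    "reject_amplitude",
    "intersect_dyad",
    "preprocess_dyad",
    "rejection_report",
]


@dataclass
class EpochSet:
    """Trial x channel x time array with labels, keep mask, and flags.

    The default window [-0.2, 1.0) s at 250 Hz gives 300 samples per
    epoch: a 200 ms pre-stimulus baseline followed by the first second
    after stimulus onset. After baseline correction the mean over the
    baseline window is zero (to 1e-9 µV) for every kept epoch/channel.
    """

    epochs: np.ndarray
    time_axis: np.ndarray
    labels: list[str]
    keep_mask: np.ndarray
    channel_names: list[str]
    fs: float
    baseline_window: tuple[float, float] = (-0.2, 0.0)
    flags: list[str | None] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trial x channel x time)")
        n = self.epochs.shape[0]
        if len(self.labels) != n or self.keep_mask.shape != (n,):
            raise ValueError("labels/keep_mask length must match trial count")
        if not self.flags:
            self.flags = [None] * n
        if len(self.flags) != n:
            raise ValueError("flags length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def kept_indices(self, condition: str | None = None) -> np.ndarray:
        """Indices of kept trials, optionally restricted to a condition.

        ``condition`` matches a full label ('fair/agent') or a single
        factor level ('fair', 'agent') appearing in the '/'-split label.
        """
        idx = np.flatnonzero(self.keep_mask)
        if condition is None:
            return idx
        return np.array(
            [i for i in idx if _label_matches(self.labels[i], condition)], dtype=int
        )

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def pick_channels(self, names: list[str]) -> "EpochSet":
        idx = [self.channel_names.index(nm) for nm in names]
        return replace(self, epochs=self.epochs[:, idx, :].copy(), channel_names=list(names))


def _label_matches(label: str, condition: str) -> bool:
    if label == condition:
        return True
    parts = label.split("/")
    wanted = condition.split("/")
    return all(w in parts for w in wanted)


def bandpass(rec: Recording, low: float = 1.0, high: float = 45.0) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward).

    The order is chosen (per edge, via ``buttord``) so the cascaded
    forward-backward response is down at least 40 dB at 0.5*low and
    1.2*high while the passband ripple stays within ~1 dB.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    # single-pass specs; filtfilt doubles the dB attenuation
    n_hp, wn_hp = signal.buttord(low / nyq, 0.5 * low / nyq, 0.5, 20.0)
    n_lp, wn_lp = signal.buttord(high / nyq, min(1.2 * high / nyq, 0.99), 0.5, 20.0)
    sos_hp = signal.butter(n_hp, wn_hp, btype="highpass", output="sos")
    sos_lp = signal.butter(n_lp, wn_lp, btype="lowpass", output="sos")
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    x = signal.sosfiltfilt(sos_hp, x, axis=1)
    x = signal.sosfiltfilt(sos_lp, x, axis=1)
    return replace(rec, data=x, markers=list(rec.markers))


def remove_eog(rec: Recording, eog_channels: list[str] | None = None) -> Recording:
    """Regress EOG channels out of every EEG channel (least squares).

    A deterministic stand-in for component-based ocular correction: each
    EEG channel is decorrelated from the (demeaned) EOG regressors over
    the whole recording. EOG channels are passed through unchanged.
    """
    if eog_channels is None:
        eog_channels = [nm for nm in rec.channel_names if "EOG" in nm.upper()]
    if not eog_channels:
        raise ValueError("no EOG channels found or given")
    missing = [nm for nm in eog_channels if nm not in rec.channel_names]
    if missing:
        raise ValueError(f"EOG channels absent from recording: {missing}")
    eog_idx = [rec.channel_names.index(nm) for nm in eog_channels]
    eeg_idx = [i for i in range(rec.n_channels) if i not in eog_idx]
    X = rec.data[eog_idx].T  # samples x regressors
    X = X - X.mean(axis=0, keepdims=True)
    Y = rec.data[eeg_idx].T
    Ym = Y.mean(axis=0, keepdims=True)
    beta, *_ = np.linalg.lstsq(X, Y - Ym, rcond=None)
    cleaned = rec.data.copy()
    cleaned[eeg_idx] = (Y - X @ beta).T
    return replace(rec, data=cleaned, markers=list(rec.markers))


def epoch(
    rec: Recording,
    window: tuple[float, float] = (-0.2, 1.0),
    baseline: tuple[float, float] = (-0.2, 0.0),
    label_map: dict[str, str] | None = None,
) -> EpochSet:
    """Cut marker-locked epochs and baseline-correct them.

    ``window`` and ``baseline`` are in seconds relative to the marker,
    half-open. Trials whose window falls off the recording edge are
    flagged 'edge' (keep_mask False), not dropped. ``label_map`` maps raw
    marker labels to canonical condition labels.
    """
    fs = rec.fs
    start = int(round(window[0] * fs))
    stop = int(round(window[1] * fs))
    n_time = stop - start
    b0 = int(round(baseline[0] * fs)) - start
    b1 = int(round(baseline[1] * fs)) - start
    if not 0 <= b0 < b1 <= n_time:
        raise ValueError("baseline window must lie inside the epoch window")
    n_trials = len(rec.markers)
    epochs = np.zeros((n_trials, rec.n_channels, n_time))
    keep = np.ones(n_trials, dtype=bool)
    flags: list[str | None] = [None] * n_trials
    labels = []
    for k, (onset, raw_label) in enumerate(rec.markers):
        labels.append(label_map.get(raw_label, raw_label) if label_map else raw_label)
        lo, hi = onset + start, onset + stop
        if lo < 0 or hi > rec.n_samples:
            keep[k] = False
            flags[k] = "edge"
            continue
        seg = rec.data[:, lo:hi]
        epochs[k] = seg - seg[:, b0:b1].mean(axis=1, keepdims=True)
    return EpochSet(
        epochs=epochs,
        time_axis=(np.arange(start, stop) / fs),
        labels=labels,
        keep_mask=keep,
        channel_names=list(rec.channel_names),
        fs=fs,
        baseline_window=baseline,
        flags=flags,
        subject_id=rec.subject_id,
    )


def reject_amplitude(es: EpochSet, threshold_uv: float = 80.0) -> EpochSet:
    """Flag epochs where any EEG channel exceeds +-threshold (strict).

    A sample at exactly +-threshold is kept; only values strictly beyond
    it reject the trial. EOG channels are ignored. Data values are never
    modified.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    eeg = [i for i, nm in enumerate(es.channel_names) if "EOG" not in nm.upper()]
    exceeded = np.abs(es.epochs[:, eeg, :]).max(axis=(1, 2)) > threshold_uv
    keep = es.keep_mask & ~exceeded
    flags = list(es.flags)
    for k in np.flatnonzero(exceeded & es.keep_mask):
        flags[k] = "amplitude"
    return replace(es, keep_mask=keep, flags=flags)


def intersect_dyad(es_r: EpochSet, es_o: EpochSet) -> tuple[EpochSet, EpochSet]:
    """Keep only trials that are artifact-free for *both* subjects."""
    if es_r.n_trials != es_o.n_trials:
        raise ValueError(
            f"trial counts differ: {es_r.n_trials} vs {es_o.n_trials}"
        )
    if es_r.labels != es_o.labels:
        raise ValueError("condition labels differ between dyad members")
    joint = es_r.keep_mask & es_o.keep_mask
    return (
        replace(es_r, keep_mask=joint.copy()),
        replace(es_o, keep_mask=joint.copy()),
    )


def rejection_report(es_r: EpochSet, es_o: EpochSet) -> pd.DataFrame:
    """Per-condition trial bookkeeping (total / kept per subject / joint)."""
    rows = []
    for label in sorted(set(es_r.labels)):
        idx = [i for i, lab in enumerate(es_r.labels) if lab == label]
        rows.append(
            {
                "condition": label,
                "n_total": len(idx),
                "kept_receiver": int(es_r.keep_mask[idx].sum()),
                "kept_observer": int(es_o.keep_mask[idx].sum()),
                "kept_joint": int((es_r.keep_mask & es_o.keep_mask)[idx].sum()),
            }
        )
    return pd.DataFrame(rows)


def preprocess_dyad(
    dyad: DyadRecording,
    low: float = 1.0,
    high: float = 45.0,
    window: tuple[float, float] = (-0.2, 1.0),
    baseline: tuple[float, float] = (-0.2, 0.0),
    threshold_uv: float = 80.0,
    eog_channels: list[str] | None = None,
    label_map: dict[str, str] | None = None,
) -> tuple[EpochSet, EpochSet, pd.DataFrame]:
    """Run the full preprocessing chain on a dyad; returns intersected
    epoch sets plus the per-condition rejection report."""
    out = {}
    for role, rec in (("receiver", dyad.receiver), ("observer", dyad.observer)):
        r = bandpass(rec, low=low, high=high)
        has_eog = eog_channels or any("EOG" in nm.upper() for nm in r.channel_names)
        if has_eog:
            r = remove_eog(r, eog_channels)
        es = epoch(r, window=window, baseline=baseline, label_map=label_map)
        out[role] = reject_amplitude(es, threshold_uv=threshold_uv)
    es_r, es_o = intersect_dyad(out["receiver"], out["observer"])
    return es_r, es_o, rejection_report(es_r, es_o)
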