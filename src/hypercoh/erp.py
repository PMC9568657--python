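"""Event-related potentials: trial averages, grand averages, peak scoring.

The component of interest is a late positive potential (LPP): a
centro-parietal positivity peaking roughly 500-700 ms after stimulus
onset, larger for fair than for hyperunfair divisions. Peaks are scored
as the simple maximum in a fixed common search window (default
0.4-0.8 s), at the midline channels Fz, Cz, Pz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import EpochSet

__all__ = ["ERPWaveform", "PeakMeasure", "average_epochs", "grand_average", "find_peak", "peak_table"]


@dataclass
class ERPWaveform:
    """Trial- (or subject-) averaged channel x time potential in µV."""

    mean: np.ndarray
    time_axis: np.ndarray
    channel_names: list[str]
    n_trials: int
    condition: str = ""
    subject_id: str = ""
    role: str = ""
    ci95: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.mean.shape != (len(self.channel_names), len(self.time_axis)):
            raise ValueError("mean shape inconsistent with channels/time axis")

    def channel(self, name: str) -> np.ndarray:
        return self.mean[self.channel_names.index(name)]


@dataclass
class PeakMeasure:
    """Peak amplitude (µV) and latency (s) within a search window."""

    channel: str
    amplitude: float
    latency: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.window[0] <= self.latency <= self.window[1]:
            raise ValueError("peak latency outside its search window")


def average_epochs(es: EpochSet, condition: str | None = None) -> ERPWaveform:
    """Arithmetic mean over *kept* trials of one condition."""
    idx = es.kept_indices(condition)
    if idx.size == 0:
        raise ValueError(f"no kept trials for condition {condition!r}")
    return ERPWaveform(
        mean=es.epochs[idx].mean(axis=0),
        time_axis=es.time_axis.copy(),
        channel_names=list(es.channel_names),
        n_trials=int(idx.size),
        condition=condition or "all",
        subject_id=es.subject_id,
    )


def grand_average(erps: list[ERPWaveform]) -> ERPWaveform:
    """Across-subject mean with per-sample 95% confidence half-widths.

    ci95 = t(0.975, n-1) * SE per channel/sample; with a single input the
    CI is undefined and a warning is raised.
    """
    if not erps:
        raise ValueError("empty input")
    ref = erps[0]
    for e in erps[1:]:
        if e.channel_names != ref.channel_names:
            raise ValueError("channel sets differ across subjects")
        if e.mean.shape != ref.mean.shape or not np.allclose(e.time_axis, ref.time_axis):
            raise ValueError("time axes differ across subjects")
    stack = np.stack([e.mean for e in erps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n < 2:
        warnings.warn("grand average of a single subject: ci95 undefined")
        ci = None
    else:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
        ci = sps.t.ppf(0.975, n - 1) * se
    return ERPWaveform(
        mean=mean,
        time_axis=ref.time_axis.copy(),
        channel_names=list(ref.channel_names),
        n_trials=n,
        condition=ref.condition,
        role=ref.role,
        ci95=ci,
    )


def find_peak(
    erp: ERPWaveform,
    channel: str,
    window: tuple[float, float] = (0.4, 0.8),
    polarity: str = "positive",
) -> PeakMeasure:
    """Maximum (or minimum) within the search window; earliest tie wins.

    If a positive peak search finds an all-negative segment the maximum is
    still returned, with a warning flagging the low amplitude.
    """
    t = erp.time_axis
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError(f"search window {window} outside the epoch time axis")
    y = erp.channel(channel)[sel]
    tw = t[sel]
    signed = y if polarity == "positive" else -y
    i = int(np.argmax(signed))  # argmax returns the first of ties
    amp = float(y[i])
    if polarity == "positive" and amp <= 0:
        warnings.warn(
            f"positive-peak search on {channel}: window maximum is {amp:.2f} µV"
        )
    return PeakMeasure(channel=channel, amplitude=amp, latency=float(tw[i]), window=window)


def peak_table(
    erps_by_cell: dict[tuple[str, str, str, str], ERPWaveform],
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz"),
    window: tuple[float, float] = (0.4, 0.8),
) -> pd.DataFrame:
    """Per-subject peak table over (subject, role, agency, fairness) cells.

    The returned long-format table (one row per cell x channel) is the
    input to the split-plot ANOVA.
    """
    rows = []
    for (subject, role, agency, fairness), erp in erps_by_cell.items():
        for ch in channels:
            pk = find_peak(erp, ch, window=window)
            rows.append(
                {
                    "subject": subject,
                    "role": role,
                    "agency": agency,
                    "fairness": fairness,
                    "channel": ch,
                    "amplitude_uv": pk.amplitude,
                    "latency_s": pk.latency,
                }
            )
    return pd.DataFrame(rows)
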