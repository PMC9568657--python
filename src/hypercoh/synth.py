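"""Ground-truth simulator for third-party-punishment hyperscanning sessions.

The generator produces what the downstream pipeline needs to be tested
against known truth: a balanced trial schedule over fairness x agency
cells, payoff bookkeeping for the economic game, and synthetic dyadic EEG
in which each trial carries an LPP-like Gabor burst (theta-band content,
~600 ms latency, centro-parietal topography) whose per-trial phase is
shared between the two subjects to a controllable degree.

Coupling model
--------------
For trial *k* the receiver's burst phase phi_r[k] is stimulus-locked:
normally distributed around 0 with a small jitter (``erp_phase_sd``), so
the trial-averaged ERP does not cancel. The observer's phase is phi_r[k]
plus (a) a per-trial von Mises offset
whose concentration is chosen so that the mean resultant length of the
phase-difference distribution equals ``kappa`` (kappa=1: identical
phases; kappa=0: independent uniform phases), and (b) a within-burst
Brownian phase drift with rate proportional to ``1 - kappa``.

Both components are needed because smoothed magnitude coherence is, by
construction, invariant to a phase offset that is *constant* over the
smoothing window: the per-trial offset (a) alone would leave trial-
averaged coherence at the burst unchanged. The drift term (b) is what
the estimator actually detects — at kappa=0 the observer's burst phase
decorrelates from the receiver's within the smoothing support, driving
coherence at the burst locus down to the noise floor, while at kappa=1
the bursts are identical. Coherence at the locus is therefore monotone
in kappa, and the per-trial phase-difference distribution still has
circular variance 1 - kappa.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ive

from .io import DyadRecording, Recording

__all__ = [
    "FAIRNESS_LEVELS",
    "AGENCY_LEVELS",
    "TrialSchedule",
    "CouplingSpec",
    "generate_schedule",
    "compute_payoffs",
    "simulate_dyad",
    "inject_artifacts",
    "default_montage",
]

FAIRNESS_LEVELS = ("fair", "unfair", "hyperunfair")
AGENCY_LEVELS = ("agent", "pc")

# Endowment splits (dictator, receiver) per fairness level; the observer may
# spend up to 4 points, each costing the dictator 3 and crediting the
# receiver 1.
_SPLITS = {"fair": (10, 10), "unfair": (14, 6), "hyperunfair": (18, 2)}
MAX_PUNISHMENT = 4


@dataclass
class TrialSchedule:
    """Ordered trial list: (block_index, fairness, agency, onset_sample)."""

    trials: list[tuple[int, str, str, int]]

    def __post_init__(self) -> None:
        onsets = [t[3] for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t[3] for t in self.trials], dtype=int)

    def cell_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for _, fairness, agency, _ in self.trials:
            counts[(fairness, agency)] = counts.get((fairness, agency), 0) + 1
        return counts

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.trials, columns=["block", "fairness", "agency", "onset_sample"]
        )

    def marker_table(self) -> list[tuple[int, str]]:
        """Markers as (onset_sample, 'fairness/agency')."""
        return [(onset, f"{f}/{a}") for _, f, a, onset in self.trials]


def generate_schedule(
    n_blocks: int = 7,
    trials_per_block: int = 30,
    conditions: tuple[tuple[str, str], ...] | None = None,
    iti_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    start_sample: int = 500,
) -> TrialSchedule:
    """Randomized schedule, exactly balanced over condition cells per block.

    Defaults give the full session: 7 blocks x 30 trials = 210 trials,
    35 per fairness x agency cell, presented in random order within block.
    """
    if conditions is None:
        conditions = tuple(
            (f, a) for f in FAIRNESS_LEVELS for a in AGENCY_LEVELS
        )
    n_cells = len(conditions)
    if trials_per_block % n_cells != 0:
        raise ValueError(
            f"trials_per_block={trials_per_block} not divisible by "
            f"{n_cells} condition cells"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    per_cell = trials_per_block // n_cells
    trials: list[tuple[int, str, str, int]] = []
    onset = start_sample
    for block in range(n_blocks):
        cells = [c for c in conditions for _ in range(per_cell)]
        order = rng.permutation(len(cells))
        for idx in order:
            fairness, agency = cells[idx]
            trials.append((block, fairness, agency, onset))
            onset += iti_samples
    return TrialSchedule(trials=trials)


def compute_payoffs(fairness: str, punishment_points: int) -> tuple[int, int, int]:
    """Payoffs after punishment: (dictator, receiver, observer_cost).

    Each punishment point costs the observer 1 point, subtracts 3 from the
    dictator and adds 1 to the receiver. Raw values are reported (no
    clipping at zero).
    """
    if fairness not in _SPLITS:
        raise ValueError(f"unknown fairness level: {fairness!r}")
    p = punishment_points
    if not (isinstance(p, (int, np.integer)) and 0 <= p <= MAX_PUNISHMENT):
        raise ValueError(
            f"punishment_points must be an integer in [0, {MAX_PUNISHMENT}], got {p!r}"
        )
    split_a, split_b = _SPLITS[fairness]
    return split_a - 3 * p, split_b + p, int(p)


# ---------------------------------------------------------------------------
# Montage helpers


_ROW_Y = {
    "Fp": 0.95, "AF": 0.75, "F": 0.55, "FT": 0.35, "FC": 0.35,
    "T": 0.0, "C": 0.0, "TP": -0.35, "CP": -0.35, "P": -0.55,
    "PO": -0.75, "O": -0.95, "I": -1.1,
}


def _approx_position(name: str) -> tuple[float, float]:
    """Rough 2-D scalp coordinate for a 10-10 label (x: left-, right+)."""
    special = {"IO": (0.0, 1.15), "Iz": (0.0, -1.1)}
    if name in special:
        return special[name]
    m = re.fullmatch(r"([A-Za-z]+?)(z|\d+)", name)
    if m is None:
        return (0.0, 0.0)
    row, num = m.group(1), m.group(2)
    y = _ROW_Y.get(row, 0.0)
    if num == "z":
        return (0.0, y)
    k = int(num)
    side = -1.0 if k % 2 == 1 else 1.0
    lateral = min(((k + 1) // 2) * 0.2, 1.2)
    if row in ("T", "TP", "FT"):
        lateral = max(lateral, 0.8)
    return (side * lateral, y)


def default_montage() -> tuple[list[str], list[str]]:
    """61 EEG labels (10-10 style, incl. the head-model-unsupported eight)
    plus 3 EOG labels."""
    eeg = (
        ["Fp1", "Fpz", "Fp2"]
        + ["AF3", "AFz", "AF4"]
        + ["F7", "F3", "F1", "Fz", "F2", "F4", "F8"]
        + ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]
        + ["T7", "C3", "C1", "Cz", "C2", "C4", "T8"]
        + ["TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10"]
        + ["P7", "P3", "P1", "Pz", "P2", "P4", "P8", "P11", "P12"]
        + ["PO7", "PO3", "POz", "PO4", "PO8"]
        + ["O9", "O1", "Oz", "O2", "O10"]
        + ["Iz", "IO"]
    )
    assert len(eeg) == 61
    eog = ["hEOG", "vEOG", "rEOG"]
    return eeg, eog


def topography_gains(
    channel_names: list[str], peak: str = "Pz", sigma: float = 0.55
) -> np.ndarray:
    """Gaussian spatial gain profile peaking at ``peak`` (EOG channels -> 0)."""
    px, py = _approx_position(peak)
    gains = np.zeros(len(channel_names))
    for i, name in enumerate(channel_names):
        if "EOG" in name.upper():
            continue
        x, y = _approx_position(name)
        d2 = (x - px) ** 2 + (y - py) ** 2
        gains[i] = np.exp(-d2 / (2 * sigma**2))
    return gains


# ---------------------------------------------------------------------------
# Coupling + simulation


@dataclass
class CouplingSpec:
    """Parameters of the planted LPP-like burst and its dyadic coupling.

    Amplitudes are in µV at the topography peak channel; no quantitative
    amplitudes are reported for the real effect, so the defaults (fair >
    hyperunfair) are plausible placeholders, documented as such.
    """

    erp_latency_s: float = 0.6
    erp_freq_hz: float = 5.0
    gabor_sigma_s: float = 0.12
    # across-trial burst-phase jitter (rad) around 0. The burst must be
    # stimulus-phase-locked for a non-vanishing trial-averaged ERP; the
    # dyadic coherence estimator is invariant to this distribution.
    erp_phase_sd: float = 0.3
    amp_by_fairness: dict[str, float] = field(
        default_factory=lambda: {"fair": 8.0, "unfair": 5.0, "hyperunfair": 4.0}
    )
    kappa: float | dict[str, float] = 1.0
    # Brownian phase-drift rate (rad/sqrt(s)) at kappa=0, scaled by
    # (1 - kappa). 5.0 makes the drift std over the estimator's ~0.2 s
    # smoothing support ~2.2 rad at kappa=0 (coherent fraction
    # e^{-sigma^2/2} ~ 0.08), so kappa in [0, 1] spans the full
    # decorrelated-to-locked transition.
    phase_drift: float = 5.0
    topography: np.ndarray | None = None
    topography_peak: str = "Pz"
    # defaults emulate realistic ongoing EEG: ~10 µV RMS 1/f background
    # plus ~2 µV sensor noise, i.e. single-trial burst SNR < 1 (the reason
    # ERPs require trial averaging). Set both to 0 for noise-free tests.
    noise_pink_sigma: float = 10.0
    noise_pink_exponent: float = 1.0
    noise_white_sigma: float = 2.0

    def __post_init__(self) -> None:
        kappas = (
            self.kappa.values() if isinstance(self.kappa, dict) else [self.kappa]
        )
        for k in kappas:
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kappa must be in [0, 1], got {k}")
        if any(a < 0 for a in self.amp_by_fairness.values()):
            raise ValueError("burst amplitudes must be non-negative")

    def kappa_for(self, fairness: str, agency: str) -> float:
        if isinstance(self.kappa, dict):
            for key in (f"{fairness}/{agency}", fairness, agency):
                if key in self.kappa:
                    return self.kappa[key]
            raise KeyError(f"no kappa entry for condition {fairness}/{agency}")
        return self.kappa


def vonmises_concentration(resultant_length: float) -> float:
    """Invert A(c) = I1(c)/I0(c) = r; returns the von Mises concentration."""
    r = float(resultant_length)
    if not 0.0 <= r < 1.0:
        raise ValueError("resultant length must be in [0, 1)")
    if r == 0.0:
        return 0.0
    if r > 0.999:
        return 1.0 / (2 * (1 - r))  # asymptotic A(c) ~ 1 - 1/(2c)
    # exponentially scaled Bessel ratio is overflow-safe
    return brentq(lambda c: ive(1, c) / ive(0, c) - r, 1e-8, 2e3, xtol=1e-10)


def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, int], fs: float, exponent: float
) -> np.ndarray:
    """Gaussian 1/f^exponent noise, unit variance per channel."""
    n_ch, n = shape
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_ch, freqs.size))
        + 1j * rng.standard_normal((n_ch, freqs.size))
    ) * scale
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _gabor(
    t: np.ndarray, t0: float, f: float, sigma: float, phase: float | np.ndarray
) -> np.ndarray:
    """Gaussian-windowed cosine; ``phase`` may vary sample-by-sample."""
    return np.exp(-((t - t0) ** 2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * f * (t - t0) + phase
    )


def simulate_dyad(
    schedule: TrialSchedule,
    coupling: CouplingSpec,
    channel_names: list[str] | None = None,
    fs: float = 250.0,
    seed: int = 0,
    epoch_window: tuple[float, float] = (-0.2, 1.0),
) -> DyadRecording:
    """Synthesize a hardware-synchronized dyad from a schedule and coupling.

    Each trial adds a Gabor burst to both subjects at the configured
    latency/frequency; receiver phase is uniform per trial and the observer
    phase follows the kappa coupling model. Spatial pattern is the
    topography gain vector; pink + white noise is added per subject.
    Fully reproducible from ``seed``.
    """
    if channel_names is None:
        eeg, eog = default_montage()
        channel_names = eeg + eog
    rng = np.random.default_rng(seed)

    onsets = schedule.onsets
    span = int(round((epoch_window[1] - epoch_window[0]) * fs))
    if np.any(np.diff(onsets) < span):
        raise ValueError(
            "epoch windows around onsets overlap; increase iti_samples"
        )
    n_samples = int(onsets[-1] + 2 * span)
    n_ch = len(channel_names)
    t_axis = np.arange(n_samples) / fs

    topo = (
        np.asarray(coupling.topography, dtype=float)
        if coupling.topography is not None
        else topography_gains(channel_names, peak=coupling.topography_peak)
    )
    if topo.shape != (n_ch,):
        raise ValueError(f"topography length {topo.shape} != {n_ch} channels")

    data = {}
    for role in ("receiver", "observer"):
        x = np.zeros((n_ch, n_samples))
        if coupling.noise_pink_sigma > 0:
            x += coupling.noise_pink_sigma * _pink_noise(
                rng, (n_ch, n_samples), fs, coupling.noise_pink_exponent
            )
        if coupling.noise_white_sigma > 0:
            x += coupling.noise_white_sigma * rng.standard_normal((n_ch, n_samples))
        data[role] = x

    half_support = 5 * coupling.gabor_sigma_s
    for _, fairness, agency, onset in schedule.trials:
        amp = coupling.amp_by_fairness[fairness]
        kap = coupling.kappa_for(fairness, agency)
        phi_r = (
            rng.normal(0.0, coupling.erp_phase_sd)
            if coupling.erp_phase_sd > 0
            else 0.0
        )
        if kap >= 1.0:
            phi_o = phi_r
        elif kap <= 0.0:
            phi_o = rng.uniform(0, 2 * np.pi)
        else:
            conc = vonmises_concentration(kap)
            phi_o = phi_r + rng.vonmises(0.0, conc)
        t0 = onset / fs + coupling.erp_latency_s
        lo = max(0, int((t0 - half_support) * fs))
        hi = min(n_samples, int((t0 + half_support) * fs) + 1)
        seg = t_axis[lo:hi]
        drift_rate = (1.0 - kap) * coupling.phase_drift
        if drift_rate > 0:
            steps = rng.standard_normal(seg.size) * drift_rate / np.sqrt(fs)
            drift = np.cumsum(steps)
            drift -= drift[np.argmin(np.abs(seg - t0))]  # anchor at burst center
            phi_o = phi_o + drift
        for role, phi in (("receiver", phi_r), ("observer", phi_o)):
            burst = amp * _gabor(seg, t0, coupling.erp_freq_hz, coupling.gabor_sigma_s, phi)
            data[role][:, lo:hi] += topo[:, None] * burst

    markers = schedule.marker_table()
    recs = {
        role: Recording(
            data=data[role],
            fs=fs,
            channel_names=list(channel_names),
            markers=markers,
            subject_id=f"sim-{role}",
        )
        for role in ("receiver", "observer")
    }
    return DyadRecording(receiver=recs["receiver"], observer=recs["observer"])


def inject_artifacts(
    rec: Recording,
    blink_rate: float = 0.0,
    spike_rate: float = 0.0,
    spike_amp_uv: float = 120.0,
    seed: int = 0,
    spike_epochs: list[int] | None = None,
    epoch_window: tuple[float, float] = (-0.2, 1.0),
) -> tuple[Recording, list[int]]:
    """Contaminate epochs with blinks/amplitude spikes; return ground truth.

    ``blink_rate``/``spike_rate`` are per-epoch contamination
    probabilities; ``spike_epochs`` selects spike-contaminated epochs
    explicitly (overriding ``spike_rate``). Epochs are defined by the
    recording's markers and ``epoch_window`` (seconds, half-open). Returns
    the contaminated recording and the sorted list of contaminated epoch
    indices.
    """
    if blink_rate < 0 or spike_rate < 0:
        raise ValueError("artifact rates must be non-negative")
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    fs = rec.fs
    pre = int(round(-epoch_window[0] * fs))
    post = int(round(epoch_window[1] * fs))
    contaminated: set[int] = set()

    eeg_idx = [i for i, nm in enumerate(rec.channel_names) if "EOG" not in nm.upper()]
    eog_idx = [i for i, nm in enumerate(rec.channel_names) if "EOG" in nm.upper()]

    if spike_epochs is None:
        spike_epochs = [
            k for k in range(len(rec.markers)) if rng.uniform() < spike_rate
        ]
    for k in spike_epochs:
        onset, _ = rec.markers[k]
        lo, hi = onset - pre, onset + post
        pos = rng.integers(max(lo, 0), min(hi, rec.n_samples))
        ch = eeg_idx[rng.integers(len(eeg_idx))]
        width = 3
        sl = slice(pos, min(pos + width, rec.n_samples))
        data[ch, sl] += spike_amp_uv * rng.choice([-1.0, 1.0])
        contaminated.add(k)

    for k in range(len(rec.markers)):
        if blink_rate > 0 and rng.uniform() < blink_rate:
            onset, _ = rec.markers[k]
            center = rng.integers(onset - pre, onset + post)
            t = np.arange(rec.n_samples) / fs
            blink = np.exp(-((t - center / fs) ** 2) / (2 * 0.08**2))
            for i in eog_idx:
                data[i] += 250.0 * blink
            frontal = [
                i for i in eeg_idx
                if rec.channel_names[i].startswith(("Fp", "AF", "IO"))
            ] or eeg_idx[:2]
            for i in frontal:
                data[i] += 110.0 * blink
            contaminated.add(k)

    out = Recording(
        data=data,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        markers=list(rec.markers),
        subject_id=rec.subject_id,
        reference_label=rec.reference_label,
    )
    return out, sorted(contaminated)
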