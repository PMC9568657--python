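"""Trial-wise wavelet coherence between homologous dyad time series.

This is the package's core method: for every artifact-free trial shared
by the two members of a dyad, compute the magnitude-squared wavelet
coherence between the receiver's and the observer's signal at the same
electrode (or ROI), then average the coherence maps across trials. The
analysis band is 4-7 Hz, matching the spectral content of ERP components.

Definitions
-----------
The continuous wavelet transform uses the analytic Morlet mother wavelet
with center frequency ``omega0 = 6`` (the standard admissibility-
respecting default); scale maps to frequency as ``f = omega0 / (2 pi s)``.
Coherence follows the Torrence-Compo/Grinsted convention::

    R^2 = |S(Wx Wy* / s)|^2 / ( S(|Wx|^2 / s) * S(|Wy|^2 / s) )

where the smoothing operator S is a Gaussian in time with standard
deviation equal to the scale, followed by a boxcar over 0.6 octave in
scale. Without smoothing, single-trial coherence is identically 1, so
smoothing is what makes the estimator informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.ndimage import uniform_filter1d

from .preprocess import EpochSet

__all__ = [
    "WCohMap",
    "CohTimeCourse",
    "morlet_scales",
    "morlet_cwt",
    "wavelet_coherence",
    "dyad_trial_coherence",
    "collapse_band",
    "power_phase_diagnostic",
]

OMEGA0 = 6.0


@dataclass
class WCohMap:
    """Time x scale coherence in [0, 1] with cone-of-influence mask.

    ``coi_valid[t, j]`` is False where the wavelet support at scale j
    spills over the epoch edge at time t (e-folding time sqrt(2)*s).
    """

    coh: np.ndarray  # (n_time, n_scales)
    time_axis: np.ndarray
    scales: np.ndarray
    freqs: np.ndarray
    coi_valid: np.ndarray
    n_trials: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.coh.shape != (len(self.time_axis), len(self.scales)):
            raise ValueError("coh must be (n_time, n_scales)")
        if np.nanmin(self.coh) < -1e-9 or np.nanmax(self.coh) > 1 + 1e-9:
            raise ValueError("coherence out of [0, 1]")


@dataclass
class CohTimeCourse:
    """Band-collapsed coherence time course in [0, 1]."""

    values: np.ndarray
    time_axis: np.ndarray
    band: tuple[float, float]
    n_valid_scales: np.ndarray
    name: str = ""


def morlet_scales(
    band: tuple[float, float] = (4.0, 7.0),
    voices: int = 12,
    omega0: float = OMEGA0,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced scales covering ``band`` at ``voices`` per octave.

    Returns (scales, freqs) ordered from high to low frequency, endpoints
    included.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    n_oct = np.log2(hi / lo)
    n = int(np.ceil(n_oct * voices)) + 1
    freqs = hi * 2.0 ** (-np.arange(n) / voices)
    freqs[-1] = max(freqs[-1], lo)
    scales = omega0 / (2 * np.pi * freqs)
    return scales, freqs


def morlet_cwt(
    x: np.ndarray,
    scales: np.ndarray,
    fs: float,
    omega0: float = OMEGA0,
) -> np.ndarray:
    """FFT-based CWT with the analytic Morlet wavelet.

    Returns complex coefficients of shape (n_scales, n_time), normalized
    per Torrence-Compo (psi_hat(s w) scaled by sqrt(2 pi s / dt)). Input
    is zero-padded to the next power of two to limit wraparound.
    """
    x = np.asarray(x, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0:
        raise ValueError("empty scale array")
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    n = x.size
    dt = 1.0 / fs
    n_pad = int(2 ** np.ceil(np.log2(2 * n)))
    xh = np.fft.fft(x, n_pad)
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, d=dt)
    W = np.empty((scales.size, n), dtype=complex)
    norm_const = np.pi**-0.25
    for j, s in enumerate(scales):
        psi_hat = np.where(
            omega > 0,
            norm_const * np.exp(-0.5 * (s * omega - omega0) ** 2),
            0.0,
        )
        W[j] = np.fft.ifft(xh * np.sqrt(2 * np.pi * s / dt) * psi_hat)[:n]
    return W


def coi_mask(n_time: int, scales: np.ndarray, fs: float) -> np.ndarray:
    """(n_time, n_scales) validity mask: True outside the cone of influence."""
    t = np.arange(n_time) / fs
    edge_dist = np.minimum(t, t[::-1])  # seconds to nearest edge
    efold = np.sqrt(2.0) * np.asarray(scales)
    return edge_dist[:, None] >= efold[None, :]


def _smooth(
    W: np.ndarray, scales: np.ndarray, fs: float, voices: int
) -> np.ndarray:
    """Torrence-Compo smoothing: Gaussian in time (std = scale), boxcar
    over 0.6 octave in scale."""
    n = W.shape[1]
    n_pad = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, d=1.0 / fs)
    out = np.empty(W.shape, dtype=complex)
    for j, s in enumerate(scales):
        kernel_hat = np.exp(-0.5 * (s * omega) ** 2)
        out[j] = np.fft.ifft(np.fft.fft(W[j], n_pad) * kernel_hat)[:n]
    nbox = max(1, int(round(0.6 * voices)))
    if nbox > 1 and len(scales) > 1:
        out = uniform_filter1d(out.real, nbox, axis=0, mode="nearest") + 1j * (
            uniform_filter1d(out.imag, nbox, axis=0, mode="nearest")
        )
    return out if np.iscomplexobj(W) else out.real


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float] = (4.0, 7.0),
    voices: int = 12,
    omega0: float = OMEGA0,
    smooth: bool = True,
) -> WCohMap:
    """Magnitude-squared wavelet coherence between two equal-length series.

    With ``smooth=False`` the estimator degenerates to 1 everywhere
    (kept available as a regression check that smoothing is active).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: coherence undefined")
    scales, freqs = morlet_scales(band, voices, omega0)
    Wx = morlet_cwt(x, scales, fs, omega0)
    Wy = morlet_cwt(y, scales, fs, omega0)
    inv_s = 1.0 / scales[:, None]
    if smooth:
        Sxy = _smooth(Wx * np.conj(Wy) * inv_s, scales, fs, voices)
        Sxx = _smooth((np.abs(Wx) ** 2) * inv_s, scales, fs, voices).real
        Syy = _smooth((np.abs(Wy) ** 2) * inv_s, scales, fs, voices).real
    else:
        Sxy = Wx * np.conj(Wy) * inv_s
        Sxx = (np.abs(Wx) ** 2) * inv_s
        Syy = (np.abs(Wy) ** 2) * inv_s
    denom = Sxx * Syy
    denom[denom <= 0] = np.finfo(float).tiny
    coh = (np.abs(Sxy) ** 2) / denom
    coh = np.clip(coh, 0.0, 1.0)
    return WCohMap(
        coh=coh.T,
        time_axis=np.arange(x.size) / fs,
        scales=scales,
        freqs=freqs,
        coi_valid=coi_mask(x.size, scales, fs),
        n_trials=1,
    )


def dyad_trial_coherence(
    es_r: EpochSet,
    es_o: EpochSet,
    channel: str,
    condition: str | None = None,
    band: tuple[float, float] = (4.0, 7.0),
    voices: int = 12,
) -> WCohMap:
    """Average per-trial coherence between homologous dyad channels.

    Requires intersected epoch sets (identical surviving trials): the
    coherence of each shared artifact-free trial is computed and the maps
    are averaged arithmetically.
    """
    if es_r.n_trials != es_o.n_trials or es_r.labels != es_o.labels:
        raise ValueError("epoch sets are not from the same trial table")
    if not np.array_equal(es_r.keep_mask, es_o.keep_mask):
        raise ValueError("epoch sets must be intersected (identical keep masks)")
    idx = es_r.kept_indices(condition)
    if idx.size < 2:
        raise ValueError(
            f"need >= 2 surviving trials for condition {condition!r}, got {idx.size}"
        )
    ci_r = es_r.channel_index(channel)
    ci_o = es_o.channel_index(channel)
    acc = None
    for k in idx:
        m = wavelet_coherence(
            es_r.epochs[k, ci_r], es_o.epochs[k, ci_o], es_r.fs, band, voices
        )
        acc = m.coh if acc is None else acc + m.coh
    mean = acc / idx.size
    return WCohMap(
        coh=mean,
        time_axis=es_r.time_axis.copy(),
        scales=m.scales,
        freqs=m.freqs,
        coi_valid=m.coi_valid,
        n_trials=int(idx.size),
        name=f"{channel}:{condition or 'all'}",
    )


def collapse_band(
    wmap: WCohMap, band: tuple[float, float] = (4.0, 7.0)
) -> CohTimeCourse:
    """Unweighted mean over in-band scales, excluding COI-masked cells.

    Edge samples are computed from however many scales remain valid there
    (``n_valid_scales`` reports the count); samples with no valid scale
    are NaN.
    """
    sel = (wmap.freqs >= band[0]) & (wmap.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} outside the map's frequency axis")
    coh = wmap.coh[:, sel]
    valid = wmap.coi_valid[:, sel]
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vals = np.where(
            n_valid > 0,
            np.where(valid, coh, 0.0).sum(axis=1) / np.maximum(n_valid, 1),
            np.nan,
        )
    return CohTimeCourse(
        values=vals,
        time_axis=wmap.time_axis.copy(),
        band=band,
        n_valid_scales=n_valid,
        name=wmap.name,
    )


def power_phase_diagnostic(
    es_r: EpochSet,
    es_o: EpochSet,
    channel: str,
    condition: str | None = None,
    band: tuple[float, float] = (4.0, 7.0),
    voices: int = 12,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-time circular-linear correlation of trial power vs cross phase.

    For every time sample, correlates each subject's trial-wise band-mean
    wavelet power with the phase of the trial cross-spectrum
    (Mardia circular-linear correlation; p via the chi-square(2)
    approximation n*R^2). A lack of correlation supports interpreting
    coherence effects as phase alignment rather than amplitude artifacts.
    Returns ``{"receiver": {"r": ..., "p": ..., "degenerate": ...}, "observer": ...}``.
    """
    if not np.array_equal(es_r.keep_mask, es_o.keep_mask):
        raise ValueError("epoch sets must be intersected")
    idx = es_r.kept_indices(condition)
    if idx.size < 10:
        raise ValueError(f"need >= 10 trials, got {idx.size}")
    scales, _ = morlet_scales(band, voices)
    ci_r = es_r.channel_index(channel)
    ci_o = es_o.channel_index(channel)
    n_time = es_r.epochs.shape[2]
    pow_r = np.empty((idx.size, n_time))
    pow_o = np.empty((idx.size, n_time))
    phase = np.empty((idx.size, n_time))
    for row, k in enumerate(idx):
        Wr = morlet_cwt(es_r.epochs[k, ci_r], scales, es_r.fs)
        Wo = morlet_cwt(es_o.epochs[k, ci_o], scales, es_o.fs)
        pow_r[row] = (np.abs(Wr) ** 2).mean(axis=0)
        pow_o[row] = (np.abs(Wo) ** 2).mean(axis=0)
        phase[row] = np.angle((Wr * np.conj(Wo)).mean(axis=0))
    out = {}
    for role, power in (("receiver", pow_r), ("observer", pow_o)):
        r = np.full(n_time, np.nan)
        p = np.full(n_time, np.nan)
        degenerate = np.zeros(n_time, dtype=bool)
        for t in range(n_time):
            r[t], p[t], degenerate[t] = _circ_linear_corr(power[:, t], phase[:, t])
        out[role] = {"r": r, "p": p, "degenerate": degenerate}
    return out


def _circ_linear_corr(x: np.ndarray, theta: np.ndarray) -> tuple[float, float, bool]:
    """Mardia's circular-linear correlation of linear x with angles theta."""
    n = x.size
    c, s = np.cos(theta), np.sin(theta)
    if np.std(x) == 0 or np.std(c) == 0 or np.std(s) == 0:
        return np.nan, np.nan, True
    rxc = np.corrcoef(x, c)[0, 1]
    rxs = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    denom = 1 - rcs**2
    if denom <= 1e-12:
        return np.nan, np.nan, True
    r2 = (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / denom
    r2 = min(max(r2, 0.0), 1.0)
    p = float(sps.chi2.sf(n * r2, df=2))
    return float(np.sqrt(r2)), p, False
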