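"""Frequency-domain HRV markers.

Band powers (ULF, VLF, LF, HF, total, LF/HF) are obtained by integrating a
Welch power spectral density of the uniformly resampled tachogram over
conventional frequency bands. Two time-resolved ULF summaries complement
them: the interquartile range of a short-time-Fourier band-power track
("ULF Fourier") and the median of a maximal-overlap discrete wavelet
transform band-energy track ("ULF wavelet"). ULF oscillations have periods
of five minutes and longer (circadian rhythm, thermoregulation), so the
time-resolved estimators use windows much longer than the 5-min Welch
segments.

Internally all powers are in ms^2 (PSD in ms^2/Hz integrated over Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .preprocess import InsufficientDataError, Tachogram

__all__ = [
    "BandScheme",
    "FreqMarkers",
    "PowerTrack",
    "band_powers",
    "stft_band_series",
    "wavelet_band_series",
    "frequency_markers",
    "modwt",
]


@dataclass
class BandScheme:
    """Frequency band edges in Hz; each band is the half-open interval (lo, hi].

    Defaults follow the conventional long-term HRV bands, with the ULF upper
    edge at 1/300 Hz (period 5 min).
    """

    ulf: tuple[float, float] = (0.0, 1.0 / 300.0)
    vlf: tuple[float, float] = (1.0 / 300.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self) -> None:
        seq = [self.ulf, self.vlf, self.lf, self.hf]
        for lo, hi in seq:
            if not lo < hi:
                raise ValueError("band edges must be increasing")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(seq, seq[1:]):
            if a_hi != b_lo:
                raise ValueError("bands must be contiguous and non-overlapping")

    def items(self):
        return [("ulf", self.ulf), ("vlf", self.vlf), ("lf", self.lf), ("hf", self.hf)]


@dataclass
class FreqMarkers:
    ulf: float | None
    vlf: float | None
    lf: float | None
    hf: float | None
    total_power: float | None
    lf_hf: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "ulf": self.ulf,
            "vlf": self.vlf,
            "lf": self.lf,
            "hf": self.hf,
            "lf_hf": self.lf_hf,
            "total_power": self.total_power,
        }


@dataclass
class PowerTrack:
    """Band power as a function of time (window centres or sample times)."""

    times: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.times) != len(self.power):
            raise ValueError("times and power must have equal length")

    def iqr(self) -> float:
        q1, q3 = np.percentile(self.power, [25, 75])
        return float(q3 - q1)

    def median(self) -> float:
        return float(np.median(self.power))


def _detrend(x: np.ndarray) -> np.ndarray:
    """Remove mean and linear trend."""
    return signal.detrend(np.asarray(x, dtype=float), type="linear")


def _integrate_band(
    freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float
) -> float | None:
    """Integrate a PSD over the half-open band (lo, hi]; None if unresolved."""
    mask = (freqs > lo) & (freqs <= hi)
    if not np.any(mask):
        return None
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[mask]) * df)


def band_powers(
    tg: Tachogram,
    bands: BandScheme | None = None,
    segment_s: float = 300.0,
    overlap: float = 0.5,
) -> FreqMarkers:
    """Welch band powers of a tachogram.

    The tachogram is detrended (mean and linear trend removed), a Welch PSD
    is estimated with Hann-windowed segments (default 5 min, 50% overlap),
    and each band power is the PSD integral over the band. Total power is the
    integral over (0, hf_upper]. Bands that contain no Fourier bin at the
    achieved resolution are reported as missing, as is LF/HF when HF is zero.
    """
    bands = bands or BandScheme()
    x = _detrend(tg.values)
    nperseg = min(int(round(segment_s * tg.rate)), len(x))
    if nperseg < 8:
        raise InsufficientDataError("tachogram too short for spectral analysis")
    noverlap = int(nperseg * overlap)
    freqs, psd = signal.welch(
        x, fs=tg.rate, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )
    out = {name: _integrate_band(freqs, psd, lo, hi) for name, (lo, hi) in bands.items()}
    total = _integrate_band(freqs, psd, 0.0, bands.hf[1])
    lf, hf = out["lf"], out["hf"]
    lf_hf = None
    # guard against numerically-zero HF power (e.g. a constant tachogram)
    floor = 1e-12 * max(float(np.var(x)), 1.0)
    if lf is not None and hf is not None and hf > floor:
        lf_hf = lf / hf
    return FreqMarkers(
        ulf=out["ulf"], vlf=out["vlf"], lf=lf, hf=hf,
        total_power=total, lf_hf=lf_hf,
    )


def stft_band_series(
    tg: Tachogram,
    band: tuple[float, float] = (0.0, 1.0 / 300.0),
    window_s: float = 1800.0,
    shift_s: float = 300.0,
) -> PowerTrack:
    """Short-time Fourier band-power track.

    Each window (default 30 min, stepped by 5 min) is detrended and its
    Hann periodogram integrated over the band; the ULF-Fourier marker is the
    interquartile range of the resulting track. The long default window is
    required to resolve oscillation periods of 5 min and above.
    """
    nwin = int(round(window_s * tg.rate))
    nshift = max(1, int(round(shift_s * tg.rate)))
    x = np.asarray(tg.values, dtype=float)
    if len(x) < nwin:
        raise InsufficientDataError(
            f"tachogram shorter than the STFT window ({len(x)} < {nwin} samples)"
        )
    times, powers = [], []
    for start in range(0, len(x) - nwin + 1, nshift):
        seg = _detrend(x[start : start + nwin])
        freqs, psd = signal.periodogram(
            seg, fs=tg.rate, window="hann", detrend=False
        )
        p = _integrate_band(freqs, psd, band[0], band[1])
        if p is None:
            raise InsufficientDataError(
                "STFT window cannot resolve the requested band"
            )
        times.append(tg.start_time + (start + nwin / 2) / tg.rate)
        powers.append(p)
    return PowerTrack(np.asarray(times), np.asarray(powers))


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    # MODWT filters are the DWT filters rescaled by 1/sqrt(2)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)
    return g, h


def modwt(x: np.ndarray, wavelet: str, levels: int) -> np.ndarray:
    """Maximal-overlap discrete wavelet transform (circular boundary).

    Returns an array of shape (levels, n) of detail coefficients
    W[j-1, t] = sum_l h_l V_{j-1}[(t - 2^(j-1) l) mod n], following the
    standard pyramid with per-level upsampled filters.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    g, h = _modwt_filters(wavelet)
    L = len(g)
    v = x.copy()
    idx_base = np.arange(n)
    details = np.empty((levels, n))
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        w_j = np.zeros(n)
        v_next = np.zeros(n)
        for l in range(L):
            shifted = v[(idx_base - step * l) % n]
            w_j += h[l] * shifted
            v_next += g[l] * shifted
        details[j - 1] = w_j
        v = v_next
    return details


def _band_levels(
    rate: float, band: tuple[float, float], max_level: int
) -> list[int]:
    """Levels whose nominal dyadic band [rate/2^(j+1), rate/2^j] meets band."""
    lo, hi = band
    levels = []
    for j in range(1, max_level + 1):
        lvl_lo, lvl_hi = rate / 2 ** (j + 1), rate / 2**j
        if lvl_lo < hi and lvl_hi > lo:
            levels.append(j)
    return levels


def wavelet_band_series(
    tg: Tachogram,
    band: tuple[float, float] = (0.0, 1.0 / 300.0),
    wavelet: str = "sym8",
) -> PowerTrack:
    """MODWT band-energy track.

    The detrended tachogram is decomposed with a maximal-overlap discrete
    wavelet transform (least-asymmetric order-8 wavelet by default); the
    track is the per-time-point sum of squared detail coefficients over the
    levels whose nominal dyadic frequency ranges intersect the band. The
    ULF-wavelet marker is the median of this track.
    """
    x = _detrend(tg.values)
    n = len(x)
    g, _ = _modwt_filters(wavelet)
    L = len(g)
    # deepest level whose equivalent filter support fits in the series
    max_feasible = 0
    while (2 ** (max_feasible + 1) - 1) * (L - 1) + 1 <= n:
        max_feasible += 1
    levels = _band_levels(tg.rate, band, max_feasible)
    if not levels:
        finest = tg.rate / 2 ** (max_feasible + 1)
        raise InsufficientDataError(
            f"band {band} not resolvable: feasible levels 1..{max_feasible} "
            f"reach down to {finest:.2e} Hz only"
        )
    details = modwt(x, wavelet, max(levels))
    power = np.zeros(n)
    for j in levels:
        power += details[j - 1] ** 2
    return PowerTrack(tg.times, power)


def frequency_markers(
    tg: Tachogram,
    bands: BandScheme | None = None,
    stft_window_s: float = 1800.0,
    stft_shift_s: float = 300.0,
    wavelet: str = "sym8",
) -> dict[str, float | None]:
    """All eight frequency-domain marker columns for one tachogram."""
    bands = bands or BandScheme()
    out: dict[str, float | None] = band_powers(tg, bands).as_dict()
    try:
        out["ulf_fourier"] = stft_band_series(
            tg, bands.ulf, stft_window_s, stft_shift_s
        ).iqr()
    except InsufficientDataError:
        out["ulf_fourier"] = None
    try:
        out["ulf_wavelet"] = wavelet_band_series(tg, bands.ulf, wavelet).median()
    except InsufficientDataError:
        out["ulf_wavelet"] = None
    return out
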