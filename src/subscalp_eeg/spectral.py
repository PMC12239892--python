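"""Multitaper spectral estimation, 1/f fitting and band peak extraction.

Power spectral densities are estimated with DPSS (Slepian) tapers over 5-s
sliding windows with 50% overlap, averaged over tapers and windows.  The
broadband aperiodic component is a straight line in log10-power versus
log10-frequency; an oscillation's "band peak power" is the maximal dB
departure of the spectrum above that line within the band — the unit in
which the -0.5 dB noninferiority margin is expressed.  Magnitude-squared
coherence pools cross- and auto-spectra over all taper-window segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.signal.windows import dpss

__all__ = [
    "MultitaperSpectrum",
    "AperiodicFit",
    "BandPeak",
    "CoherenceSpectrum",
    "Spectrogram",
    "multitaper_psd",
    "fit_aperiodic",
    "band_peak_power",
    "coherence",
    "coherence_from_stft",
    "band_peak_coherence",
    "band_mean_coherence",
    "spectrogram",
    "tapered_stft",
    "n_sliding_windows",
]

DEFAULT_WINDOW_S = 5.0
DEFAULT_OVERLAP = 0.5
DEFAULT_TIME_BANDWIDTH = 4.0
MIN_COHERENCE_WINDOWS = 8


@dataclass
class MultitaperSpectrum:
    frequencies: np.ndarray  # Hz, spacing 1/window_length
    power: np.ndarray  # one-sided density, uV^2/Hz
    window_length: float
    overlap_fraction: float
    n_windows: int
    time_bandwidth: float
    degenerate: bool = False  # all-constant input: no power away from DC

    @property
    def power_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10 * np.log10(self.power)

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.frequencies >= lo) & (self.frequencies <= hi)


@dataclass
class AperiodicFit:
    """Least-squares line through (log10 f, log10 power): P(f) ~ c * f^-exponent."""

    offset: float  # log10 power density at 1 Hz
    exponent: float
    fit_range: tuple[float, float]

    def fitted_log10(self, frequencies: np.ndarray) -> np.ndarray:
        f = np.asarray(frequencies, float)
        with np.errstate(divide="ignore"):
            return self.offset - self.exponent * np.log10(f)

    def fitted_db(self, frequencies: np.ndarray) -> np.ndarray:
        return 10 * self.fitted_log10(frequencies)


@dataclass
class BandPeak:
    band_name: str
    band: tuple[float, float]
    peak_frequency: float
    peak_power_db: float  # dB above the aperiodic fit; negative if no peak


@dataclass
class CoherenceSpectrum:
    frequencies: np.ndarray
    coherence: np.ndarray  # magnitude-squared, in [0, 1]
    n_windows: int
    n_tapers: int
    bias_floor_value: Optional[float] = None

    @property
    def n_segments(self) -> int:
        """Number of pooled taper-window segments K."""
        return self.n_windows * self.n_tapers

    @property
    def bias_floor(self) -> float:
        """Expected coherence of independent signals.

        1/K for K independent segments; when the estimator was built with
        overlapping windows the stored exact value (which accounts for the
        correlation between overlapping segments) is returned instead.
        """
        if self.bias_floor_value is not None:
            return self.bias_floor_value
        return 1.0 / self.n_segments


@dataclass
class Spectrogram:
    times: np.ndarray  # window centers, s
    frequencies: np.ndarray
    power_db: np.ndarray  # (n_freqs, n_times)
    flattened: bool
    window_length: float
    overlap_fraction: float


def n_sliding_windows(n_samples: int, window_samples: int, step: int) -> int:
    if n_samples < window_samples:
        return 0
    return (n_samples - window_samples) // step + 1


@lru_cache(maxsize=16)
def _dpss_tapers(window_samples: int, time_bandwidth: float,
                 n_tapers: int) -> np.ndarray:
    return dpss(window_samples, time_bandwidth, n_tapers)


@lru_cache(maxsize=16)
def _adjacent_window_leakage(window_samples: int, time_bandwidth: float,
                             n_tapers: int, step: int) -> float:
    """Sum over taper pairs of the squared overlap inner products.

    For independent white inputs, segments from adjacent overlapping windows
    are correlated through q_kl = sum_t d_k(t) d_l(t + step); this quantity
    sets the excess of the coherence bias floor over the independent-segment
    value 1/K.
    """
    if step >= window_samples:
        return 0.0
    tapers = _dpss_tapers(window_samples, time_bandwidth, n_tapers)
    q = tapers[:, : window_samples - step] @ tapers[:, step:].T
    return float((q**2).sum())


def expected_coherence_floor(n_windows: int, n_tapers: int,
                             window_samples: int, time_bandwidth: float,
                             step: int) -> float:
    """Expected MSC of independent signals for the pooled estimator."""
    k = n_windows * n_tapers
    q2 = _adjacent_window_leakage(window_samples, time_bandwidth, n_tapers,
                                  step)
    return (k + 2 * (n_windows - 1) * q2) / k**2


def tapered_stft(
    x: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """DPSS-tapered sliding-window Fourier coefficients.

    Returns ``(frequencies, X)`` with ``X`` of shape
    ``(..., n_windows, n_tapers, n_freqs)``; ``x`` may be 1D or (channels,
    samples).  Tapers are unit-energy; 2*NW - 2 tapers are retained for
    time-bandwidth NW, the ones whose spectral concentration exceeds 0.99 —
    the marginally concentrated last taper would otherwise leak the power
    of strong low-frequency oscillations across the whole spectrum and
    corrupt the 1/f fit.
    """
    x = np.asarray(x, float)
    w = int(round(window_s * fs))
    step = max(1, int(round(w * (1 - overlap))))
    n = x.shape[-1]
    n_win = n_sliding_windows(n, w, step)
    if n_win < 1:
        raise ValueError(
            f"signal of {n} samples is shorter than one {w}-sample window"
        )
    n_tapers = max(1, int(2 * time_bandwidth - 2))
    tapers = _dpss_tapers(w, time_bandwidth, n_tapers)  # (n_tapers, w), unit energy
    idx = np.arange(w)[None, :] + step * np.arange(n_win)[:, None]
    segments = x[..., idx]  # (..., n_win, w)
    tapered = segments[..., None, :] * tapers[None, :, :]  # (..., n_win, K, w)
    X = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(w, 1 / fs)
    return freqs, X


def multitaper_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
) -> MultitaperSpectrum:
    """One-sided multitaper PSD averaged over tapers and sliding windows.

    Normalized as a density: the integral over frequency equals the signal
    variance (Parseval).  An all-constant signal yields a degenerate
    spectrum (zero density away from DC), flagged rather than raised.
    """
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("multitaper_psd expects a single-channel 1D signal")
    freqs, X = tapered_stft(x, fs, window_s, overlap, time_bandwidth)
    n_win, n_tapers = X.shape[0], X.shape[1]
    power = (np.abs(X) ** 2).mean(axis=(0, 1)) / fs
    power[1:] *= 2.0
    w = int(round(window_s * fs))
    if w % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    degenerate = bool(np.ptp(x) == 0)
    return MultitaperSpectrum(
        frequencies=freqs,
        power=power,
        window_length=window_s,
        overlap_fraction=overlap,
        n_windows=n_win,
        time_bandwidth=time_bandwidth,
        degenerate=degenerate,
    )


def fit_aperiodic(
    spectrum: MultitaperSpectrum,
    fit_range: tuple[float, float] = (1.0, 45.0),
    exclude_bands: Sequence[tuple[float, float]] = (),
    min_bins: int = 10,
) -> AperiodicFit:
    """Fit the 1/f aperiodic line over ``fit_range``, excluding oscillation bands."""
    lo, hi = fit_range
    f = spectrum.frequencies
    if lo < f[f > 0].min() - 1e-9 or hi > f.max() + 1e-9:
        raise ValueError(
            f"fit_range {fit_range} outside spectrum support "
            f"({f[f > 0].min():.2f}-{f.max():.2f} Hz)"
        )
    mask = (f >= lo) & (f <= hi)
    for b_lo, b_hi in exclude_bands:
        mask &= ~((f >= b_lo) & (f <= b_hi))
    mask &= spectrum.power > 0
    if mask.sum() < min_bins:
        raise ValueError(
            f"only {int(mask.sum())} frequency bins remain after exclusion; "
            f"need at least {min_bins}"
        )
    logf = np.log10(f[mask])
    logp = np.log10(spectrum.power[mask])
    slope, intercept = np.polyfit(logf, logp, 1)
    return AperiodicFit(offset=float(intercept), exponent=float(-slope),
                        fit_range=(lo, hi))


def band_peak_power(
    spectrum: MultitaperSpectrum,
    fit: AperiodicFit,
    band: tuple[float, float],
    band_name: str = "",
) -> BandPeak:
    """Maximal dB departure of the spectrum above the aperiodic fit in ``band``.

    May be negative when no oscillation rises above the broadband background.
    """
    mask = spectrum.band_slice(band)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency grid points")
    departure = spectrum.power_db[mask] - fit.fitted_db(spectrum.frequencies[mask])
    i = int(np.argmax(departure))
    return BandPeak(
        band_name=band_name,
        band=tuple(band),
        peak_frequency=float(spectrum.frequencies[mask][i]),
        peak_power_db=float(departure[i]),
    )


def coherence_from_stft(
    Xa: np.ndarray, Xb: np.ndarray, freqs: np.ndarray
) -> CoherenceSpectrum:
    """Magnitude-squared coherence from two tapered STFTs (windows, tapers, freqs)."""
    if Xa.shape != Xb.shape:
        raise ValueError("STFT shapes differ")
    sab = np.einsum("wkf,wkf->f", Xa, np.conj(Xb))
    saa = (np.abs(Xa) ** 2).sum(axis=(0, 1))
    sbb = (np.abs(Xb) ** 2).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(sab) ** 2 / (saa * sbb)
    msc = np.clip(np.nan_to_num(msc), 0.0, 1.0)
    return CoherenceSpectrum(
        frequencies=freqs,
        coherence=msc,
        n_windows=Xa.shape[0],
        n_tapers=Xa.shape[1],
    )


def coherence(
    a: np.ndarray,
    b: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
    min_windows: int = MIN_COHERENCE_WINDOWS,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence |S_ab|^2 / (S_aa S_bb).

    Cross- and auto-spectra are pooled over tapers x windows (Welch-style);
    a minimum of ``min_windows`` sliding windows is required, since coherence
    is undefined from a single segment.  Independent signals give an expected
    coherence of ~1/K, where K = tapers x windows.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coherence expects two equal-length 1D signals")
    w = int(round(window_s * fs))
    step = max(1, int(round(w * (1 - overlap))))
    n_win = n_sliding_windows(len(a), w, step)
    if n_win < min_windows:
        raise ValueError(
            f"{n_win} windows available but coherence requires at least "
            f"{min_windows}; provide a longer signal or shorter window"
        )
    freqs, Xa = tapered_stft(a, fs, window_s, overlap, time_bandwidth)
    _, Xb = tapered_stft(b, fs, window_s, overlap, time_bandwidth)
    out = coherence_from_stft(Xa, Xb, freqs)
    out.bias_floor_value = expected_coherence_floor(
        out.n_windows, out.n_tapers, w, time_bandwidth, step
    )
    return out


def band_peak_coherence(coh: CoherenceSpectrum, band: tuple[float, float]) -> float:
    """Maximum coherence over the band grid."""
    lo, hi = band
    mask = (coh.frequencies >= lo) & (coh.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency grid points")
    return float(coh.coherence[mask].max())


def band_mean_coherence(
    coh: CoherenceSpectrum, freq_range: tuple[float, float] = (0.5, 30.0)
) -> float:
    """Arithmetic mean coherence over grid points in ``freq_range``."""
    lo, hi = freq_range
    mask = (coh.frequencies >= lo) & (coh.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"range {freq_range} contains no frequency grid points")
    return float(coh.coherence[mask].mean())


def spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
    flatten: bool = False,
    fit: Optional[AperiodicFit] = None,
    fit_range: tuple[float, float] = (1.0, 45.0),
) -> Spectrogram:
    """Sliding-window multitaper spectrogram, optionally 1/f-flattened.

    With ``flatten=True`` the session-level aperiodic fit (supplied, or
    estimated from the time-averaged spectrum) is subtracted, in dB, from
    every column, so stationary power-law noise averages to 0 dB everywhere.
    """
    freqs, X = tapered_stft(x, fs, window_s, overlap, time_bandwidth)
    w = int(round(window_s * fs))
    step = max(1, int(round(w * (1 - overlap))))
    power = (np.abs(X) ** 2).mean(axis=1) / fs  # (n_win, n_freqs)
    power[:, 1:] *= 2.0
    if w % 2 == 0:
        power[:, -1] /= 2.0
    n_win = power.shape[0]
    times = (w / 2 + step * np.arange(n_win)) / fs
    with np.errstate(divide="ignore"):
        power_db = 10 * np.log10(power.T)
    if flatten:
        if fit is None:
            mean_spec = MultitaperSpectrum(
                frequencies=freqs,
                power=power.mean(axis=0),
                window_length=window_s,
                overlap_fraction=overlap,
                n_windows=n_win,
                time_bandwidth=time_bandwidth,
            )
            fit = fit_aperiodic(mean_spec, fit_range=fit_range)
        power_db = power_db - fit.fitted_db(freqs)[:, None]
    return Spectrogram(
        times=times,
        frequencies=freqs,
        power_db=power_db,
        flattened=flatten,
        window_length=window_s,
        overlap_fraction=overlap,
    )
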