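"""Spectral preprocessing: low-pass filtering, epoching, per-epoch
cross-spectral densities, and individual-alpha-peak-frequency (IAPF)
anchored band definitions.

The pipeline works on *cleaned* continuous EEG.  Artifact removal, channel
interpolation and re-referencing are upstream concerns and are not handled
here.

Band edges are defined relative to each subject's IAPF: delta spans
[IAPF-8, IAPF-6), theta [IAPF-6, IAPF-4), alpha [IAPF-4, IAPF+2) and beta
[IAPF+2, 30] Hz.  The four bands tile [IAPF-8, 30] without gaps or overlap,
so band membership of a frequency bin is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

__all__ = [
    "ContinuousEEG",
    "EpochSet",
    "CrossSpectralDensity",
    "IAPFEstimate",
    "BandDefinition",
    "BAND_NAMES",
    "lowpass_filter",
    "segment_epochs",
    "compute_csd",
    "estimate_iapf",
    "derive_bands",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta")


@dataclass
class ContinuousEEG:
    """Cleaned multichannel EEG time series.

    Parameters
    ----------
    channel_labels : list of str
        Unique sensor names (10-10 system for the default montage).
    sampling_rate : float
        Sampling frequency in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    units: str = "µV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            ch, smp = bad[0]
            raise ValueError(
                f"non-finite samples, first at channel "
                f"{self.channel_labels[ch]!r} sample {smp}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class EpochSet:
    """Overlapping fixed-length segments of a continuous recording."""

    data: np.ndarray  # (epochs, channels, samples)
    sampling_rate: float
    epoch_length: float
    overlap: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class CrossSpectralDensity:
    """Per-epoch cross-spectral densities in factored form.

    Rather than materialising the full ``(epochs, channels, channels,
    freqs)`` complex array, the per-epoch tapered Fourier coefficients
    ``spectra`` with shape ``(epochs, channels, freqs)`` are stored; the
    cross-spectrum of a pair is ``X_i * conj(X_j)``.  This representation
    is Hermitian in the channel pair by construction and keeps memory
    linear in the channel count.

    Coefficients are scaled so that ``X_i * conj(X_i)`` is a one-sided
    spectral density: summing the auto-spectrum times the bin width
    recovers the (windowed) signal variance.
    """

    freqs: np.ndarray
    spectra: np.ndarray  # (epochs, channels, freqs), complex
    channel_labels: list[str]
    epoch_length: float

    @property
    def n_epochs(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]

    @property
    def df(self) -> float:
        """Frequency resolution (1 / epoch_length) in Hz."""
        return 1.0 / self.epoch_length

    def pair(self, i: int, j: int) -> np.ndarray:
        """Cross-spectrum of channels ``(i, j)``: (epochs, freqs) complex."""
        return self.spectra[:, i, :] * np.conj(self.spectra[:, j, :])

    def at_bin(self, b: int) -> np.ndarray:
        """Full Hermitian CSD matrix at one frequency bin: (epochs, n, n)."""
        x = self.spectra[:, :, b]
        return x[:, :, None] * np.conj(x[:, None, :])

    def auto_psd(self) -> np.ndarray:
        """Epoch-averaged power spectral density, shape (channels, freqs)."""
        return np.mean(np.abs(self.spectra) ** 2, axis=0)


@dataclass(frozen=True)
class IAPFEstimate:
    """Subject-level individual alpha peak frequency."""

    iapf: float
    n_channels_contributing: int
    quality_flag: str  # "ok" | "no_peak"


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [f_lo, f_hi); beta is closed at 30 Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of bin centres belonging to this band."""
        freqs = np.asarray(freqs, dtype=float)
        if self.name == "beta":
            return (freqs >= self.f_lo) & (freqs <= self.f_hi)
        return (freqs >= self.f_lo) & (freqs < self.f_hi)


def lowpass_filter(eeg: ContinuousEEG, cutoff: float = 30.0,
                   order: int = 5) -> ContinuousEEG:
    """Zero-phase Butterworth low-pass.

    Applied forward-backward (``sosfiltfilt``) so the passband has no group
    delay.  The default order 5 gives more than 20 dB of power attenuation
    at 1.25x the cutoff after the two passes.
    """
    nyq = eeg.sampling_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=eeg.sampling_rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, eeg.data, axis=1)
    return ContinuousEEG(list(eeg.channel_labels), eeg.sampling_rate,
                         filtered, eeg.units)


def segment_epochs(eeg: ContinuousEEG, length: float = 12.0,
                   overlap: float = 0.5) -> EpochSet:
    """Cut the recording into overlapping epochs.

    With step ``length * (1 - overlap)`` the epoch count is
    ``floor((duration - length) / step) + 1``; trailing samples that do not
    fill a whole epoch are discarded.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    n_per = int(round(length * eeg.sampling_rate))
    if eeg.n_samples < n_per:
        raise ValueError(
            f"recording of {eeg.duration:.3f} s is shorter than one "
            f"{length} s epoch"
        )
    step = int(round(length * (1 - overlap) * eeg.sampling_rate))
    starts = np.arange(0, eeg.n_samples - n_per + 1, step)
    data = np.stack([eeg.data[:, s:s + n_per] for s in starts])
    return EpochSet(data, eeg.sampling_rate, length, overlap,
                    list(eeg.channel_labels))


def compute_csd(epochs: EpochSet, fmax: float | None = None
                ) -> CrossSpectralDensity:
    """Per-epoch Hanning-tapered cross-spectral densities.

    Each epoch is demeaned, multiplied by a single Hann taper and Fourier
    transformed; the frequency resolution is ``1 / epoch_length``.  At
    least two epochs are required because the dwPLI estimator downstream
    needs multiple independent observations of the cross-spectrum.
    """
    if epochs.n_epochs < 2:
        raise ValueError(
            "need at least 2 epochs: the debiased WPLI estimator requires "
            "multiple cross-spectrum observations"
        )
    n_per = epochs.data.shape[2]
    fs = epochs.sampling_rate
    win = sps.windows.hann(n_per, sym=False)
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    coeffs = rfft(data * win, axis=2)
    freqs = rfftfreq(n_per, d=1.0 / fs)
    # density scaling: auto-spectrum integrates (one-sided) to the
    # windowed variance, as in a Hann-windowed periodogram
    scale = np.sqrt(1.0 / (fs * np.sum(win ** 2)))
    coeffs = coeffs * scale
    onesided = np.full(freqs.shape, np.sqrt(2.0))
    onesided[0] = 1.0
    if n_per % 2 == 0:
        onesided[-1] = 1.0
    coeffs = coeffs * onesided
    if fmax is not None:
        keep = freqs <= fmax + 1e-12
        freqs = freqs[keep]
        coeffs = coeffs[:, :, keep]
    return CrossSpectralDensity(freqs, coeffs, list(epochs.channel_labels),
                                epochs.epoch_length)


def _smooth_psd(psd: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    window = min(window, psd.shape[-1] if psd.shape[-1] % 2 else psd.shape[-1] - 1)
    if window <= polyorder:
        return psd
    return sps.savgol_filter(psd, window_length=window, polyorder=polyorder,
                             axis=-1)


def estimate_iapf(epochs: EpochSet | CrossSpectralDensity,
                  search_window: tuple[float, float] = (7.0, 13.0),
                  smooth_window: int = 11,
                  smooth_polyorder: int = 5,
                  min_rise: float = 1.0) -> IAPFEstimate:
    """Estimate the individual alpha peak frequency.

    Per channel the epoch-averaged power spectrum is smoothed with a
    Savitzky-Golay filter and the largest local maximum (negative second
    difference) inside ``search_window`` is taken as the channel peak.
    To qualify, a peak must exceed a power-law background (log-log
    linear fit over the window) by at least ``min_rise`` times the
    background level — i.e. reach (1 + min_rise) x background — so noise
    ripples on a peakless spectrum do not count.  The subject IAPF is
    the prominence-weighted mean of channel peaks; channels without a
    qualifying peak do not contribute.  If no channel has a peak the
    estimate is flagged ``no_peak`` rather than raising.
    """
    csd = epochs if isinstance(epochs, CrossSpectralDensity) \
        else compute_csd(epochs)
    psd = csd.auto_psd()
    freqs = csd.freqs
    smoothed = _smooth_psd(psd, smooth_window, smooth_polyorder)

    lo, hi = search_window
    in_win = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_win):
        return IAPFEstimate(float("nan"), 0, "no_peak")

    win_idx = np.flatnonzero(in_win)
    peak_freqs: list[float] = []
    prominences: list[float] = []
    for ch in range(smoothed.shape[0]):
        spec = smoothed[ch]
        # power-law background over the search window
        f_win = freqs[in_win]
        p_win = spec[in_win]
        good = (f_win > 0) & (p_win > 0)
        if good.sum() >= 2:
            coef = np.polyfit(np.log(f_win[good]), np.log(p_win[good]), 1)
            background = np.exp(np.polyval(coef, np.log(np.maximum(
                f_win, 1e-12))))
        else:
            background = np.full(f_win.shape, max(np.median(p_win), 1e-30))
        bg = dict(zip(win_idx.tolist(), background))
        idx, _ = sps.find_peaks(spec)
        # genuine local maxima inside the window, with negative curvature,
        # rising at least (1 + min_rise) x above the fitted background
        idx = [i for i in idx
               if in_win[i] and 0 < i < len(spec) - 1
               and spec[i - 1] - 2 * spec[i] + spec[i + 1] < 0
               and spec[i] >= (1.0 + min_rise) * bg[i]]
        if not idx:
            continue
        proms = sps.peak_prominences(spec, idx)[0]
        best = int(np.argmax(spec[idx]))
        peak_freqs.append(float(freqs[idx[best]]))
        prominences.append(float(max(proms[best], 1e-30)))
    if not peak_freqs:
        return IAPFEstimate(float("nan"), 0, "no_peak")
    w = np.asarray(prominences)
    iapf = float(np.sum(w * np.asarray(peak_freqs)) / np.sum(w))
    return IAPFEstimate(iapf, len(peak_freqs), "ok")


def derive_bands(iapf: IAPFEstimate | float,
                 beta_top: float = 30.0) -> list[BandDefinition]:
    """IAPF-relative band edges.

    delta [IAPF-8, IAPF-6), theta [IAPF-6, IAPF-4), alpha [IAPF-4, IAPF+2),
    beta [IAPF+2, 30].  The bands shift rigidly with the IAPF and tile
    [IAPF-8, 30] without gaps.
    """
    if isinstance(iapf, IAPFEstimate):
        if iapf.quality_flag != "ok":
            raise ValueError(
                "no alpha peak detected; pass a canonical IAPF (e.g. 10 Hz) "
                "explicitly to fall back to fixed bands"
            )
        f = iapf.iapf
    else:
        f = float(iapf)
    return [
        BandDefinition("delta", f - 8, f - 6),
        BandDefinition("theta", f - 6, f - 4),
        BandDefinition("alpha", f - 4, f + 2),
        BandDefinition("beta", f + 2, beta_top),
    ]
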