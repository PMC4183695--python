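"""Per-epoch EEG power spectra with the parabolic Welch taper.

Each 30-s epoch (6000 samples at 200 Hz) is cut into 512-point windows
overlapping by half (22 windows per epoch).  Every window is demeaned and
detrended by subtracting its linear least-squares fit, multiplied by the
parabolic Welch taper

    w[n] = 1 - ((n - (N-1)/2) / ((N-1)/2))**2,

Fourier-transformed, and converted to a one-sided power spectrum.  Power is
compensated for the taper's mean-square so that, for white noise, the summed
linear power over all bins estimates the signal variance.  The 22 per-window
spectra are averaged and returned on the natural-log scale, on a frequency
grid spaced at 200/512 = 0.390625 Hz.

Band powers are natural logs of summed linear bin power over bins whose
center frequency lies in the half-open interval [low, high).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Band",
    "SpectralConfig",
    "EpochSpectrum",
    "CANONICAL_BANDS",
    "REPORTED_BANDS",
    "welch_taper",
    "epoch_spectrum",
    "epoch_spectra",
    "band_bins",
    "band_power",
    "band_power_series",
    "load_eeg_edf",
]


@dataclass(frozen=True)
class Band:
    """A named frequency band, half-open: low <= f < high."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError(f"band {self.name!r}: need 0 <= low < high, got [{self.low}, {self.high})")


#: Canonical band edges.  ``total`` (0.1-48 Hz) is the reported broadband power;
#: ``total_screen`` (0.8-48 Hz) is the broadband series used by the deviant-epoch
#: screen.  Both are kept as distinct named bands.
CANONICAL_BANDS: dict[str, Band] = {
    b.name: b
    for b in (
        Band("delta1", 0.1, 1.0),
        Band("delta2", 1.0, 3.5),
        Band("theta", 3.5, 8.0),
        Band("alpha", 8.0, 12.0),
        Band("sigma1", 12.0, 14.0),
        Band("sigma2", 14.0, 16.0),
        Band("beta1", 16.0, 24.0),
        Band("beta2", 24.0, 32.0),
        Band("gamma", 32.0, 48.0),
        Band("total", 0.1, 48.0),
        Band("total_screen", 0.8, 48.0),
    )
}

#: The ten bands reported per stage (2 stages x 10 bands = 20 spectral variables).
REPORTED_BANDS: tuple[str, ...] = (
    "total", "delta1", "delta2", "theta", "alpha",
    "sigma1", "sigma2", "beta1", "beta2", "gamma",
)


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the per-epoch spectral analysis.

    Defaults reproduce a 200-Hz recording analysed in 30-s epochs with
    512-point half-overlapping windows (bin spacing 0.390625 Hz, 22 windows
    per epoch).
    """

    sampling_rate: float = 200.0
    epoch_seconds: float = 30.0
    window_len: int = 512
    overlap: float = 0.5
    log_floor: float = 1e-300  # linear power floor before taking the log

    @property
    def epoch_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_seconds))

    @property
    def hop(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap)))

    @property
    def n_windows(self) -> int:
        return (self.epoch_samples - self.window_len) // self.hop + 1

    @property
    def bin_hz(self) -> float:
        return self.sampling_rate / self.window_len

    @property
    def freqs(self) -> np.ndarray:
        """Bin center frequencies, k * sampling_rate / window_len."""
        return np.arange(self.window_len // 2 + 1) * self.bin_hz


@dataclass
class EpochSpectrum:
    """Averaged one-sided log power spectrum of one 30-s epoch."""

    freqs: np.ndarray
    log_power: np.ndarray
    n_windows_averaged: int
    config: SpectralConfig = field(default_factory=SpectralConfig)


def welch_taper(n: int) -> np.ndarray:
    """Parabolic Welch window w[n] = 1 - ((n-(N-1)/2)/((N-1)/2))**2."""
    half = (n - 1) / 2.0
    k = np.arange(n)
    return 1.0 - ((k - half) / half) ** 2


def _window_view(signal: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """(n_windows, window_len) strided view of one epoch."""
    n_win, wlen, hop = cfg.n_windows, cfg.window_len, cfg.hop
    return np.lib.stride_tricks.as_strided(
        signal,
        shape=(n_win, wlen),
        strides=(signal.strides[0] * hop, signal.strides[0]),
        writeable=False,
    )


def _detrend(windows: np.ndarray) -> np.ndarray:
    """Subtract the linear least-squares line from each row."""
    n = windows.shape[-1]
    t = np.arange(n) - (n - 1) / 2.0
    denom = float(t @ t)
    mean = windows.mean(axis=-1, keepdims=True)
    slope = (windows @ t)[..., None] / denom
    return windows - mean - slope * t


def _linear_power(signals: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """Averaged one-sided linear power, (n_epochs, n_bins)."""
    wlen = cfg.window_len
    taper = welch_taper(wlen)
    scale = 1.0 / (wlen * float(taper @ taper))
    out = np.empty((signals.shape[0], wlen // 2 + 1))
    for i, sig in enumerate(signals):
        win = _detrend(_window_view(np.ascontiguousarray(sig, dtype=float), cfg))
        spec = np.fft.rfft(win * taper, axis=-1)
        power = (spec.real**2 + spec.imag**2) * scale
        power[:, 1:] *= 2.0
        if wlen % 2 == 0:
            power[:, -1] /= 2.0
        out[i] = power.mean(axis=0)
    return out


def epoch_spectrum(signal: np.ndarray, cfg: SpectralConfig | None = None) -> EpochSpectrum:
    """Averaged log power spectrum of a single epoch.

    Parameters
    ----------
    signal : array of shape (epoch_samples,)
        One epoch of EEG, ``sampling_rate * epoch_seconds`` samples.
    cfg : SpectralConfig, optional

    Raises
    ------
    ValueError
        If the signal length does not match the configured epoch length.
    """
    cfg = cfg or SpectralConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.shape[0] != cfg.epoch_samples:
        raise ValueError(
            f"epoch signal must have {cfg.epoch_samples} samples "
            f"({cfg.sampling_rate} Hz x {cfg.epoch_seconds} s); got shape {signal.shape}"
        )
    power = _linear_power(signal[None, :], cfg)[0]
    return EpochSpectrum(
        freqs=cfg.freqs,
        log_power=np.log(np.maximum(power, cfg.log_floor)),
        n_windows_averaged=cfg.n_windows,
        config=cfg,
    )


def epoch_spectra(signals: np.ndarray, cfg: SpectralConfig | None = None) -> np.ndarray:
    """Log power spectra for a stack of epochs.

    Parameters
    ----------
    signals : array of shape (n_epochs, epoch_samples)

    Returns
    -------
    log_power : array of shape (n_epochs, window_len//2 + 1)
    """
    cfg = cfg or SpectralConfig()
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] != cfg.epoch_samples:
        raise ValueError(
            f"expected (n_epochs, {cfg.epoch_samples}) signal array, got shape {signals.shape}"
        )
    power = _linear_power(signals, cfg)
    return np.log(np.maximum(power, cfg.log_floor))


def band_bins(band: Band | str, freqs: np.ndarray) -> np.ndarray:
    """Indices of bins with center frequency in [band.low, band.high)."""
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    idx = np.nonzero((freqs >= band.low) & (freqs < band.high))[0]
    if idx.size == 0:
        raise ValueError(f"band {band.name!r} [{band.low}, {band.high}) contains no bin centers")
    return idx


def band_power(spec: EpochSpectrum, band: Band | str) -> float:
    """Natural-log band power: log of the summed linear bin power in the band."""
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    nyquist = spec.freqs[-1]
    if not (0 <= band.low < band.high <= nyquist + 1e-12):
        raise ValueError(f"band {band.name!r} outside [0, {nyquist}] Hz")
    idx = band_bins(band, spec.freqs)
    floor = spec.config.log_floor
    return float(np.log(max(np.exp(spec.log_power[idx]).sum(), floor)))


def band_power_series(log_power: np.ndarray, band: Band | str,
                      cfg: SpectralConfig | None = None) -> np.ndarray:
    """Per-epoch log band power from an (n_epochs, n_bins) log-power array."""
    cfg = cfg or SpectralConfig()
    idx = band_bins(band, cfg.freqs)
    linear = np.exp(log_power[:, idx]).sum(axis=1)
    return np.log(np.maximum(linear, cfg.log_floor))


def load_eeg_edf(path, channel: str, cfg: SpectralConfig | None = None) -> np.ndarray:
    """Read one EEG channel from an EDF file and reshape it into epochs.

    Requires ``mne``.  Trailing samples that do not fill a whole epoch are
    discarded.  Returns an (n_epochs, epoch_samples) array.
    """
    import mne  # local import: EDF support is optional

    cfg = cfg or SpectralConfig()
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    if abs(raw.info["sfreq"] - cfg.sampling_rate) > 1e-9:
        raise ValueError(
            f"EDF sampling rate {raw.info['sfreq']} Hz != configured {cfg.sampling_rate} Hz"
        )
    data = raw.get_data(picks=[channel])[0]
    n_epochs = data.shape[0] // cfg.epoch_samples
    return data[: n_epochs * cfg.epoch_samples].reshape(n_epochs, cfg.epoch_samples)
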