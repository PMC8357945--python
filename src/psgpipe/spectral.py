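"""Per-epoch EEG/EMG band-power extraction.

The scoring features are integrated spectral powers on the 8-s epoch
grid: EEG delta (0.16-4 Hz), theta (6-9 Hz), sigma (10-14 Hz) and beta
(14-32 Hz) from 16-s FFT windows with 50% overlap, and EMG power in
32-64 Hz from 2-s FFT windows averaged within each epoch. The product
sigma*theta is the wake-vs-sleep EEG discriminant used by staging.

Conventions
-----------
* Each 16-s EEG window is centred on the 8-s epoch it scores (hop 8 s
  realises the 50% overlap); the first/last epochs reuse the nearest
  valid window.
* A frequency bin belongs to a band if ``lo <= f < hi`` (half-open), so
  adjacent bands such as sigma (10-14) and beta (14-32) never share the
  14 Hz bin. The band set leaves gaps at 4-6 and 9-10 Hz; these
  are deliberate and preserved, so the four band powers sum to less than the total
  spectral power.
* Windows are mean-detrended and Hann-tapered before the FFT; powers are
  integrated one-sided periodogram densities (signal-units^2).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .states import EPOCH_SECONDS, PSGRecording

#: EEG band edges in Hz, half-open [lo, hi)
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.16, 4.0),
    "theta": (6.0, 9.0),
    "sigma": (10.0, 14.0),
    "beta": (14.0, 32.0),
}
#: EMG integration band, Hz
EMG_BAND: tuple[float, float] = (32.0, 64.0)

#: analog front-end passbands, Hz
EEG_FILTER: tuple[float, float] = (0.16, 53.05)
EMG_FILTER: tuple[float, float] = (0.72, 112.88)

EEG_WINDOW_SECONDS: float = 16.0
EMG_WINDOW_SECONDS: float = 2.0


def bandpass(
    x: np.ndarray,
    sampling_rate: float,
    lo: float,
    hi: float,
    order: int = 10,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``), so the effective
    attenuation is twice the single-pass roll-off. ``hi`` at or above
    Nyquist is clipped just below it with a warning (the stated analog
    edge can exceed what the digital rate supports).
    """
    x = np.asarray(x, dtype=float)
    if not 0 < lo < hi:
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
    nyq = sampling_rate / 2.0
    if hi >= nyq:
        clipped = nyq * (1.0 - 1e-3)
        warnings.warn(
            f"upper band edge {hi} Hz is at/above Nyquist ({nyq} Hz); "
            f"clipping to {clipped:.3f} Hz",
            stacklevel=2,
        )
        hi = clipped
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    # a low hi-pass edge (0.16 Hz) has a long impulse response; pad by
    # several of its time constants to keep edge transients out
    padlen = min(x.size - 1, int(8 * sampling_rate / lo))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def _windowed_psd(frames: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann periodogram density for each row of `frames`.

    Returns (freqs, psd) with psd in signal-units^2 per Hz; integrating
    psd * df over all bins recovers the tapered window's mean power
    (periodogram convention, matches ``scipy.signal.periodogram``).
    """
    n = frames.shape[-1]
    win = sps.get_window("hann", n)
    frames = frames - frames.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(frames * win, axis=-1)
    psd = (np.abs(spec) ** 2) * (2.0 / (sampling_rate * np.sum(win**2)))
    psd[..., 0] /= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return freqs, psd


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs < hi)


def eeg_band_powers(
    eeg: np.ndarray,
    sampling_rate: float = 125.0,
    bands: dict[str, tuple[float, float]] | None = None,
    epoch_seconds: float = EPOCH_SECONDS,
    window_seconds: float = EEG_WINDOW_SECONDS,
) -> pd.DataFrame:
    """Integrated EEG band powers, one row per 8-s epoch.

    The 16-s analysis window centred on each epoch provides its
    estimate; windows therefore hop by one epoch (50% overlap). Also
    returns ``total`` (all-bin integrated power of the window) so band
    sums can be checked against a Parseval-style bound.
    """
    eeg = np.asarray(eeg, dtype=float)
    bands = EEG_BANDS if bands is None else bands
    n_win = int(round(window_seconds * sampling_rate))
    n_ep = int(round(epoch_seconds * sampling_rate))
    if eeg.size < n_win:
        raise ValueError(
            f"signal ({eeg.size} samples) shorter than one {window_seconds}-s window"
        )
    n_epochs = eeg.size // n_ep
    # window start for epoch i: centre of epoch minus half window, clipped
    starts = np.arange(n_epochs) * n_ep + n_ep // 2 - n_win // 2
    starts = np.clip(starts, 0, eeg.size - n_win)
    frames = sliding_window_view(eeg, n_win)[starts]
    freqs, psd = _windowed_psd(frames, sampling_rate)
    df = freqs[1] - freqs[0]
    out = {
        name: psd[:, _band_mask(freqs, lo, hi)].sum(axis=1) * df
        for name, (lo, hi) in bands.items()
    }
    out["total"] = psd.sum(axis=1) * df
    return pd.DataFrame(out)


def emg_band_power(
    emg: np.ndarray,
    sampling_rate: float = 250.0,
    band: tuple[float, float] = EMG_BAND,
    epoch_seconds: float = EPOCH_SECONDS,
    window_seconds: float = EMG_WINDOW_SECONDS,
) -> np.ndarray:
    """Per-epoch EMG power in `band` (default 32-64 Hz).

    2-s FFT windows tile each epoch; the per-epoch value is the mean of
    its sub-window band powers (robust to one noisy sub-window and
    preserves units).
    """
    emg = np.asarray(emg, dtype=float)
    n_win = int(round(window_seconds * sampling_rate))
    n_ep = int(round(epoch_seconds * sampling_rate))
    if emg.size < n_ep:
        raise ValueError(f"signal ({emg.size} samples) shorter than one epoch")
    per_epoch = n_ep // n_win
    n_epochs = emg.size // n_ep
    frames = emg[: n_epochs * per_epoch * n_win].reshape(-1, n_win)
    freqs, psd = _windowed_psd(frames, sampling_rate)
    df = freqs[1] - freqs[0]
    win_power = psd[:, _band_mask(freqs, *band)].sum(axis=1) * df
    return win_power.reshape(n_epochs, per_epoch).mean(axis=1)


def build_band_power_series(
    recording: PSGRecording,
    bands: dict[str, tuple[float, float]] | None = None,
    emg_band: tuple[float, float] = EMG_BAND,
    epoch_seconds: float = EPOCH_SECONDS,
    eeg_window_seconds: float = EEG_WINDOW_SECONDS,
    emg_window_seconds: float = EMG_WINDOW_SECONDS,
    prefilter: bool = True,
) -> pd.DataFrame:
    """Aligned per-epoch feature table for one recording.

    Columns: epoch_index, zt_seconds, delta, theta, sigma, beta,
    sigma_theta (= sigma * theta, elementwise), emg_power, eeg_total.
    A trailing partial epoch is discarded.
    """
    eeg = recording.eeg
    emg = recording.emg
    if prefilter:
        eeg = bandpass(eeg, recording.eeg_rate, *EEG_FILTER)
        emg = bandpass(emg, recording.emg_rate, *EMG_FILTER)
    eeg_tab = eeg_band_powers(
        eeg, recording.eeg_rate, bands, epoch_seconds, eeg_window_seconds
    )
    emg_pow = emg_band_power(
        emg, recording.emg_rate, emg_band, epoch_seconds, emg_window_seconds
    )
    n = min(len(eeg_tab), emg_pow.size)
    eeg_tab = eeg_tab.iloc[:n].reset_index(drop=True)
    tab = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "zt_seconds": recording.zt_start + np.arange(n) * epoch_seconds,
        }
    )
    for name in (bands or EEG_BANDS):
        tab[name] = eeg_tab[name]
    tab["sigma_theta"] = tab["sigma"] * tab["theta"]
    tab["emg_power"] = emg_pow[:n]
    tab["eeg_total"] = eeg_tab["total"]
    return tab
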