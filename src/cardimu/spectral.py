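"""Power spectral density of cardiac motion signals.

Short 600-sample windows with 595-sample overlap (the analysis settings
used throughout this package) give a raw bin width of fs/600 ~ 1.17 Hz at
700 S/s, too coarse to place a ~2 Hz heart-rate fundamental; segments are
therefore zero-padded (default 8192 points, bin ~ 0.085 Hz) and Hann
tapered.  Power is normalised to sum to one, i.e. the spectrum describes
the proportional distribution of power across frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

__all__ = ["SpectrumResult", "power_spectrum", "dominant_frequency"]

WINDOW_LEN_DEFAULT = 600
OVERLAP_DEFAULT = 595
PAD_TO_DEFAULT = 8192


@dataclass
class SpectrumResult:
    """Normalised averaged periodogram (power sums to 1)."""

    frequencies: np.ndarray  # Hz, ascending, 0 .. fs/2
    power: np.ndarray  # unitless, >= 0, sums to 1
    peak_hz: float
    window_len: int = WINDOW_LEN_DEFAULT
    overlap: int = OVERLAP_DEFAULT


def power_spectrum(
    signal: np.ndarray,
    fs: float,
    window_len: int = WINDOW_LEN_DEFAULT,
    overlap: int = OVERLAP_DEFAULT,
    pad_to: int = PAD_TO_DEFAULT,
) -> SpectrumResult:
    """Welch-averaged periodogram over Hann-tapered, overlapping,
    zero-padded segments, normalised to total power one.

    Segment means are removed before tapering, so the spectrum describes
    fluctuation about the local mean; an exactly constant signal is
    reported as pure DC (all power in the 0 Hz bin).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if signal.size < window_len:
        raise ValueError(
            f"signal length {signal.size} shorter than the window ({window_len})"
        )
    if not 0 <= overlap < window_len:
        raise ValueError("overlap must be in [0, window_len)")
    if pad_to < window_len:
        raise ValueError("pad_to must be >= window_len")
    freqs, psd = welch(
        signal,
        fs=fs,
        window="hann",
        nperseg=window_len,
        noverlap=overlap,
        nfft=pad_to,
        detrend="constant",
    )
    total = psd.sum()
    if total <= 0 or not np.isfinite(total):
        power = np.zeros_like(psd)
        power[0] = 1.0
    else:
        power = psd / total
    return SpectrumResult(
        frequencies=freqs,
        power=power,
        peak_hz=float(freqs[int(np.argmax(power))]),
        window_len=window_len,
        overlap=overlap,
    )


def dominant_frequency(spectrum: SpectrumResult) -> float:
    """Frequency (Hz) of the global power maximum; ties resolve to the
    lowest frequency."""
    return float(spectrum.frequencies[int(np.argmax(spectrum.power))])
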