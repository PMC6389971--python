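"""R-peak detection, heart-cycle slicing, time normalisation, ensembles.

The detector is a simple adaptive-threshold/refractory peak picker that is
exact on clean synthetic ECG spike trains; externally determined R-peaks
(e.g. manually corrected ones for real recordings) can be supplied to every
downstream function instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "CycleIndexSet",
    "BeatEnsemble",
    "detect_r_peaks",
    "slice_cycles",
    "resample_cycle",
    "ensemble_median",
]

N_NORM_DEFAULT = 400

#: physiological cycle-length bounds (seconds) used to flag implausible RR
RR_BOUNDS_S = (60.0 / 250.0, 60.0 / 30.0)


@dataclass
class CycleIndexSet:
    """Ordered R-peak sample indices with per-cycle heart rates."""

    r_peaks: np.ndarray  # strictly increasing ints
    fs: float

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.r_peaks.size > 1 and not np.all(np.diff(self.r_peaks) > 0):
            raise ValueError("r_peaks must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(0, self.r_peaks.size - 1)

    def cycle_hr_bpm(self) -> np.ndarray:
        """Per-cycle heart rate (bpm) from consecutive RR intervals."""
        rr = np.diff(self.r_peaks) / self.fs
        return 60.0 / rr


@dataclass
class BeatEnsemble:
    """Pointwise median and quartile traces over time-normalised cycles."""

    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    n_cycles: int
    n_norm: int = N_NORM_DEFAULT


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    min_rr_s: float = RR_BOUNDS_S[0],
    k_mad: float = 8.0,
) -> CycleIndexSet:
    """Detect R-peaks as local maxima above an adaptive threshold.

    Threshold = median + k_mad * MAD of the signal; when the MAD collapses
    to zero (noiseless synthetic ECG) half of the peak-to-median range is
    used instead.  A refractory period of ``min_rr_s`` is enforced.  An
    empty result (flat signal) is returned with a warning, not an error.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 2 * min_rr_s * fs:
        raise ValueError("signal shorter than two refractory periods")
    med = float(np.median(ecg))
    mad = float(np.median(np.abs(ecg - med)))
    rng_up = float(ecg.max() - med)
    if mad > 0:
        thr = med + k_mad * mad
    elif rng_up > 0:
        thr = med + 0.5 * rng_up
    else:
        warnings.warn("flat ECG signal: no R-peaks found")
        return CycleIndexSet(r_peaks=np.array([], dtype=int), fs=fs)
    peaks, _ = find_peaks(ecg, height=thr, distance=max(1, int(round(min_rr_s * fs))))
    # plateau/edge handling: a spike at sample 0 has no left neighbour and
    # is missed by find_peaks; recover it explicitly
    if ecg[0] > thr and (ecg.size < 2 or ecg[0] >= ecg[1]):
        if peaks.size == 0 or peaks[0] > min_rr_s * fs:
            peaks = np.concatenate([[0], peaks])
    if peaks.size == 0:
        warnings.warn("no R-peaks found above the adaptive threshold")
    rr = np.diff(peaks) / fs
    if rr.size and (np.any(rr < RR_BOUNDS_S[0]) or np.any(rr > RR_BOUNDS_S[1])):
        warnings.warn("some RR intervals fall outside physiological bounds")
    return CycleIndexSet(r_peaks=peaks, fs=fs)


def slice_cycles(signal: np.ndarray, cycles: CycleIndexSet) -> list[np.ndarray]:
    """Slice a signal into per-cycle segments [r_k, r_{k+1}).

    The trailing partial cycle after the last R-peak is dropped.  Works on
    1-D signals or (channels, N) arrays (sliced along the last axis).
    """
    signal = np.asarray(signal)
    n = signal.shape[-1]
    r = cycles.r_peaks
    if r.size < 2:
        raise ValueError("insufficient cycles: need at least 2 R-peaks")
    if r[0] < 0 or r[-1] > n:
        raise ValueError("R-peak indices outside signal bounds")
    return [signal[..., r[k]: r[k + 1]] for k in range(r.size - 1)]


def resample_cycle(segment: np.ndarray, n_norm: int = N_NORM_DEFAULT) -> np.ndarray:
    """Time-normalise one cycle to ``n_norm`` samples (linear interpolation).

    The new grid spans the segment inclusively, so endpoint values are
    preserved exactly.  Multichannel (c, n) segments are resampled per
    channel.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    x_new = np.linspace(0.0, n - 1.0, n_norm)
    x_old = np.arange(n)
    if segment.ndim == 1:
        return np.interp(x_new, x_old, segment)
    return np.vstack([np.interp(x_new, x_old, row) for row in segment])


def ensemble_median(cycles: list[np.ndarray]) -> BeatEnsemble:
    """Pointwise median and interquartile traces over normalised cycles."""
    if len(cycles) == 0:
        raise ValueError("at least one cycle required")
    n_norm = len(np.asarray(cycles[0]))
    stack = np.vstack([np.asarray(c, dtype=float) for c in cycles])
    if stack.shape[1] != n_norm:
        raise ValueError("cycles must share the normalised length")
    return BeatEnsemble(
        median=np.median(stack, axis=0),
        q1=np.quantile(stack, 0.25, axis=0),
        q3=np.quantile(stack, 0.75, axis=0),
        n_cycles=stack.shape[0],
        n_norm=n_norm,
    )
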