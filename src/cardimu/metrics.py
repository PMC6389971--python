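"""End-systole timing, end-systolic motion, and 3D motion reduction.

End-systole (time of dP/dt_min) is estimated from heart rate with a fixed
quadratic regression calibrated on invasive LV pressure:

    t_es(HR) = 0.61 - 4.317e-3 * HR + 1.05e-5 * HR^2   [seconds]

valid for heart rates of roughly 80-200 bpm (we warn outside 30-250).
End-systolic motion (ESM) is the absolute excursion of a motion trace from
the R-peak (end-diastole) to the end-systolic sample.  Three-dimensional
motion is reduced to one dimension by projecting onto the main contraction
direction estimated from baseline cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ES_REGRESSION_COEFFS",
    "ESEstimate",
    "DirectionVector",
    "es_delay_from_hr",
    "es_sample_index",
    "main_direction",
    "project_3d",
    "esm",
]

#: (intercept [s], linear [s/bpm], quadratic [s/bpm^2]) of the heart-rate ->
#: R-to-dP/dt_min regression; treated as constants (the fit requires
#: invasive pressure data).
ES_REGRESSION_COEFFS = (0.61, -4.317e-3, 1.05e-5)

_HR_VALID = (30.0, 250.0)


@dataclass(frozen=True)
class ESEstimate:
    hr_bpm: float
    t_es_s: float
    es_sample: int


@dataclass(frozen=True)
class DirectionVector:
    """Unit main-contraction direction in the sensor frame."""

    vector: np.ndarray  # (3,), unit norm
    n_cycles: int
    dispersion_deg: float  # mean angle between cycle vectors and the mean

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.vector) - 1.0) > 1e-9:
            raise ValueError("direction vector must be unit norm")


def es_delay_from_hr(hr_bpm: float) -> float:
    """Delay (s) from the R-peak to end-systole (dP/dt_min) at ``hr_bpm``.

    Heart rates outside the calibrated range return the extrapolated value
    with a warning; negative heart rate is an error.
    """
    if hr_bpm < 0:
        raise ValueError("heart rate must be non-negative")
    if not _HR_VALID[0] <= hr_bpm <= _HR_VALID[1]:
        warnings.warn(
            f"heart rate {hr_bpm:.1f} bpm outside the regression's validity "
            f"range [{_HR_VALID[0]:.0f}, {_HR_VALID[1]:.0f}]; extrapolating",
            stacklevel=2,
        )
    a, b, c = ES_REGRESSION_COEFFS
    return a + b * hr_bpm + c * hr_bpm**2


def es_sample_index(hr_bpm: float, fs: float, cycle_len: int | None = None) -> ESEstimate:
    """End-systolic sample offset from the R-peak (half-up rounding).

    If ``cycle_len`` is given the index is clamped inside the cycle, with a
    warning when clamping occurs.
    """
    t_es = es_delay_from_hr(hr_bpm)
    idx = int(np.floor(t_es * fs + 0.5))
    if cycle_len is not None and not 0 < idx < cycle_len:
        warnings.warn("end-systolic sample clamped inside the cycle", stacklevel=2)
        idx = int(np.clip(idx, 1, cycle_len - 1))
    return ESEstimate(hr_bpm=hr_bpm, t_es_s=t_es, es_sample=idx)


def main_direction(cycles: list[np.ndarray]) -> DirectionVector:
    """Main contraction direction from baseline 3D displacement cycles.

    Per cycle: the unit vector from the cycle-start position to the point
    farthest from it.  The result is the normalised arithmetic mean of the
    per-cycle unit vectors; dispersion (mean angle to the cycle vectors) is
    reported for quality control.
    """
    if len(cycles) == 0:
        raise ValueError("at least one cycle required")
    dirs = []
    for p in cycles:
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape[0] != 3:
            raise ValueError("each cycle must be a (3, n) displacement array")
        rel = p - p[:, :1]
        dist = np.linalg.norm(rel, axis=0)
        k = int(np.argmax(dist))
        if dist[k] <= 0:
            raise ValueError("degenerate direction: cycle has zero motion")
        dirs.append(rel[:, k] / dist[k])
    mean = np.mean(dirs, axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        raise ValueError("degenerate direction: cycle directions cancel")
    v = mean / norm
    angles = [np.degrees(np.arccos(np.clip(d @ v, -1.0, 1.0))) for d in dirs]
    return DirectionVector(vector=v, n_cycles=len(cycles),
                           dispersion_deg=float(np.mean(angles)))


def project_3d(displacement: np.ndarray, direction: DirectionVector | np.ndarray) -> np.ndarray:
    """Project a (3, n) displacement cycle onto a unit direction (signed)."""
    v = direction.vector if isinstance(direction, DirectionVector) else np.asarray(direction, float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    displacement = np.asarray(displacement, dtype=float)
    if displacement.ndim != 2 or displacement.shape[0] != 3:
        raise ValueError("displacement must be (3, n)")
    return v @ displacement


def esm(trace: np.ndarray, es_sample: int) -> float:
    """End-systolic motion: |trace(es) - trace(start)| of a per-cycle trace."""
    trace = np.asarray(trace, dtype=float)
    if not 0 <= es_sample < trace.shape[-1]:
        raise ValueError("es_sample outside the cycle")
    return float(abs(trace[..., es_sample] - trace[..., 0]))
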