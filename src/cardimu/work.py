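"""Regional myocardial work from LV pressure and segment-length strain.

The regional work index is the signed area of the pressure-strain loop
(mmHg * %strain) over one heart cycle.  The sign convention is fixed so
that a healthy loop - shortening at high pressure, re-lengthening at low
pressure - encloses positive area; ischemic segments (isovolumic
lengthening, post-systolic shortening) enclose reduced or negative area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WorkLoop", "strain_from_lengths", "loop_work"]


@dataclass
class WorkLoop:
    """One closed pressure-strain loop and its signed area."""

    pressure: np.ndarray  # mmHg
    strain: np.ndarray  # percent
    work: float  # mmHg * %

    @classmethod
    def from_cycle(cls, pressure: np.ndarray, strain: np.ndarray) -> "WorkLoop":
        return cls(pressure=np.asarray(pressure, float),
                   strain=np.asarray(strain, float),
                   work=loop_work(pressure, strain))


def strain_from_lengths(seg_len: np.ndarray, ed_sample: int = 0) -> np.ndarray:
    """Lagrangian strain (%) relative to the end-diastolic length.

    strain(t) = 100 * (L(t) - L_ED) / L_ED with L_ED taken at ``ed_sample``
    (the R-peak by convention, consistent with the ESM reference).
    """
    seg_len = np.asarray(seg_len, dtype=float)
    if np.any(seg_len <= 0):
        raise ValueError("segment lengths must be positive")
    if not 0 <= ed_sample < seg_len.shape[-1]:
        raise ValueError("ed_sample outside the trace")
    l_ed = seg_len[..., ed_sample]
    return 100.0 * (seg_len - l_ed) / l_ed


def loop_work(pressure: np.ndarray, strain: np.ndarray) -> float:
    """Signed pressure-strain loop area (mmHg * %) via the shoelace formula.

    The loop is closed by joining the last sample back to the first.  With
    strain on the abscissa and pressure on the ordinate, counter-clockwise
    traversal is positive; a physiological healthy cycle (pressure rises at
    constant length, shortens at high pressure, re-lengthens at low
    pressure) traverses counter-clockwise and therefore yields positive
    work.  Constant pressure gives zero area regardless of strain.
    """
    x = np.asarray(strain, dtype=float)
    y = np.asarray(pressure, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pressure and strain must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("a loop needs at least 3 points")
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
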