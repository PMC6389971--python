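"""Gravity compensation and integration of inertial signals, per cycle.

Two gravity-compensation routes are implemented:

* **static** (STAc): subtract the per-cycle mean acceleration.  Valid when
  the sensor does not rotate; a rotating sensor leaves a time-varying
  gravity residual that double integration amplifies.
* **dynamic** (DYNc): integrate the gyro to a per-sample orientation track,
  fit the cycle-start gravity vector from the cycle-mean acceleration
  (motion acceleration has ~zero mean over a whole cycle), and subtract the
  propagated gravity at every sample.

Displacement follows from drift-corrected double integration under the
cyclicity assumption (the heart starts and ends each beat in approximately
the same place): trapezoidal integration with linear ramp corrections that
pin start and end velocity/displacement to zero.  All functions operate on
one whole cycle; each cycle is re-anchored so integration error cannot
accumulate across beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .simulate import G_STANDARD

__all__ = [
    "OrientationTrack",
    "GravityEstimate",
    "MotionTrace",
    "static_compensate",
    "integrate_orientation",
    "estimate_initial_gravity",
    "dynamic_compensate",
    "double_integrate_cyclic",
    "rotation_from_gyro",
]


@dataclass
class OrientationTrack:
    """Per-sample body attitude relative to the cycle-start attitude.

    ``matrices[k]`` maps cycle-start-frame vectors to the body frame at
    sample k is the transpose; concretely ``matrices[k] @ v_body_k`` is the
    vector expressed in the start frame.
    """

    matrices: np.ndarray  # (n, 3, 3), each orthonormal, det +1
    fs: float

    def __post_init__(self) -> None:
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (3, 3):
            raise ValueError("matrices must be (n, 3, 3)")


@dataclass(frozen=True)
class GravityEstimate:
    """Cycle-start body-frame gravity reaction, rescaled to standard norm."""

    g0: np.ndarray  # (3,), m/s^2, norm == gravity_mag
    residual: float  # norm of the least-squares residual (m/s^2)
    gravity_mag: float = G_STANDARD


@dataclass
class MotionTrace:
    """Per-cycle motion traces for one recording and one method.

    ``cycles`` holds one (3, n_k) array per heart cycle; displacement
    methods are in mm, rotation in degrees.  Every cycle trace starts at 0.
    """

    method: str  # "STAc" | "DYNc" | "ROT"
    cycles: list = field(default_factory=list)
    fs: float = 700.0
    units: str = "mm"


def _as_3xn(x, name="acc"):
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != 3:
        raise ValueError(f"{name} must be a (3, n) array")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite samples")
    return x


def static_compensate(acc: np.ndarray) -> np.ndarray:
    """Subtract the per-axis mean over the cycle (static gravity removal)."""
    acc = _as_3xn(acc)
    return acc - acc.mean(axis=1, keepdims=True)


def integrate_orientation(gyro: np.ndarray, fs: float) -> OrientationTrack:
    """Integrate body-frame angular velocity to an orientation track.

    Per-sample rotation-vector exponential with midpoint angular velocity:
    ``Phi_{k+1} = Phi_k @ exp([0.5 (w_k + w_{k+1}) dt]_x)``; ``Phi_0 = I``.
    Orthonormality is inherited from composing exact rotation operators.
    """
    gyro = _as_3xn(gyro, "gyro")
    n = gyro.shape[1]
    dt = 1.0 / fs
    mats = np.empty((n, 3, 3))
    mats[0] = np.eye(3)
    if n > 1:
        rotvecs = 0.5 * (gyro[:, :-1] + gyro[:, 1:]).T * dt
        increments = Rotation.from_rotvec(rotvecs).as_matrix()
        cur = np.eye(3)
        for k in range(n - 1):
            cur = cur @ increments[k]
            mats[k + 1] = cur
    return OrientationTrack(matrices=mats, fs=fs)


def estimate_initial_gravity(
    acc: np.ndarray,
    track: OrientationTrack,
    gravity_mag: float = G_STANDARD,
) -> GravityEstimate:
    """Fit the cycle-start gravity vector from the cycle-mean acceleration.

    Since motion acceleration averages to ~zero over a whole cycle, the
    mean measured acceleration obeys ``mean_t(Phi_t^T) g0 = mean_t(acc)``
    where g0 is the start-frame gravity reaction.  The solution is rescaled
    to ``gravity_mag`` to absorb accelerometer scale error.
    """
    acc = _as_3xn(acc)
    M = track.matrices.transpose(0, 2, 1).mean(axis=0)
    b = acc.mean(axis=1)
    if np.linalg.cond(M) > 1e8:
        raise ValueError(
            "orientation track leaves the start gravity ambiguous (near-"
            "singular mean rotation); use shorter cycles or check the gyro"
        )
    g0 = np.linalg.solve(M, b)
    nrm = np.linalg.norm(g0)
    if nrm < 1e-9:
        raise ValueError("zero-mean acceleration: cannot estimate gravity")
    g0 = g0 * (gravity_mag / nrm)
    residual = float(np.linalg.norm(M @ g0 - b))
    return GravityEstimate(g0=g0, residual=residual, gravity_mag=gravity_mag)


def dynamic_compensate(
    acc: np.ndarray, gyro: np.ndarray, fs: float, gravity_mag: float = G_STANDARD
) -> np.ndarray:
    """Remove the gravity vector at every sample using the gyro.

    The measured acceleration is rotated into the cycle-start frame with
    the integrated orientation track and the fitted start-frame gravity is
    subtracted; the residual per-axis mean (scale mismatch, noise) is then
    removed, so that with a zero gyro this reduces exactly to static
    compensation.  The output is motion-only acceleration expressed in the
    cycle-start frame.
    """
    acc = _as_3xn(acc)
    track = integrate_orientation(gyro, fs)
    g0 = estimate_initial_gravity(acc, track, gravity_mag).g0
    # einsum: start_frame[k] = Phi_k @ acc[:, k]
    rotated = np.einsum("nij,jn->in", track.matrices, acc)
    out = rotated - g0[:, None]
    return out - out.mean(axis=1, keepdims=True)


def _ramp_correct(x: np.ndarray) -> np.ndarray:
    """Subtract the linear ramp through (0, 0) and (n-1, x[-1])."""
    n = x.shape[-1]
    if n < 2:
        return x - x
    ramp = np.linspace(0.0, 1.0, n)
    return x - x[..., -1:] * ramp


def double_integrate_cyclic(motion_acc: np.ndarray, fs: float) -> np.ndarray:
    """Drift-corrected double integration of motion acceleration to mm.

    Trapezoidal integration to velocity, ramp correction pinning the
    end-of-cycle velocity to zero (cyclic motion), trapezoidal integration
    to displacement, ramp correction pinning the end-of-cycle displacement
    to zero.  Output is displacement in mm, zero at the cycle start.
    """
    motion_acc = _as_3xn(motion_acc, "motion_acc")
    dt = 1.0 / fs
    vel = np.concatenate(
        [np.zeros((3, 1)), np.cumsum(0.5 * (motion_acc[:, 1:] + motion_acc[:, :-1]) * dt, axis=1)],
        axis=1,
    )
    vel = _ramp_correct(vel)
    disp = np.concatenate(
        [np.zeros((3, 1)), np.cumsum(0.5 * (vel[:, 1:] + vel[:, :-1]) * dt, axis=1)],
        axis=1,
    )
    disp = _ramp_correct(disp)
    return disp * 1e3


def rotation_from_gyro(gyro: np.ndarray, fs: float) -> np.ndarray:
    """Per-axis rotation (degrees) from angular velocity over one cycle.

    The per-cycle mean angular velocity is subtracted first (cyclic-motion
    bias removal, which also absorbs constant gyro bias), then the signal
    is integrated with the trapezoidal rule and zeroed at the cycle start.
    """
    gyro = _as_3xn(gyro, "gyro")
    w = gyro - gyro.mean(axis=1, keepdims=True)
    dt = 1.0 / fs
    ang = np.concatenate(
        [np.zeros((3, 1)), np.cumsum(0.5 * (w[:, 1:] + w[:, :-1]) * dt, axis=1)], axis=1
    )
    return np.degrees(ang)
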