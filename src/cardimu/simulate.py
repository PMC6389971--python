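"""Physics-based generator of epicardial accelerometer/gyro recordings.

The heart apex is modelled as a rigid sensor platform that translates along
the three LV-aligned axes (x longitudinal, y circumferential, z radial) and
rotates about its long axis once per heart cycle.  The accelerometer output
is the specific force measured in the rotating body frame,

    acc(t) = R(t)^T (p_ddot_world(t) - g_world) + noise,

so a static sensor reads the gravity reaction (norm 9.81 m/s^2) and a
rotating sensor sees a *time-varying* gravity projection on its axes - the
artifact that static gravity compensation cannot remove.  The gyro reads the
body-frame angular velocity (theta_dot about the long axis).

Ground-truth kinematics are retained on every recording so the analysis
chain can be tested by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import es_delay_from_hr

G_STANDARD = 9.81
DEFAULT_FS = 700.0

__all__ = [
    "Geometry",
    "NoiseConfig",
    "InterventionParams",
    "KinematicGroundTruth",
    "SubjectRecording",
    "CohortDataset",
    "REFERENCE_PARAMS",
    "DEFAULT_PROTOCOL",
    "kinematic_waveform",
    "simulate_subject",
    "simulate_pressure_strain",
    "simulate_cohort",
]


@dataclass(frozen=True)
class Geometry:
    """Orientation of the heart's long axis in the gravity field.

    ``inclination_deg`` is the angle between the long (rotation) axis and
    the vertical: 0 means the rotation plane is horizontal and rotation
    produces no time-varying gravity component; 90 is the supine-like case
    where the rotation plane contains the gravity vector and the rotational
    gravity artifact is maximal (it scales with sin(inclination)).

    ``artifact_sign`` (+1/-1) selects whether the rotational gravity
    artifact adds to or subtracts from the true circumferential
    displacement at end-systole; the sign depends on which way the sensor's
    radial axis points relative to gravity, which is surgical happenstance.
    """

    inclination_deg: float = 90.0
    gravity_mag: float = G_STANDARD
    artifact_sign: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.inclination_deg <= 90.0:
            raise ValueError("inclination_deg must be in [0, 90]")
        if self.gravity_mag <= 0:
            raise ValueError("gravity_mag must be positive")
        if self.artifact_sign not in (-1, 1):
            raise ValueError("artifact_sign must be +1 or -1")

    def gravity_start_frame(self) -> np.ndarray:
        """Gravity reaction vector in the cycle-start body frame (m/s^2).

        The perpendicular component is placed on the body z (radial) axis;
        its sign is chosen so that ``artifact_sign=+1`` yields an artifact
        displacement that adds constructively to the true circumferential
        displacement at end-systole (double integration maps a positive
        acceleration pulse into a negative displacement pulse, hence the
        internal sign flip).
        """
        inc = np.deg2rad(self.inclination_deg)
        return np.array(
            [
                self.gravity_mag * np.cos(inc),
                0.0,
                -self.artifact_sign * self.gravity_mag * np.sin(inc),
            ]
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Additive sensor noise. Defaults are plausible MEMS figures."""

    acc_sd: float = 0.05  # m/s^2, white
    gyro_sd: float = 0.005  # rad/s, white
    gyro_bias: float = 0.002  # rad/s, constant per axis
    ecg_sd: float = 0.0
    lvp_sd: float = 0.2  # mmHg
    seg_len_sd: float = 0.002  # mm

    NOISELESS: "NoiseConfig" = None  # set below

    def __post_init__(self) -> None:
        for name in ("acc_sd", "gyro_sd", "ecg_sd", "lvp_sd", "seg_len_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NoiseConfig.NOISELESS = NoiseConfig(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class InterventionParams:
    """Per-intervention hemodynamic and kinematic amplitudes.

    Defaults (see REFERENCE_PARAMS) are observed cohort means; the true
    end-systolic amplitudes are the rotation (deg) and the displacement
    (mm) reached at end-systole, relative to the R-peak.
    """

    label: str
    hr_bpm: float
    rot_esm_deg: float
    disp_esm_mm: float  # circumferential (body y)
    disp_long_mm: float = 0.0
    disp_rad_mm: float = 0.0
    lvp_sys_mmHg: float = 82.0
    lvp_dia_mmHg: float = 5.0
    work_target_mmHg_pct: float = 850.0
    ischemic: bool = False

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0:
            raise ValueError("hr_bpm must be positive")
        for name in ("rot_esm_deg", "disp_esm_mm", "disp_long_mm", "disp_rad_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ischemic != (self.label in ("ischemia", "dob_isc")):
            raise ValueError("ischemic flag inconsistent with label")


#: Cohort-mean parameters per intervention (means of the observed
#: hemodynamics and DYNc/rotation end-systolic motion); secondary-axis
#: displacement amplitudes are design choices (longitudinal ~1/3, radial
#: ~1/6 of circumferential at baseline).
REFERENCE_PARAMS: dict[str, InterventionParams] = {
    "baseline": InterventionParams(
        "baseline", 108.0, 9.6, 6.0, 2.0, 1.0, 82.0, 5.0, 850.0, False
    ),
    "ischemia": InterventionParams(
        "ischemia", 108.0, 2.2, 3.1, 1.0, 0.5, 71.0, 5.0, 118.0, True
    ),
    "dobutamine": InterventionParams(
        "dobutamine", 144.0, 14.8, 5.8, 2.0, 1.0, 100.0, 5.0, 1140.0, False
    ),
    "dob_isc": InterventionParams(
        "dob_isc", 147.0, 3.2, 3.3, 1.0, 0.5, 87.0, 5.0, 292.0, True
    ),
    # Reperfusion is treated as baseline-like (not part of the default
    # protocol counts; see docs/methods.md).
    "reperfusion": InterventionParams(
        "reperfusion", 108.0, 9.6, 6.0, 2.0, 1.0, 82.0, 5.0, 850.0, False
    ),
}

#: Between-subject standard deviations of the observed baseline values,
#: used as coefficient-of-variation anchors for subject random effects.
REFERENCE_BASELINE_SD = {
    "rot": 3.5,  # deg (mean 9.6)
    "disp": 1.9,  # mm (mean 6.0)
    "work": 445.0,  # mmHg*% (mean 850)
    "hr": 21.0,  # bpm (mean 108)
    "lvp": 7.0,  # mmHg (mean 82)
}

#: Default protocol: 11 subjects with baseline + ischemia, the first 4 of
#: which also receive dobutamine and dobutamine + ischemia.
DEFAULT_PROTOCOL = {
    "baseline": 11,
    "ischemia": 11,
    "dobutamine": 4,
    "dob_isc": 4,
}


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _check_waveform_args(es_delay_s: float, period_s: float) -> None:
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    if not 0.0 < es_delay_s < period_s:
        raise ValueError(
            f"es_delay_s must lie strictly inside (0, period_s); "
            f"got {es_delay_s} with period {period_s}"
        )


def kinematic_waveform(
    amplitude: float, es_delay_s: float, period_s: float, t: np.ndarray
) -> np.ndarray:
    """Raised-cosine contraction pulse: 0 at cycle start, peak ``amplitude``
    at ``es_delay_s``, back to 0 at ``period_s``; C1-continuous and periodic
    in ``t``."""
    _check_waveform_args(es_delay_s, period_s)
    tt = np.asarray(t, dtype=float) % period_s
    t1, t2 = es_delay_s, period_s - es_delay_s
    rising = tt <= t1
    out = np.empty_like(tt)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * tt[rising] / t1))
    s = tt[~rising] - t1
    out[~rising] = 0.5 * (1.0 + np.cos(np.pi * s / t2))
    return amplitude * out


def _waveform_d1(amplitude, es_delay_s, period_s, t):
    """Analytic first derivative of :func:`kinematic_waveform`."""
    _check_waveform_args(es_delay_s, period_s)
    tt = np.asarray(t, dtype=float) % period_s
    t1, t2 = es_delay_s, period_s - es_delay_s
    rising = tt <= t1
    out = np.empty_like(tt)
    out[rising] = 0.5 * np.pi / t1 * np.sin(np.pi * tt[rising] / t1)
    s = tt[~rising] - t1
    out[~rising] = -0.5 * np.pi / t2 * np.sin(np.pi * s / t2)
    return amplitude * out


def _waveform_d2(amplitude, es_delay_s, period_s, t):
    """Analytic second derivative of :func:`kinematic_waveform`."""
    _check_waveform_args(es_delay_s, period_s)
    tt = np.asarray(t, dtype=float) % period_s
    t1, t2 = es_delay_s, period_s - es_delay_s
    rising = tt <= t1
    out = np.empty_like(tt)
    out[rising] = 0.5 * (np.pi / t1) ** 2 * np.cos(np.pi * tt[rising] / t1)
    s = tt[~rising] - t1
    out[~rising] = -0.5 * (np.pi / t2) ** 2 * np.cos(np.pi * s / t2)
    return amplitude * out


def _half_cosine_ramp(t, t_start, t_end, y0, y1):
    """Smooth monotone transition y0 -> y1 on [t_start, t_end]."""
    out = np.full_like(np.asarray(t, dtype=float), y0)
    out[t >= t_end] = y1
    mid = (t >= t_start) & (t < t_end)
    phase = (t[mid] - t_start) / (t_end - t_start)
    out[mid] = y0 + (y1 - y0) * 0.5 * (1.0 - np.cos(np.pi * phase))
    return out


# ---------------------------------------------------------------------------
# ground truth / recording containers
# ---------------------------------------------------------------------------

@dataclass
class KinematicGroundTruth:
    """True simulated kinematics, kept for parameter-recovery tests."""

    t: np.ndarray  # seconds, length N
    theta_deg: np.ndarray  # long-axis rotation, length N
    p_mm: np.ndarray  # (3, N) displacement: x long, y circ, z radial
    cycle_starts: np.ndarray  # sample index of each cycle start
    es_sample_offset: int  # samples from cycle start to end-systole
    es_time_s: float  # seconds from R-peak to dP/dt_min
    rot_esm_deg: float  # true ED->ES rotation
    disp_esm_mm: np.ndarray  # true ED->ES displacement per axis (3,)


@dataclass
class SubjectRecording:
    """One subject x intervention multichannel recording at a common fs."""

    subject_id: str
    intervention: str
    fs: float
    acc: np.ndarray  # (3, N) m/s^2, body frame, gravity included
    gyro: np.ndarray | None  # (3, N) rad/s, body frame (None: accelerometer-only)
    ecg: np.ndarray  # (N,)
    lvp: np.ndarray | None = None  # (N,) mmHg
    seg_len: np.ndarray | None = None  # (N,) mm
    r_peaks: np.ndarray | None = None  # ground-truth R-peak indices
    ground_truth: KinematicGroundTruth | None = None

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    def __post_init__(self) -> None:
        n = self.acc.shape[1]
        if self.acc.shape[0] != 3:
            raise ValueError("acc must be (3, N)")
        if self.gyro is not None and self.gyro.shape != (3, n):
            raise ValueError("gyro must be (3, N) with N matching acc")
        for name in ("ecg", "lvp", "seg_len"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(f"channel {name} length mismatch")


@dataclass
class CohortDataset:
    """A seeded cohort of recordings plus the subject-level random effects."""

    recordings: list[SubjectRecording]
    seed: int
    subject_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def by_subject(self, subject_id: str) -> list[SubjectRecording]:
        return [r for r in self.recordings if r.subject_id == subject_id]

    def subjects(self) -> list[str]:
        seen: list[str] = []
        for r in self.recordings:
            if r.subject_id not in seen:
                seen.append(r.subject_id)
        return seen


# ---------------------------------------------------------------------------
# pressure / strain loops
# ---------------------------------------------------------------------------

def _pressure_cycle(params: InterventionParams, t, period_s, t_es):
    """LV pressure pulse whose dP/dt_min falls exactly at ``t_es``.

    Half-cosine upstroke to the systolic peak, half-cosine decay of
    duration 0.2*period centred (in slope) on t_es, diastolic plateau
    elsewhere.
    """
    t_fall = 0.2 * period_s
    t_peak = t_es - 0.5 * t_fall
    t_rise0 = 0.04 * period_s
    if t_peak <= t_rise0:  # very early ES: compress the upstroke
        t_rise0 = 0.5 * t_peak
    p = np.full_like(t, params.lvp_dia_mmHg)
    up = _half_cosine_ramp(t, t_rise0, t_peak, params.lvp_dia_mmHg, params.lvp_sys_mmHg)
    down = _half_cosine_ramp(
        t, t_peak, t_peak + t_fall, params.lvp_sys_mmHg, params.lvp_dia_mmHg
    )
    p = np.where(t < t_peak, up, down)
    return p


def _strain_shape_healthy(t, period_s, t_es):
    """Unit healthy strain: shortening (negative) during ejection with peak
    shortening at end-systole, hold through isovolumic relaxation,
    re-lengthening during filling.  Peak magnitude 1."""
    t_short0 = 0.25 * t_es
    t_hold_end = min(t_es + 0.12 * period_s, 0.95 * period_s)
    shorten = _half_cosine_ramp(t, t_short0, t_es, 0.0, -1.0)
    relax = _half_cosine_ramp(t, t_hold_end, period_s, -1.0, 0.0)
    return np.where(t < t_es, shorten, np.where(t < t_hold_end, -1.0, relax))


def _strain_shape_ischemic(t, period_s, t_es):
    """Unit ischemic strain: the segment lengthens (positive bulge) during
    the isovolumic contraction phase and shows post-systolic shortening as
    pressure falls; peak shortening magnitude 1."""
    t_bulge_end = 0.9 * t_es
    bulge = 0.6 * np.sin(np.pi * np.clip(t / t_bulge_end, 0.0, 1.0)) ** 2
    t_ps_peak = min(t_es + 0.18 * period_s, 0.8 * period_s)  # post-systolic
    t_short0 = 0.8 * t_es
    shorten = _half_cosine_ramp(t, t_short0, t_ps_peak, 0.0, -1.0)
    relax = _half_cosine_ramp(t, min(t_ps_peak + 0.05 * period_s, 0.97 * period_s),
                              period_s, -1.0, 0.0)
    short_part = np.where(t < t_ps_peak, shorten,
                          np.where(t < t_ps_peak + 0.05 * period_s, -1.0, relax))
    return bulge + short_part


def _shoelace(x, y):
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def simulate_pressure_strain(
    params: InterventionParams,
    n_cycles: int = 5,
    seed: int | None = None,
    fs: float = DEFAULT_FS,
    noise: NoiseConfig | None = None,
):
    """Generate (lvp, seg_len) traces over ``n_cycles`` whole cycles.

    The strain amplitude is scaled so the signed pressure-strain loop area
    of one noiseless cycle equals ``params.work_target_mmHg_pct`` (the loop
    area is exactly linear in the strain amplitude, so the scale is a
    single division, not an iterative fit).  Ischemic loops additionally
    carry the isovolumic-lengthening / post-systolic-shortening morphology.
    """
    noise = noise if noise is not None else NoiseConfig()
    rng = np.random.default_rng(seed)
    n_samp = int(round(fs * 60.0 / params.hr_bpm))
    period = n_samp / fs
    t = np.arange(n_samp) / fs
    t_es = float(np.clip(es_delay_from_hr(60.0 / period), 0.05 * period, 0.9 * period))

    lvp_cycle = _pressure_cycle(params, t, period, t_es)
    shape_fn = _strain_shape_ischemic if params.ischemic else _strain_shape_healthy
    unit = shape_fn(t, period, t_es)
    unit_area = _shoelace(unit, lvp_cycle)
    if abs(unit_area) < 1e-9:
        raise ValueError("degenerate strain shape: zero unit loop area")
    amp = params.work_target_mmHg_pct / unit_area
    # Lagrangian strain below -100% would make the segment length
    # non-positive; cap the excursion at +-95% and warn that the work
    # target cannot be met (only reachable with extreme work targets)
    peak_unit = float(np.abs(unit).max())
    if abs(amp) * peak_unit > 95.0:
        warnings.warn(
            f"work target {params.work_target_mmHg_pct:.0f} mmHg%% implies "
            "peak strain beyond +-95%; capping the strain amplitude",
            stacklevel=2,
        )
        amp = np.sign(amp) * 95.0 / peak_unit
    strain_cycle = amp * unit  # percent

    lvp = np.tile(lvp_cycle, n_cycles)
    strain = np.tile(strain_cycle, n_cycles)
    seg_len = 10.0 * (1.0 + strain / 100.0)
    if noise.lvp_sd > 0:
        lvp = lvp + rng.normal(0.0, noise.lvp_sd, lvp.size)
    if noise.seg_len_sd > 0:
        seg_len = seg_len + rng.normal(0.0, noise.seg_len_sd, seg_len.size)
    return lvp, seg_len


# ---------------------------------------------------------------------------
# forward IMU model
# ---------------------------------------------------------------------------

def simulate_subject(
    params: InterventionParams,
    geometry: Geometry | None = None,
    noise: NoiseConfig | None = None,
    n_cycles: int = 10,
    seed: int | None = None,
    fs: float = DEFAULT_FS,
    subject_id: str = "S00",
) -> SubjectRecording:
    """Simulate one recording of ``n_cycles`` identical heart cycles.

    Kinematics: displacement p(t) along the three LV axes and rotation
    theta(t) about the long axis are raised-cosine pulses peaking at the
    end-systolic delay predicted from heart rate, so the configured
    amplitudes are the true end-systolic motion values.  The accelerometer
    sees ``Rx(-theta) (p_ddot + g0)`` where g0 is the start-frame gravity
    reaction; the gyro sees ``(theta_dot, 0, 0)``.
    """
    if n_cycles < 3:
        raise ValueError("n_cycles must be >= 3")
    geometry = geometry if geometry is not None else Geometry()
    noise = noise if noise is not None else NoiseConfig()
    rng = np.random.default_rng(seed)

    n_samp = int(round(fs * 60.0 / params.hr_bpm))
    period = n_samp / fs
    hr_actual = 60.0 / period
    t_cycle = np.arange(n_samp) / fs
    t_es = float(np.clip(es_delay_from_hr(hr_actual), 0.05 * period, 0.9 * period))
    es_off = int(round(t_es * fs))

    # amplitude 0 would violate the waveform preconditions only via es
    # bounds; handled above by clipping.
    def pulse(amp):
        return kinematic_waveform(amp, t_es, period, t_cycle)

    def pulse_d1(amp):
        return _waveform_d1(amp, t_es, period, t_cycle)

    def pulse_d2(amp):
        return _waveform_d2(amp, t_es, period, t_cycle)

    theta_deg_c = pulse(params.rot_esm_deg)
    theta_dot_c = np.deg2rad(pulse_d1(params.rot_esm_deg))
    p_mm_c = np.vstack(
        [pulse(params.disp_long_mm), pulse(params.disp_esm_mm), pulse(params.disp_rad_mm)]
    )
    p_dd_c = 1e-3 * np.vstack(
        [pulse_d2(params.disp_long_mm), pulse_d2(params.disp_esm_mm),
         pulse_d2(params.disp_rad_mm)]
    )  # m/s^2

    n = n_samp * n_cycles
    theta = np.tile(np.deg2rad(theta_deg_c), n_cycles)
    theta_dot = np.tile(theta_dot_c, n_cycles)
    p_dd = np.tile(p_dd_c, n_cycles)

    g0 = geometry.gravity_start_frame()
    f = p_dd + g0[:, None]  # start-frame specific force
    c, s = np.cos(theta), np.sin(theta)
    acc = np.vstack([f[0], c * f[1] + s * f[2], -s * f[1] + c * f[2]])
    gyro = np.vstack([theta_dot, np.zeros(n), np.zeros(n)])

    if noise.acc_sd > 0:
        acc = acc + rng.normal(0.0, noise.acc_sd, acc.shape)
    if noise.gyro_bias != 0.0:
        gyro = gyro + noise.gyro_bias
    if noise.gyro_sd > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_sd, gyro.shape)

    # ECG: 10-sample unit triangular spike at each cycle start.
    ecg = np.zeros(n)
    spike = np.concatenate([np.linspace(0, 1, 5, endpoint=False), np.linspace(1, 0, 5)])
    cycle_starts = np.arange(n_cycles) * n_samp
    for k in cycle_starts:
        ecg[k : k + 10] = spike[: min(10, n - k)]
    if noise.ecg_sd > 0:
        ecg = ecg + rng.normal(0.0, noise.ecg_sd, n)

    lvp, seg_len = simulate_pressure_strain(
        params, n_cycles=n_cycles, fs=fs, noise=noise,
        seed=int(rng.integers(2**31 - 1)),
    )

    gt = KinematicGroundTruth(
        t=np.arange(n) / fs,
        theta_deg=np.tile(theta_deg_c, n_cycles),
        p_mm=np.tile(p_mm_c, n_cycles),
        cycle_starts=cycle_starts,
        es_sample_offset=es_off,
        es_time_s=t_es,
        rot_esm_deg=params.rot_esm_deg,
        disp_esm_mm=np.array(
            [params.disp_long_mm, params.disp_esm_mm, params.disp_rad_mm]
        ),
    )
    return SubjectRecording(
        subject_id=subject_id,
        intervention=params.label,
        fs=fs,
        acc=acc,
        gyro=gyro,
        ecg=ecg,
        lvp=lvp,
        seg_len=seg_len,
        r_peaks=cycle_starts.copy(),
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def simulate_cohort(
    n_subjects: int = 11,
    protocol: dict[str, int] | None = None,
    seed: int = 0,
    geometry: Geometry | None = None,
    noise: NoiseConfig | None = None,
    n_cycles: int = 10,
    fs: float = DEFAULT_FS,
    re_sd_scale: float = 1.0,
) -> CohortDataset:
    """Simulate a cohort across interventions with subject random effects.

    Between-recording variability is decomposed into two log-normal
    multipliers per quantity family (rotation, displacement, work, heart
    rate, pressure): a subject-level effect shared by all of a subject's
    recordings, and an independent recording-level effect (repeat
    interventions within one animal do not scale identically).  Each
    component carries half the observed baseline variance, so the total
    per-intervention coefficient of variation matches the observed spread.
    ``re_sd_scale`` scales both components (0 makes all subjects identical
    up to sensor-noise realisations).  Protocol counts give the number of
    subjects receiving each intervention; the first ``count`` subjects
    receive it, so every subject has a baseline under the default protocol.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocol = dict(protocol) if protocol is not None else dict(DEFAULT_PROTOCOL)
    geometry = geometry if geometry is not None else Geometry()
    noise = noise if noise is not None else NoiseConfig()
    rng = np.random.default_rng(seed)

    sig = {
        "rot": _lognormal_sigma(REFERENCE_BASELINE_SD["rot"] / 9.6),
        "disp": _lognormal_sigma(REFERENCE_BASELINE_SD["disp"] / 6.0),
        "work": _lognormal_sigma(REFERENCE_BASELINE_SD["work"] / 850.0),
        "hr": _lognormal_sigma(REFERENCE_BASELINE_SD["hr"] / 108.0),
        "lvp": _lognormal_sigma(REFERENCE_BASELINE_SD["lvp"] / 82.0),
    }

    split = 1.0 / np.sqrt(2.0)  # equal subject/recording variance split
    effects: dict[str, dict[str, float]] = {}
    recordings: list[SubjectRecording] = []
    for i in range(n_subjects):
        sid = f"S{i:02d}"
        m = {
            q: float(np.exp(rng.normal(0.0, re_sd_scale * split * s)))
            for q, s in sig.items()
        }
        effects[sid] = m
        for label, count in protocol.items():
            if i >= min(count, n_subjects):
                continue
            jit = {
                q: float(np.exp(rng.normal(0.0, re_sd_scale * split * s)))
                for q, s in sig.items()
            }
            mm = {q: m[q] * jit[q] for q in m}
            base = REFERENCE_PARAMS[label]
            params = replace(
                base,
                hr_bpm=float(np.clip(base.hr_bpm * mm["hr"], 40.0, 240.0)),
                rot_esm_deg=base.rot_esm_deg * mm["rot"],
                disp_esm_mm=base.disp_esm_mm * mm["disp"],
                disp_long_mm=base.disp_long_mm * mm["disp"],
                disp_rad_mm=base.disp_rad_mm * mm["disp"],
                lvp_sys_mmHg=base.lvp_sys_mmHg * mm["lvp"],
                work_target_mmHg_pct=base.work_target_mmHg_pct * mm["work"],
            )
            rec_seed = int(rng.integers(2**31 - 1))
            recordings.append(
                simulate_subject(
                    params,
                    geometry=geometry,
                    noise=noise,
                    n_cycles=n_cycles,
                    seed=rec_seed,
                    fs=fs,
                    subject_id=sid,
                )
            )
    if not any(r.intervention == "baseline" for r in recordings):
        warnings.warn("protocol contains no baseline recordings")
    return CohortDataset(recordings=recordings, seed=seed, subject_effects=effects)
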