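"""Seeded synthetic generator for locked-elbow shoulder motion trials.

Stands in for a motion-capture corpus: each activity template produces a
smooth humerus pose series (shoulder position + orientation quaternion) built
from sums of sinusoids with per-trial randomized amplitude, phase and speed.
Trajectories are qualitative stand-ins — the downstream load pipeline only
consumes poses, not marker data.

Global frame is right-handed, z-up, gravity (0, 0, -9.81) m/s^2.  Body frame
convention: the humeral distal direction is -z at identity orientation, so the
long axis (pointing proximally) is ``R @ (0, 0, 1)``.  Orientations are built
as intrinsic X-Y-Z Euler rotations; the third (Z) angle is axial humeral
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from oiload.errors import InvalidInputError, ParseError
from oiload.limb_model import SubjectAnthropometry

GRAVITY = np.array([0.0, 0.0, -9.81])

ACTIVITIES = (
    "jumping_jack",
    "jug_lift",
    "underhand_toss",
    "jogging",
    "internal_rotation",
    "briefcase_carry",
)

WEIGHTED_ACTIVITIES = ("jug_lift", "briefcase_carry")

DEFAULT_BRIEFCASE_MASS = 4.5  # kg
DEFAULT_JUG_MASS = 3.8  # kg
DEFAULT_HANDHELD_MASSES = {
    "briefcase_carry": DEFAULT_BRIEFCASE_MASS,
    "jug_lift": DEFAULT_JUG_MASS,
}

DEFAULT_SAMPLE_RATE = 100.0  # Hz
DEFAULT_ANGULAR_SPEED_CAP = 20.0  # rad/s

# Upper-arm length as a fraction of stature.
UPPER_ARM_STATURE_RATIO = 0.186

SUBJECT_STATURE_RANGE = (1.6, 1.9)  # m
SUBJECT_MASS_RANGE = (44.1, 123.7)  # kg


@dataclass(frozen=True)
class ActivityParams:
    """Kinematic template for one activity.

    Angles are intrinsic X-Y-Z Euler angles of the humerus: X ~ ab/adduction
    plane swing, Y ~ transverse swing, Z ~ axial rotation.  Amplitudes are
    drawn once per trial as ``|Normal(mean, sd)|`` per axis, split over 1-3
    harmonics of the fundamental.
    """

    duration: float = 5.0  # s
    fundamental_frequency: float = 1.0  # Hz
    base_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)  # rad
    amplitude_means: tuple[float, float, float] = (0.3, 0.1, 0.1)  # rad
    amplitude_sds: tuple[float, float, float] = (0.06, 0.02, 0.02)  # rad
    n_harmonics: int = 2
    translation_amplitude: float = 0.02  # m
    elbow_flexion: float = 0.35  # rad, locked
    speed_jitter_sd: float = 0.10  # fractional jitter on the fundamental
    smoothing_window: float = 0.0  # s, optional extra zero-phase smoothing
    weighted: bool = False

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise InvalidInputError("duration must be > 0")
        if not self.fundamental_frequency > 0:
            raise InvalidInputError("fundamental_frequency must be > 0")
        if any(a < 0 for a in self.amplitude_means):
            raise InvalidInputError("amplitudes must be >= 0")


ACTIVITY_DEFAULTS: dict[str, ActivityParams] = {
    "jumping_jack": ActivityParams(
        fundamental_frequency=1.0, amplitude_means=(1.2, 0.15, 0.2),
        amplitude_sds=(0.20, 0.04, 0.05), translation_amplitude=0.05),
    "jug_lift": ActivityParams(
        fundamental_frequency=0.3, base_angles=(0.6, 0.0, 0.0),
        amplitude_means=(0.6, 0.10, 0.10), amplitude_sds=(0.10, 0.03, 0.03),
        translation_amplitude=0.02, elbow_flexion=0.0, weighted=True),
    "underhand_toss": ActivityParams(
        fundamental_frequency=0.5, base_angles=(0.3, 0.0, 0.0),
        amplitude_means=(0.8, 0.15, 0.10), amplitude_sds=(0.15, 0.04, 0.03),
        translation_amplitude=0.02),
    "jogging": ActivityParams(
        fundamental_frequency=1.4, base_angles=(0.2, 0.0, 0.0),
        amplitude_means=(0.35, 0.10, 0.15), amplitude_sds=(0.07, 0.03, 0.04),
        translation_amplitude=0.04),
    "internal_rotation": ActivityParams(
        fundamental_frequency=1.5, amplitude_means=(0.08, 0.08, 1.0),
        amplitude_sds=(0.02, 0.02, 0.15), translation_amplitude=0.005),
    "briefcase_carry": ActivityParams(
        fundamental_frequency=0.9, amplitude_means=(0.15, 0.08, 0.05),
        amplitude_sds=(0.04, 0.02, 0.015), translation_amplitude=0.03,
        weighted=True),
}


@dataclass(frozen=True)
class MotionTrial:
    """One locked-elbow motion trial.

    ``quaternions`` are scalar-first (w, x, y, z), unit norm.  ``time`` is
    strictly increasing and uniformly sampled; ``elbow_flexion`` is the locked
    value, constant across the trial.
    """

    activity: str
    sample_rate: float
    time: np.ndarray  # (n,)
    shoulder_position: np.ndarray  # (n, 3) m
    quaternions: np.ndarray  # (n, 4) scalar-first
    elbow_flexion: float  # rad
    handheld_mass: float = 0.0
    subject_id: str = ""
    trial_index: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        pos = np.asarray(self.shoulder_position, dtype=float)
        quat = np.asarray(self.quaternions, dtype=float)
        if time.ndim != 1 or len(time) < 2:
            raise InvalidInputError("trial needs at least 2 samples")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise InvalidInputError("time must be uniformly sampled")
        if pos.shape != (len(time), 3) or quat.shape != (len(time), 4):
            raise InvalidInputError("position/quaternion shape mismatch")
        norms = np.linalg.norm(quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidInputError("quaternion norm drift exceeds 1e-6")
        if self.handheld_mass < 0:
            raise InvalidInputError("handheld_mass must be >= 0")
        if self.handheld_mass > 0 and self.activity not in WEIGHTED_ACTIVITIES:
            raise InvalidInputError(
                f"handheld mass is only carried in {WEIGHTED_ACTIVITIES}")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "shoulder_position", pos)
        # idempotent renormalization keeps CSV round trips bit-exact
        if np.any(np.abs(norms - 1.0) > 1e-13):
            quat = quat / norms[:, None]
        object.__setattr__(self, "quaternions", quat)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def rotations(self) -> Rotation:
        """Scipy rotations (note: scipy stores quaternions scalar-last)."""
        return Rotation.from_quat(self.quaternions[:, [1, 2, 3, 0]])

    def equals(self, other: "MotionTrial", atol: float = 0.0) -> bool:
        return (self.activity == other.activity
                and np.allclose(self.time, other.time, atol=atol, rtol=0)
                and np.allclose(self.shoulder_position,
                                other.shoulder_position, atol=atol, rtol=0)
                and np.allclose(self.quaternions, other.quaternions,
                                atol=atol, rtol=0)
                and self.elbow_flexion == other.elbow_flexion
                and self.handheld_mass == other.handheld_mass)


# ---------------------------------------------------------------------------
# subject sampling
# ---------------------------------------------------------------------------

def sample_subject(rng: np.random.Generator,
                   subject_id: str = "") -> SubjectAnthropometry:
    """Draw one subject spanning the cohort extremes.

    Stature uniform in [1.6, 1.9] m; body mass drawn around a
    stature-correlated mean and clipped to [44.1, 123.7] kg.  Segment lengths
    and joint widths scale with stature.
    """
    s_lo, s_hi = SUBJECT_STATURE_RANGE
    m_lo, m_hi = SUBJECT_MASS_RANGE
    stature = rng.uniform(s_lo, s_hi)
    t = (stature - s_lo) / (s_hi - s_lo)
    mass = float(np.clip(m_lo + t * (m_hi - m_lo) + rng.normal(0.0, 8.0),
                         m_lo, m_hi))
    sex = "F" if rng.random() < 0.5 else "M"
    return SubjectAnthropometry(
        body_mass=mass,
        stature=stature,
        upper_arm_length=UPPER_ARM_STATURE_RATIO * stature,
        elbow_width=0.040 * stature,
        wrist_width=0.030 * stature,
        hand_length=0.108 * stature,
        sex_label=sex)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _euler_angle_series(time: np.ndarray, params: ActivityParams,
                        rng: np.random.Generator) -> np.ndarray:
    """(n, 3) intrinsic XYZ Euler angle series with randomized harmonics."""
    f0 = params.fundamental_frequency * (
        1.0 + params.speed_jitter_sd * rng.standard_normal())
    f0 = max(f0, 0.1 * params.fundamental_frequency)
    angles = np.tile(np.asarray(params.base_angles, dtype=float),
                     (len(time), 1))
    for axis in range(3):
        amp = abs(rng.normal(params.amplitude_means[axis],
                             params.amplitude_sds[axis]))
        for k in range(1, params.n_harmonics + 1):
            a_k = amp / (k * k) if k > 1 else amp
            phase = rng.uniform(0.0, 2.0 * np.pi)
            angles[:, axis] += a_k * np.sin(2.0 * np.pi * f0 * k * time + phase)
    if params.smoothing_window > 0:
        n_win = max(3, int(params.smoothing_window * len(time) / time[-1]) | 1)
        win = np.hanning(n_win)
        win /= win.sum()
        pad = n_win // 2
        padded = np.pad(angles, ((pad, pad), (0, 0)), mode="edge")
        angles = np.stack([np.convolve(padded[:, i], win, mode="valid")
                           for i in range(3)], axis=1)
    return angles


def _translation_series(time: np.ndarray, params: ActivityParams,
                        rng: np.random.Generator) -> np.ndarray:
    f0 = params.fundamental_frequency
    amp = params.translation_amplitude * abs(rng.normal(1.0, 0.2))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    pos = np.zeros((len(time), 3))
    pos[:, 0] = 0.2 * amp * np.sin(2.0 * np.pi * f0 * time + phases[0])
    pos[:, 1] = 0.2 * amp * np.sin(2.0 * np.pi * f0 * time + phases[1])
    # vertical bounce at twice the fundamental (both arm swings load the legs)
    pos[:, 2] = amp * np.sin(2.0 * np.pi * 2.0 * f0 * time + phases[2])
    return pos


def _max_angular_speed(time: np.ndarray, quat_wxyz: np.ndarray) -> float:
    omega = _finite_difference_omega(time, quat_wxyz)
    return float(np.max(np.linalg.norm(omega, axis=1)))


def _finite_difference_omega(time: np.ndarray,
                             quat_wxyz: np.ndarray) -> np.ndarray:
    """World-frame angular velocity from a quaternion series, 2*dq/dt (x) q*."""
    q = np.array(quat_wxyz, dtype=float)
    # enforce sign continuity before differentiating
    flips = np.cumsum(np.einsum("ij,ij->i", q[1:], q[:-1]) < 0)
    q[1:] *= np.where(flips % 2 == 1, -1.0, 1.0)[:, None]
    dq = np.gradient(q, time, axis=0, edge_order=2)
    w, x, y, z = q.T
    dw, dx, dy, dz = dq.T
    # vector part of 2 * dq/dt * conj(q)
    ox = 2.0 * (-dw * x + dx * w - dy * z + dz * y)
    oy = 2.0 * (-dw * y + dx * z + dy * w - dz * x)
    oz = 2.0 * (-dw * z - dx * y + dy * x + dz * w)
    return np.column_stack([ox, oy, oz])


def generate_trial(activity: str, subject: SubjectAnthropometry,
                   rng: np.random.Generator,
                   params: ActivityParams | None = None,
                   sample_rate: float = DEFAULT_SAMPLE_RATE,
                   handheld_mass: float | None = None,
                   subject_id: str = "", trial_index: int = 0,
                   seed: int | None = None,
                   angular_speed_cap: float = DEFAULT_ANGULAR_SPEED_CAP,
                   ) -> MotionTrial:
    """Generate one seeded trial for ``activity``.

    Amplitudes/phases/speed are drawn once per trial from ``params``; a trial
    whose peak angular speed exceeds ``angular_speed_cap`` is regenerated
    (fresh draws from the same stream), with a deterministic rescale fallback.
    """
    if activity not in ACTIVITIES:
        raise InvalidInputError(
            f"unknown activity {activity!r}; expected one of {ACTIVITIES}")
    if params is None:
        params = ACTIVITY_DEFAULTS[activity]
    if handheld_mass is None:
        handheld_mass = DEFAULT_HANDHELD_MASSES.get(activity, 0.0) \
            if params.weighted else 0.0

    n = int(round(params.duration * sample_rate)) + 1
    time = np.arange(n) / sample_rate

    for attempt in range(20):
        angles = _euler_angle_series(time, params, rng)
        quat = _to_wxyz(Rotation.from_euler("XYZ", angles))
        if _max_angular_speed(time, quat) <= angular_speed_cap:
            break
        if attempt == 18:  # deterministic fallback: shrink the template
            params = replace(params, amplitude_means=tuple(
                0.25 * a for a in params.amplitude_means))
    pos = _translation_series(time, params, rng)

    return MotionTrial(activity=activity, sample_rate=sample_rate, time=time,
                       shoulder_position=pos, quaternions=quat,
                       elbow_flexion=params.elbow_flexion,
                       handheld_mass=handheld_mass, subject_id=subject_id,
                       trial_index=trial_index, seed=seed)


def _to_wxyz(rot: Rotation) -> np.ndarray:
    q = rot.as_quat()  # scalar-last
    return q[:, [3, 0, 1, 2]]


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("time", "px", "py", "pz", "qw", "qx", "qy", "qz",
                "elbow_flexion", "handheld_mass")


def write_trial_csv(trial: MotionTrial, path) -> None:
    """Write a trial as plain CSV (full float precision, '#' metadata lines)."""
    with open(path, "w") as fh:
        fh.write(f"# activity={trial.activity}\n")
        fh.write(f"# sample_rate={trial.sample_rate!r}\n")
        fh.write(f"# subject_id={trial.subject_id}\n")
        fh.write(f"# trial_index={trial.trial_index}\n")
        fh.write(f"# seed={'' if trial.seed is None else trial.seed}\n")
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        for i in range(trial.n_samples):
            row = [trial.time[i], *trial.shoulder_position[i],
                   *trial.quaternions[i], trial.elbow_flexion,
                   trial.handheld_mass]
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_trial_csv(path) -> MotionTrial:
    """Read a trial written by :func:`write_trial_csv`.

    Raises :class:`ParseError` naming the offending line on malformed input;
    quaternion norm drift beyond 1e-6 raises a validation error.
    """
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if tuple(fields) != _CSV_COLUMNS:
                    raise ParseError(
                        f"line {lineno}: expected columns {_CSV_COLUMNS}, "
                        f"got {tuple(fields)}")
                header_seen = True
                continue
            if len(fields) != len(_CSV_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(_CSV_COLUMNS)} fields, "
                    f"got {len(fields)}")
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    if not header_seen:
        raise ParseError("line 1: missing header row")
    if len(rows) < 2:
        raise ParseError(f"line {len(rows) + 1}: need at least 2 data rows")
    data = np.array(rows)
    quat = data[:, 4:8]
    if np.any(np.abs(np.linalg.norm(quat, axis=1) - 1.0) > 1e-6):
        raise InvalidInputError("quaternion norm drift exceeds 1e-6 on read")
    elbow = data[:, 8]
    if np.ptp(elbow) > 0:
        raise InvalidInputError("elbow_flexion must be constant (locked)")
    seed_str = meta.get("seed", "")
    return MotionTrial(
        activity=meta.get("activity", ""),
        sample_rate=float(meta.get("sample_rate", "0") or 0) or
        1.0 / (data[1, 0] - data[0, 0]),
        time=data[:, 0], shoulder_position=data[:, 1:4], quaternions=quat,
        elbow_flexion=float(elbow[0]), handheld_mass=float(data[0, 9]),
        subject_id=meta.get("subject_id", ""),
        trial_index=int(meta.get("trial_index", "0") or 0),
        seed=int(seed_str) if seed_str else None)
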