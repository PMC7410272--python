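"""Newton-Euler intersegmental loads at the bone-implant interface plane.

With the elbow locked, every body distal of the interface plane moves rigidly
with the humerus, so one pose series (shoulder position + humerus orientation)
fixes all segment kinematics.  The interface force and moment are

    F = sum_i m_i (a_i - g)
    M = sum_i [(r_i - p) x m_i (a_i - g) + I_i alpha + omega x I_i omega]

summed over bodies distal of the plane (handheld mass as a point mass), then
resolved along the humeral long axis u (pointing proximally) into

    axial   = F . u          (tensile / pullout positive)
    torsion = |M . u|
    bending = |M - (M . u) u|

:func:`point_mass_oracle` recomputes F, M by brute force - discretizing every
segment into point masses along its axis and numerically differentiating each
point's position - with no inertia-tensor shortcuts, as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from oiload.errors import InvalidInputError
from oiload.limb_model import LimbModel, SegmentInertialParams
from oiload.motion_synth import GRAVITY, MotionTrial, _finite_difference_omega

DEFAULT_FILTER_CUTOFF = 6.0  # Hz, zero-phase 4th-order low-pass


# ---------------------------------------------------------------------------
# body-frame geometry (depends on the locked elbow flexion angle)
# ---------------------------------------------------------------------------

def _chain_directions(elbow_flexion: float) -> tuple[np.ndarray, np.ndarray]:
    """(humeral distal direction, forearm/hand distal direction) in body frame."""
    humeral = np.array([0.0, 0.0, -1.0])
    forearm = np.array([0.0, np.sin(elbow_flexion), -np.cos(elbow_flexion)])
    return humeral, forearm


def _body_frame_point(arc: float, upper_arm_length: float,
                      elbow_flexion: float) -> np.ndarray:
    """3-D body-frame position of a chain point at arc length ``arc``."""
    d_h, d_f = _chain_directions(elbow_flexion)
    if arc <= upper_arm_length:
        return arc * d_h
    return upper_arm_length * d_h + (arc - upper_arm_length) * d_f


def _segment_axis(seg: SegmentInertialParams, upper_arm_length: float,
                  elbow_flexion: float) -> np.ndarray:
    d_h, d_f = _chain_directions(elbow_flexion)
    return d_f if seg.role in ("forearm", "hand") else d_h


def _segment_inertia_body(seg: SegmentInertialParams, axis: np.ndarray
                          ) -> np.ndarray:
    """Inertia tensor about the segment COM, expressed in the body frame."""
    it, _, ia = seg.principal_inertia
    # symmetric about the axis: I = it * (1 - aa^T) + ia * aa^T
    outer = np.outer(axis, axis)
    return it * (np.eye(3) - outer) + ia * outer


@dataclass(frozen=True)
class _DistalBody:
    name: str
    mass: float
    com_body: np.ndarray  # (3,) body frame
    axis_body: np.ndarray  # (3,)
    length: float
    proximal_body: np.ndarray  # (3,)
    inertia_body: np.ndarray  # (3, 3) about COM


def distal_bodies(model: LimbModel, elbow_flexion: float,
                  handheld_mass: float | None = None) -> list[_DistalBody]:
    """Rigid bodies distal of the interface plane, in the humerus body frame."""
    L = model.upper_arm_length
    bodies = []
    for seg in model.distal_segments:
        axis = _segment_axis(seg, L, elbow_flexion)
        proximal = _body_frame_point(seg.proximal_offset, L, elbow_flexion)
        com = proximal + seg.com_offset * seg.length * axis
        bodies.append(_DistalBody(
            name=seg.name, mass=seg.mass, com_body=com, axis_body=axis,
            length=seg.length, proximal_body=proximal,
            inertia_body=_segment_inertia_body(seg, axis)))
    hh = model.handheld_mass if handheld_mass is None else handheld_mass
    if hh > 0:
        _, d_f = _chain_directions(elbow_flexion)
        hand_com = _body_frame_point(model.hand_com_arc_position, L,
                                     elbow_flexion)
        com = hand_com + model.handheld_offset * d_f
        bodies.append(_DistalBody(
            name="handheld", mass=hh, com_body=com, axis_body=d_f,
            length=0.0, proximal_body=com, inertia_body=np.zeros((3, 3))))
    return bodies


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinematicState:
    """Per-sample kinematics of the locked-elbow distal chain."""

    time: np.ndarray  # (n,)
    rotations: np.ndarray  # (n, 3, 3) body -> world
    shoulder_position: np.ndarray  # (n, 3) (filtered)
    com_positions: np.ndarray  # (B, n, 3)
    com_accelerations: np.ndarray  # (B, n, 3)
    omega: np.ndarray  # (n, 3) world frame
    alpha: np.ndarray  # (n, 3)
    u_hat: np.ndarray  # (n, 3) long axis, pointing proximally
    interface_point: np.ndarray  # (n, 3)
    body_names: tuple[str, ...]
    elbow_flexion: float = 0.0

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.u_hat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidInputError("u_hat must be unit length within 1e-9")


def _quat_to_matrices(quat_wxyz: np.ndarray) -> np.ndarray:
    w, x, y, z = quat_wxyz.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                  2 * (x * z + w * y)], axis=-1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                  2 * (y * z - w * x)], axis=-1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                  1 - 2 * (x * x + y * y)], axis=-1),
    ], axis=1)


def _lowpass(series: np.ndarray, sample_rate: float, cutoff: float
             ) -> np.ndarray:
    nyquist = 0.5 * sample_rate
    if cutoff >= nyquist:
        return series
    b, a = butter(4, cutoff / nyquist)
    return filtfilt(b, a, series, axis=0)


def differentiate_poses(trial: MotionTrial, model: LimbModel,
                        filter_cutoff: float | None = DEFAULT_FILTER_CUTOFF,
                        ) -> KinematicState:
    """Forward kinematics + zero-phase filtering + central-difference derivatives.

    The pose series (shoulder position and quaternions) is low-pass filtered
    first (4th-order Butterworth, zero phase, ``filter_cutoff`` Hz; ``None``
    disables), then COM positions follow by forward kinematics and
    accelerations by two passes of central differences (one-sided at the
    endpoints).  Angular velocity comes from the quaternion derivative.
    """
    if trial.n_samples < 5:
        raise InvalidInputError("need at least 5 samples to differentiate")
    time = trial.time
    pos = trial.shoulder_position
    quat = trial.quaternions
    if filter_cutoff is not None:
        if trial.n_samples <= 15:
            raise InvalidInputError(
                "trial too short for zero-phase filtering; "
                "pass filter_cutoff=None")
        pos = _lowpass(pos, trial.sample_rate, filter_cutoff)
        quat = _lowpass(quat, trial.sample_rate, filter_cutoff)
        quat = quat / np.linalg.norm(quat, axis=1)[:, None]

    rots = _quat_to_matrices(quat)
    bodies = distal_bodies(model, trial.elbow_flexion)
    coms_body = np.array([b.com_body for b in bodies])  # (B, 3)
    # r_i(t) = p_s(t) + R(t) c_i
    com_world = pos[None, :, :] + np.einsum("nij,bj->bni", rots, coms_body)
    vel = np.gradient(com_world, time, axis=1, edge_order=2)
    acc = np.gradient(vel, time, axis=1, edge_order=2)

    omega = _finite_difference_omega(time, quat)
    alpha = np.gradient(omega, time, axis=0, edge_order=2)

    u_hat = rots[:, :, 2]  # R @ e_z, long axis pointing proximally
    if model.interface_position is None:
        raise InvalidInputError("model has no interface plane")
    p_body = _body_frame_point(model.interface_position,
                               model.upper_arm_length, trial.elbow_flexion)
    interface = pos + np.einsum("nij,j->ni", rots, p_body)

    return KinematicState(
        time=time, rotations=rots, shoulder_position=pos,
        com_positions=com_world, com_accelerations=acc, omega=omega,
        alpha=alpha, u_hat=u_hat, interface_point=interface,
        body_names=tuple(b.name for b in bodies),
        elbow_flexion=trial.elbow_flexion)


# ---------------------------------------------------------------------------
# loads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadSeries:
    """Interface force/moment series with resolved components.

    Invariants: bending^2 + torsion^2 = |M|^2 and
    axial^2 + |transverse force|^2 = |F|^2 at every sample.
    """

    time: np.ndarray  # (n,)
    force: np.ndarray  # (n, 3) N, global frame
    moment: np.ndarray  # (n, 3) N.m about the interface point
    u_hat: np.ndarray  # (n, 3)
    bending: np.ndarray  # (n,) N.m >= 0
    torsion: np.ndarray  # (n,) N.m >= 0
    axial: np.ndarray  # (n,) N, tensile positive

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "time": self.time,
            "Fx": self.force[:, 0], "Fy": self.force[:, 1],
            "Fz": self.force[:, 2],
            "Mx": self.moment[:, 0], "My": self.moment[:, 1],
            "Mz": self.moment[:, 2],
            "bending": self.bending, "torsion": self.torsion,
            "axial": self.axial,
        }).to_csv(path, index=False)


def resolve_components(force, moment, u_hat):
    """Resolve (F, M) along the long axis u into (bending, torsion, axial).

    Accepts single 3-vectors or (n, 3) arrays.  ``axial = F . u`` (tensile
    positive with u proximal), ``torsion = |M . u|``,
    ``bending = |M - (M . u) u|``.
    """
    force = np.asarray(force, dtype=float)
    moment = np.asarray(moment, dtype=float)
    u_hat = np.asarray(u_hat, dtype=float)
    single = force.ndim == 1
    f = np.atleast_2d(force)
    m = np.atleast_2d(moment)
    u = np.atleast_2d(u_hat)
    if np.any(np.abs(np.linalg.norm(u, axis=1) - 1.0) > 1e-9):
        raise InvalidInputError("u_hat must be unit length within 1e-9")
    axial = np.einsum("ni,ni->n", f, u)
    m_axial = np.einsum("ni,ni->n", m, u)
    torsion = np.abs(m_axial)
    bending = np.linalg.norm(m - m_axial[:, None] * u, axis=1)
    if single:
        return float(bending[0]), float(torsion[0]), float(axial[0])
    return bending, torsion, axial


def interface_loads(model: LimbModel, kin: KinematicState,
                    handheld_mass: float | None = None,
                    elbow_flexion: float | None = None,
                    gravity: np.ndarray = GRAVITY) -> LoadSeries:
    """Newton-Euler interface loads summed over all bodies distal of the plane.

    ``handheld_mass`` overrides the model's carried mass (point mass at the
    hand COM + configured offset).  ``elbow_flexion`` defaults to the value
    recorded in the kinematic state.
    """
    if np.any(~np.isfinite(kin.com_accelerations)):
        bad = np.argwhere(~np.isfinite(kin.com_accelerations))[0]
        raise InvalidInputError(
            f"non-finite acceleration for body {kin.body_names[bad[0]]} "
            f"at sample {bad[1]}")
    flexion = kin.elbow_flexion if elbow_flexion is None else elbow_flexion
    bodies = distal_bodies(model, flexion, handheld_mass=handheld_mass)
    if tuple(b.name for b in bodies) != kin.body_names:
        raise InvalidInputError(
            "kinematic state bodies do not match the model; recompute "
            "differentiate_poses for this model/handheld configuration")
    g = np.asarray(gravity, dtype=float)

    masses = np.array([b.mass for b in bodies])  # (B,)
    net = kin.com_accelerations - g  # (B, n, 3)
    force = np.einsum("b,bni->ni", masses, net)

    lever = kin.com_positions - kin.interface_point[None, :, :]  # (B, n, 3)
    moment = np.einsum("b,bni->ni", masses, np.cross(lever, net, axis=2))

    # rotational terms: I_w = R I_b R^T per body per sample
    inertia_body = np.array([b.inertia_body for b in bodies])  # (B, 3, 3)
    iw = np.einsum("nij,bjk,nlk->bnil", kin.rotations, inertia_body,
                   kin.rotations)
    moment += np.einsum("bnij,nj->ni", iw, kin.alpha)
    i_omega = np.einsum("bnij,nj->bni", iw, kin.omega)
    moment += np.cross(np.broadcast_to(kin.omega, i_omega.shape), i_omega,
                       axis=2).sum(axis=0)

    bending, torsion, axial = resolve_components(force, moment, kin.u_hat)
    return LoadSeries(time=kin.time, force=force, moment=moment,
                      u_hat=kin.u_hat, bending=bending, torsion=torsion,
                      axial=axial)


def point_mass_oracle(model: LimbModel, kin: KinematicState,
                      n_points: int = 1000,
                      handheld_mass: float | None = None,
                      elbow_flexion: float | None = None,
                      gravity: np.ndarray = GRAVITY) -> LoadSeries:
    """Brute-force loads from a point-mass discretization of every segment.

    Each distal segment becomes ``n_points`` equal point masses at midpoints
    along its axis; each point's world position series is differentiated
    numerically (no filtering, no inertia tensors) and ``m (a - g)`` terms are
    summed directly.  Matches :func:`interface_loads` exactly for statics and
    converges as 1/n_points^2 for rod-inertia (zero transverse radius) models;
    axial spin inertia of finite-radius cylinders is not representable by
    on-axis points.
    """
    if n_points < 10:
        raise InvalidInputError("n_points must be >= 10 per segment")
    g = np.asarray(gravity, dtype=float)
    flexion = kin.elbow_flexion if elbow_flexion is None else elbow_flexion
    bodies = distal_bodies(model, flexion, handheld_mass=handheld_mass)

    offsets = []
    masses = []
    for b in bodies:
        if b.length == 0.0 or b.mass == 0.0:
            offsets.append(b.com_body[None, :])
            masses.append(np.array([b.mass]))
        else:
            # uniform rod of length L centered on the segment COM: preserves
            # mass, COM and the m L^2 / 12 second moment the model assumes
            fractions = (np.arange(n_points) + 0.5) / n_points - 0.5
            offsets.append(b.com_body[None, :]
                           + fractions[:, None] * b.length * b.axis_body)
            masses.append(np.full(n_points, b.mass / n_points))
    points_body = np.concatenate(offsets)  # (P, 3)
    point_masses = np.concatenate(masses)  # (P,)

    # world positions and accelerations of every point
    pos = kin.shoulder_position[None, :, :] + np.einsum(
        "nij,pj->pni", kin.rotations, points_body)
    vel = np.gradient(pos, kin.time, axis=1, edge_order=2)
    acc = np.gradient(vel, kin.time, axis=1, edge_order=2)

    net = acc - g  # (P, n, 3)
    force = np.einsum("p,pni->ni", point_masses, net)
    lever = pos - kin.interface_point[None, :, :]
    moment = np.einsum("p,pni->ni", point_masses, np.cross(lever, net, axis=2))

    bending, torsion, axial = resolve_components(force, moment, kin.u_hat)
    return LoadSeries(time=kin.time, force=force, moment=moment,
                      u_hat=kin.u_hat, bending=bending, torsion=torsion,
                      axial=axial)


def loads_for_trial(trial: MotionTrial, model: LimbModel,
                    filter_cutoff: float | None = DEFAULT_FILTER_CUTOFF,
                    gravity: np.ndarray = GRAVITY) -> LoadSeries:
    """Convenience: differentiate the trial then compute interface loads.

    The model's handheld mass is taken from the trial.
    """
    carried = model.with_handheld(trial.handheld_mass, model.handheld_offset) \
        if trial.handheld_mass != model.handheld_mass else model
    kin = differentiate_poses(trial, carried, filter_cutoff=filter_cutoff)
    return interface_loads(carried, kin, elbow_flexion=trial.elbow_flexion,
                           gravity=gravity)
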