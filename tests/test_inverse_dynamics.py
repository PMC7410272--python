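import dataclasses

import numpy as np
import pytest

from conftest import prosthetic_model, static_trial, zero_radius
from oiload.errors import InvalidInputError
from oiload.inverse_dynamics import (
    differentiate_poses,
    interface_loads,
    loads_for_trial,
    point_mass_oracle,
    resolve_components,
)
from oiload.limb_model import AmputationConfig, build_prosthetic_model
from oiload.motion_synth import ActivityParams, MotionTrial, generate_trial
from oiload.sensitivity import scale_distal_masses

G = 9.81

GENTLE = ActivityParams(duration=2.0, fundamental_frequency=0.6,
                        amplitude_means=(0.5, 0.3, 0.4),
                        amplitude_sds=(0.1, 0.08, 0.1),
                        translation_amplitude=0.03)


class TestDifferentiatePoses:
    def test_constant_pose_zero_kinematics(self, subject):
        model = prosthetic_model(subject, "advanced", 0.75)
        kin = differentiate_poses(static_trial(), model, filter_cutoff=None)
        assert np.allclose(kin.com_accelerations, 0.0)
        assert np.allclose(kin.omega, 0.0)
        assert np.allclose(kin.alpha, 0.0)

    def test_uniform_rotation_rate(self, subject):
        model = prosthetic_model(subject, "advanced", 0.25)
        rate = 2.5
        t = np.arange(0, 3, 0.01)
        half = rate * t / 2
        quat = np.column_stack(
            [np.cos(half), np.sin(half), 0 * t, 0 * t])
        trial = MotionTrial("jogging", 100.0, t, np.zeros((len(t), 3)), quat,
                            0.0)
        kin = differentiate_poses(trial, model, filter_cutoff=None)
        speeds = np.linalg.norm(kin.omega, axis=1)
        assert np.allclose(speeds, rate, rtol=1e-3)

    def test_parabolic_translation(self, subject):
        model = prosthetic_model(subject, "advanced", 0.25)
        accel = np.array([0.7, -0.3, 1.1])
        t = np.arange(0, 2, 0.01)
        pos = 0.5 * accel[None, :] * t[:, None] ** 2
        trial = MotionTrial("jogging", 100.0, t, pos,
                            np.tile([1.0, 0, 0, 0], (len(t), 1)), 0.0)
        kin = differentiate_poses(trial, model, filter_cutoff=None)
        for b in range(kin.com_accelerations.shape[0]):
            assert np.allclose(kin.com_accelerations[b], accel, rtol=1e-3,
                               atol=1e-9)

    def test_too_short(self, subject):
        model = prosthetic_model(subject)
        with pytest.raises(InvalidInputError):
            differentiate_poses(static_trial(n=3), model, filter_cutoff=None)


class TestResolveComponents:
    def test_compressive_axial(self):
        bending, torsion, axial = resolve_components(
            [0, 0, -10.0], [0, 0, 0.0], [0, 0, 1.0])
        assert axial == pytest.approx(-10.0)
        assert bending == 0 and torsion == 0

    def test_pythagorean_bending(self):
        bending, torsion, _ = resolve_components(
            [0, 0, 0.0], [3.0, 4.0, 0.0], [0, 0, 1.0])
        assert bending == pytest.approx(5.0)
        assert torsion == pytest.approx(0.0)

    def test_pure_torsion(self):
        bending, torsion, _ = resolve_components(
            [0, 0, 0.0], [0.0, 0.0, 7.0], [0, 0, 1.0])
        assert torsion == pytest.approx(7.0)
        assert bending == pytest.approx(0.0)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(InvalidInputError):
            resolve_components([1, 0, 0], [0, 1, 0], [0, 0, 2.0])

    def test_magnitude_invariants_random(self, rng):
        f = rng.normal(size=(40, 3))
        m = rng.normal(size=(40, 3))
        u = rng.normal(size=(40, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        bending, torsion, axial = resolve_components(f, m, u)
        assert np.allclose(bending ** 2 + torsion ** 2,
                           np.sum(m * m, axis=1), rtol=1e-12)
        transverse = f - np.einsum("ni,ni->n", f, u)[:, None] * u
        assert np.allclose(axial ** 2 + np.sum(transverse ** 2, axis=1),
                           np.sum(f * f, axis=1), rtol=1e-12)


class TestStatics:
    def test_vertical_hang_advanced_75(self, subject):
        model = prosthetic_model(subject, "advanced", 0.75)
        kin = differentiate_poses(static_trial(), model, filter_cutoff=None)
        loads = interface_loads(model, kin)
        assert np.allclose(loads.axial, (0.1 + 1.875 + 1.525) * G)
        assert np.allclose(loads.bending, 0.0, atol=1e-10)
        assert np.allclose(loads.torsion, 0.0, atol=1e-10)

    def test_horizontal_arm_bending_matches_hand_sum(self, subject):
        model = prosthetic_model(subject, "advanced", 0.25)
        s2 = np.sqrt(0.5)
        trial = static_trial(quat=(s2, s2, 0, 0))  # arm horizontal along +y
        kin = differentiate_poses(trial, model, filter_cutoff=None)
        loads = interface_loads(model, kin)
        expected = G * sum(
            seg.mass * abs(seg.com_arc_position - model.interface_position)
            for seg in model.distal_segments)
        assert np.allclose(loads.bending, expected, rtol=1e-12)
        assert np.allclose(loads.axial, 0.0, atol=1e-9)

    def test_point_mass_degenerate_reduction(self, subject):
        model = prosthetic_model(subject, "advanced", 0.25)
        weightless = dataclasses.replace(model, segments=tuple(
            dataclasses.replace(s, mass=0.0) for s in model.segments),
            handheld_mass=1.0)
        kin = differentiate_poses(static_trial(elbow_flexion=0.0), weightless,
                                  filter_cutoff=None)
        loads = interface_loads(weightless, kin)
        assert np.allclose(loads.axial, 1.0 * G)
        d = weightless.hand_com_arc_position - weightless.interface_position
        assert np.allclose(loads.bending, 0.0, atol=1e-10)
        # horizontal: moment = m g d
        s2 = np.sqrt(0.5)
        kin2 = differentiate_poses(static_trial(quat=(s2, s2, 0, 0)),
                                   weightless, filter_cutoff=None)
        loads2 = interface_loads(weightless, kin2)
        assert np.allclose(loads2.bending, 1.0 * G * d, rtol=1e-12)


class TestOracle:
    def test_static_equivalence(self, subject):
        model = prosthetic_model(subject, "myoelectric_hand", 0.25)
        kin = differentiate_poses(static_trial(elbow_flexion=0.3), model,
                                  filter_cutoff=None)
        impl = interface_loads(model, kin)
        oracle = point_mass_oracle(model, kin, n_points=100)
        assert np.allclose(impl.force, oracle.force, atol=1e-9)
        assert np.allclose(impl.moment, oracle.moment, atol=1e-9)

    def test_dynamic_convergence(self, subject):
        model = zero_radius(prosthetic_model(subject, "advanced", 0.25))
        trial = generate_trial("jumping_jack", subject,
                               np.random.default_rng(5), params=GENTLE,
                               sample_rate=200.0)
        kin = differentiate_poses(trial, model, filter_cutoff=None)
        impl = interface_loads(model, kin)
        scale_f = np.abs(impl.force).max()
        scale_m = np.abs(impl.moment).max()
        errs = {}
        for n in (100, 1000):
            oracle = point_mass_oracle(model, kin, n_points=n)
            errs[n] = max(np.abs(impl.force - oracle.force).max() / scale_f,
                          np.abs(impl.moment - oracle.moment).max() / scale_m)
        assert errs[1000] < 1e-3
        assert errs[1000] <= errs[100]

    def test_zero_mass_model(self, subject):
        model = prosthetic_model(subject, "advanced", 0.25)
        weightless = dataclasses.replace(model, segments=tuple(
            dataclasses.replace(s, mass=0.0) for s in model.segments))
        trial = generate_trial("jogging", subject, np.random.default_rng(2))
        kin = differentiate_poses(trial, weightless, filter_cutoff=None)
        oracle = point_mass_oracle(weightless, kin, n_points=50)
        assert np.allclose(oracle.force, 0.0)
        assert np.allclose(oracle.moment, 0.0)

    def test_min_points(self, subject):
        model = prosthetic_model(subject)
        kin = differentiate_poses(static_trial(), model, filter_cutoff=None)
        with pytest.raises(InvalidInputError):
            point_mass_oracle(model, kin, n_points=5)


class TestLinearity:
    @pytest.mark.parametrize("k", [0.5, 1.5])
    def test_exact_scaling_all_distal_masses(self, subject, k):
        model = prosthetic_model(subject, "advanced", 0.25).with_handheld(2.0)
        model = dataclasses.replace(model, handheld_mass=0.0)
        trial = generate_trial("jumping_jack", subject,
                               np.random.default_rng(3))
        base = loads_for_trial(trial, model, filter_cutoff=None)
        scaled_model = scale_distal_masses(model, k, include_handheld=True,
                                           include_connectors=True)
        scaled = loads_for_trial(trial, scaled_model, filter_cutoff=None)
        assert np.allclose(scaled.force, k * base.force, rtol=1e-12, atol=1e-12)
        assert np.allclose(scaled.moment, k * base.moment, rtol=1e-12,
                           atol=1e-12)
        assert np.allclose(scaled.bending, k * base.bending, rtol=1e-12,
                           atol=1e-12)
        assert np.allclose(scaled.torsion, k * base.torsion, rtol=1e-12,
                           atol=1e-12)
        assert np.allclose(scaled.axial, k * base.axial, rtol=1e-12,
                           atol=1e-10)

    def test_fixed_pylon_bounds_peak_ratio(self, subject):
        k = 0.5
        model = prosthetic_model(subject, "body_powered", 0.25)
        trial = generate_trial("jumping_jack", subject,
                               np.random.default_rng(4))
        base = loads_for_trial(trial, model, filter_cutoff=None)
        partial = scale_distal_masses(model, k)  # pylon/adapter untouched
        scaled = loads_for_trial(trial, partial, filter_cutoff=None)
        for attr in ("bending", "axial"):
            ratio = getattr(scaled, attr).max() / getattr(base, attr).max()
            assert k < ratio < 1.0


class TestTorsionLevelInvariance:
    def test_identical_series_across_levels(self, subject):
        trial = generate_trial("internal_rotation", subject,
                               np.random.default_rng(6))
        torsions = {}
        for level in (0.25, 0.50, 0.75):
            model = zero_radius(prosthetic_model(subject, "advanced", level))
            torsions[level] = loads_for_trial(trial, model,
                                              filter_cutoff=None).torsion
        assert np.allclose(torsions[0.25], torsions[0.50], atol=1e-10)
        assert np.allclose(torsions[0.25], torsions[0.75], atol=1e-10)
        assert torsions[0.25].max() > 0.1  # non-trivial signal


class TestFrameInvariance:
    def test_rigid_global_rotation(self, subject):
        from oiload.inverse_dynamics import _quat_to_matrices

        model = prosthetic_model(subject, "myoelectric_hand", 0.25)
        trial = generate_trial("underhand_toss", subject,
                               np.random.default_rng(8))
        base = loads_for_trial(trial, model, filter_cutoff=None)

        # rotate the whole world (kinematics + gravity) by Q
        axis = np.array([0.3, 0.5, 0.81])
        axis /= np.linalg.norm(axis)
        qr = np.concatenate([[np.cos(0.4)], np.sin(0.4) * axis])

        def qmul(a, b):
            w1, x1, y1, z1 = a.T
            w2, x2, y2, z2 = b.T
            return np.column_stack([
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2])

        Q = _quat_to_matrices(qr[None, :])[0]
        rotated = MotionTrial(
            trial.activity, trial.sample_rate, trial.time,
            trial.shoulder_position @ Q.T,
            qmul(np.tile(qr, (trial.n_samples, 1)), trial.quaternions),
            trial.elbow_flexion, handheld_mass=trial.handheld_mass)
        carried = model.with_handheld(trial.handheld_mass)
        kin = differentiate_poses(rotated, carried, filter_cutoff=None)
        loads = interface_loads(carried, kin,
                                gravity=Q @ np.array([0.0, 0.0, -9.81]))
        assert np.allclose(loads.bending, base.bending, atol=1e-9)
        assert np.allclose(loads.torsion, base.torsion, atol=1e-9)
        assert np.allclose(loads.axial, base.axial, atol=1e-9)


class TestErrorPropagation:
    def test_nan_names_sample(self, subject):
        model = prosthetic_model(subject)
        kin = differentiate_poses(static_trial(), model, filter_cutoff=None)
        acc = kin.com_accelerations.copy()
        acc[0, 7, 1] = np.nan
        bad = dataclasses.replace(kin, com_accelerations=acc)
        with pytest.raises(InvalidInputError, match="sample 7"):
            interface_loads(model, bad)
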