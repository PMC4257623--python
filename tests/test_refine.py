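import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stillframe import (
    Beam,
    CrystalModel,
    SpotObservation,
    UnitCell,
    build_a_matrix,
    compute_delta_psi,
    hybrid_target,
    misorientation_angle,
    perturb_model,
    positional_target,
    project_to_detector,
    q_from_hkl,
    refine_model,
    reflecting_position,
    run_protocol,
    simulate_still,
    symmetrize_to_bravais,
)
from stillframe.refine import ProtocolError, RefinementResult


def _strip_noise_free_spots(scene):
    return scene.spots


def _one_spot_setup(delta_psi=math.pi / 10):
    """A single reflection whose positional residual is zero by construction
    and whose delta-psi equals the requested value (rotate an on-sphere point
    off the sphere by -delta_psi about its axis)."""
    beam = Beam(wavelength=1.0)
    from stillframe import psi_detector

    det = psi_detector()
    # an on-sphere point: |r| = 0.6 with r . e_a = |r|^2 lambda / 2 fixes the polar angle
    qn = 0.6
    cos_tr = qn / 2
    sin_tr = math.sqrt(1 - cos_tr**2)
    e_a = np.array([0.0, 0.0, 1.0])
    e_b = np.array([1.0, 0.0, 0.0])
    r_on = qn * (cos_tr * e_a + sin_tr * e_b)
    axis = np.cross(e_a, e_b)
    q = Rotation.from_rotvec(-delta_psi * axis).apply(r_on)
    rec = compute_delta_psi(q, beam)
    assert rec.delta_psi == pytest.approx(delta_psi, abs=1e-12)
    A = np.column_stack([q, [0, 0.05, 0], [0, 0, 0.05]])
    model = CrystalModel(A)
    obs_xy = project_to_detector(reflecting_position(q, beam) + beam.s0, beam, det)
    spot = SpotObservation(position=obs_xy, hkl=(1, 0, 0))
    return model, [spot], beam, det


class TestTargets:
    def test_perfect_model_gives_zero_positional_target(self, clean_scene):
        s = clean_scene
        assert positional_target(s.truth_model, s.spots, s.beam, s.det) < 1e-16

    def test_on_sphere_spot_gives_zero_hybrid_target(self):
        model, spots, beam, det = _one_spot_setup(delta_psi=0.0)
        assert hybrid_target(model, spots, beam, det) < 1e-20

    def test_hybrid_decomposes_into_positional_plus_delta_psi(self, clean_scene):
        s = clean_scene
        pos = positional_target(s.truth_model, s.spots, s.beam, s.det)
        hyb = hybrid_target(s.truth_model, s.spots, s.beam, s.det)
        dpsi_sum = sum(
            (sp.extras["delta_psi_rad"] / (2 * math.pi)) ** 2 for sp in s.spots
        )
        assert hyb == pytest.approx(pos + dpsi_sum, rel=1e-10)

    def test_single_offset_spot(self, clean_scene):
        s = clean_scene
        spots = [SpotObservation(position=sp.position, hkl=sp.hkl) for sp in s.spots]
        spots[0].position = (spots[0].position[0] + 0.1, spots[0].position[1])
        assert positional_target(s.truth_model, spots, s.beam, s.det) == pytest.approx(
            0.01, rel=1e-9
        )

    def test_hybrid_unit_convention(self):
        model, spots, beam, det = _one_spot_setup(math.pi / 10)
        # delta-psi term only: (pi/10 / 2 pi)^2 = 0.0025
        assert positional_target(model, spots, beam, det) == pytest.approx(0.0, abs=1e-18)
        assert hybrid_target(model, spots, beam, det) == pytest.approx(0.0025, rel=1e-9)

    def test_hybrid_additivity(self):
        model, spots, beam, det = _one_spot_setup(math.pi / 10)
        spots[0].position = (spots[0].position[0] + 0.1, spots[0].position[1])
        assert hybrid_target(model, spots, beam, det) == pytest.approx(0.0125, rel=1e-9)

    def test_target_equals_per_spot_oracle(self, noisy_scene):
        s = noisy_scene
        model = perturb_model(s.truth_model, (0.05, -0.03, 0.02), 0.0005)
        total = hybrid_target(model, s.spots, s.beam, s.det)
        manual = 0.0
        for sp in s.spots:
            q = q_from_hkl(model, sp.hkl)
            rec = compute_delta_psi(q, s.beam)
            calc = project_to_detector(reflecting_position(q, s.beam) + s.beam.s0,
                                       s.beam, s.det)
            manual += (sp.position[0] - calc[0]) ** 2 + (sp.position[1] - calc[1]) ** 2
            manual += (rec.delta_psi / (2 * math.pi)) ** 2
        assert total == pytest.approx(manual, rel=1e-12)

    def test_unassigned_spot_rejected(self, clean_scene):
        s = clean_scene
        spots = [SpotObservation(position=(0.0, 0.0))]
        with pytest.raises(ValueError):
            positional_target(s.truth_model, spots, s.beam, s.det)


class TestRefineModel:
    def test_stationary_at_truth(self, clean_scene):
        s = clean_scene
        res = refine_model(s.spots, s.truth_model, s.beam, s.det, target="eq1",
                           constraint="triclinic")
        assert res.converged and res.n_iterations <= 2
        ang, _ = misorientation_angle(res.model.A, s.truth_model.A, "hexagonal_622")
        assert ang < 1e-8

    def test_hybrid_stays_near_truth_on_clean_data(self, clean_scene):
        """The delta-psi residuals of real (envelope-accepted) reflections are
        nonzero even at the true model, so the hybrid optimum sits close to
        but not exactly at the truth; the displacement is bounded by the
        within-envelope scatter."""
        s = clean_scene
        res = refine_model(s.spots, s.truth_model, s.beam, s.det, target="eq2",
                           constraint="triclinic")
        ang, _ = misorientation_angle(res.model.A, s.truth_model.A, "hexagonal_622")
        assert ang < 0.01

    def test_history_non_increasing(self, noisy_scene):
        s = noisy_scene
        start = perturb_model(s.truth_model, (0.2, -0.15, 0.1), 0.002)
        res = refine_model(s.spots, start, s.beam, s.det, target="eq2",
                           constraint="triclinic")
        assert np.all(np.diff(res.target_history) <= 0.0)

    def test_per_spot_residuals_recomputable(self, noisy_scene):
        s = noisy_scene
        start = perturb_model(s.truth_model, (0.1, 0.1, -0.1), 0.001)
        res = refine_model(s.spots, start, s.beam, s.det, target="eq2",
                          constraint="triclinic")
        row = res.per_spot.iloc[17]
        q = q_from_hkl(res.model, (row.h, row.k, row.l))
        rec = compute_delta_psi(q, s.beam)
        assert rec.delta_psi == pytest.approx(row.delta_psi_rad, abs=1e-10)
        calc = project_to_detector(reflecting_position(q, s.beam) + s.beam.s0,
                                   s.beam, s.det)
        assert calc[0] == pytest.approx(row.x_calc_mm, abs=1e-10)

    def test_too_few_spots_rejected(self, clean_scene):
        s = clean_scene
        with pytest.raises(ValueError):
            refine_model(s.spots[:5], s.truth_model, s.beam, s.det,
                         constraint="triclinic")

    def test_hybrid_recovers_transverse_misorientation(self, clean_scene):
        s = clean_scene
        R = (Rotation.from_euler("x", 0.2, degrees=True)
             * Rotation.from_euler("y", -0.15, degrees=True)
             * Rotation.from_euler("z", 0.1, degrees=True)).as_matrix()
        start = CrystalModel(R @ s.truth_model.A, s.truth_model.symmetry_tag)
        res = run_protocol(s.spots, start, s.beam, s.det, "eq2", "eq2")
        ang, _ = misorientation_angle(res.model.A, s.truth_model.A, "hexagonal_622")
        assert ang < 0.01

    def test_positional_only_leaves_transverse_error(self, clean_scene):
        """The positional target carries no transverse-angle information on a
        still, so an eq1-only protocol retains most of the start R_x/R_y error
        while the hybrid protocol removes it."""
        s = clean_scene
        R = (Rotation.from_euler("x", 0.2, degrees=True)
             * Rotation.from_euler("y", -0.15, degrees=True)
             * Rotation.from_euler("z", 0.1, degrees=True)).as_matrix()
        start = CrystalModel(R @ s.truth_model.A, s.truth_model.symmetry_tag)
        res1 = run_protocol(s.spots, start, s.beam, s.det, "eq1", "eq1")
        res2 = run_protocol(s.spots, start, s.beam, s.det, "eq2", "eq2")
        ang1, _ = misorientation_angle(res1.model.A, s.truth_model.A, "hexagonal_622")
        ang2, _ = misorientation_angle(res2.model.A, s.truth_model.A, "hexagonal_622")
        assert ang1 >= 5.0 * ang2

    def test_curvature_degeneracy_of_positional_target(self, clean_scene):
        """At the true solution the positional target's curvature along the
        transverse angles is far below the curvature along the beam-axis
        rotation (the still-shot degeneracy)."""
        s = clean_scene

        def curv(ax):
            h = 2e-4
            v = np.zeros(3)
            v[ax] = h

            def f(vv):
                R = Rotation.from_rotvec(vv).as_matrix()
                m = CrystalModel(R @ s.truth_model.A, s.truth_model.symmetry_tag)
                return positional_target(m, s.spots, s.beam, s.det)

            return (f(v) - 2 * f(np.zeros(3)) + f(-v)) / h**2

        cx, cy, cz = curv(0), curv(1), curv(2)
        assert cz >= 10.0 * cx and cz >= 10.0 * cy


class TestProtocol:
    def test_symmetrization_of_nearly_hexagonal_cell(self):
        cell = UnitCell(281.2, 280.9, 165.25, 90.02, 89.98, 119.95)
        rng = np.random.default_rng(5)
        m = build_a_matrix(cell, Rotation.random(rng=rng).as_matrix())
        sym = symmetrize_to_bravais(m, "hexagonal_622")
        c = sym.cell
        assert c.a == pytest.approx((281.2 + 280.9) / 2, rel=1e-12)
        assert c.b == pytest.approx(c.a, rel=1e-12)
        assert (c.alpha, c.beta, c.gamma) == pytest.approx((90, 90, 120), abs=1e-9)
        assert sym.symmetry_tag == "hexagonal_622"

    def test_triclinic_symmetrization_is_identity(self, clean_scene):
        m = clean_scene.truth_model
        assert symmetrize_to_bravais(m, "triclinic") is m

    def test_stage1_divergence_aborts(self, clean_scene, monkeypatch):
        s = clean_scene
        diverged = RefinementResult(
            model=s.truth_model, target_history=np.array([1.0, 2.0]),
            converged=False, per_spot=None, n_iterations=1,
            message="divergence: no decreasing step within damping budget",
        )
        monkeypatch.setattr("stillframe.refine.refine_model",
                            lambda *a, **k: diverged)
        with pytest.raises(ProtocolError) as err:
            run_protocol(s.spots, s.truth_model, s.beam, s.det, "eq1", "eq1")
        assert err.value.stage == 1

    def test_skipping_stage_two(self, clean_scene):
        s = clean_scene
        start = perturb_model(s.truth_model, (0.1, 0.1, 0.1), 0.001)
        res = run_protocol(s.spots, start, s.beam, s.det, "eq2", None)
        assert res.model.symmetry_tag == "hexagonal_622"
        c = res.model.cell
        assert c.a == pytest.approx(c.b, rel=1e-12)
        assert c.gamma == pytest.approx(120.0, abs=1e-9)
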