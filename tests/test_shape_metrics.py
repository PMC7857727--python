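"""Principal axes, the binding-site orientation angle and model-space
distance metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import sphere_pr
from ringfit.scattering_calc import BeadModel
from ringfit.shape_metrics import alpha_angle, model_dmax, model_pr, principal_axes
from ringfit.synthetic import make_oligomer, preset


def tilted_ring_model(alpha_deg: float, n: int = 4, ring_r: float = 100.0):
    """n eye-pair anchors on a ring in the xy-plane, each eye vector tilted
    at ``alpha_deg`` to +z; extra beads make the assembly flat."""
    coords = []
    anchors = {}
    protomer = []
    alpha = np.radians(alpha_deg)
    for k in range(n):
        theta = 2 * np.pi * k / n
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        center = ring_r * radial
        vec = np.sin(alpha) * radial + np.cos(alpha) * np.array([0, 0, 1.0])
        anchors[f"S345/{k}"] = len(coords)
        coords.append(center)
        anchors[f"A402/{k}"] = len(coords)
        coords.append(center + 20.0 * vec)
        # flatten the assembly so z is unambiguously the thin axis
        for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            coords.append(0.7 * ring_r * np.array([np.cos(theta + ang),
                                                   np.sin(theta + ang), 0.0]))
            protomer.append(k)
    protomer_id = np.zeros(len(coords), dtype=int)
    i = 0
    for k in range(n):
        protomer_id[i:i + 10] = k
        i += 10
    return BeadModel(np.asarray(coords), protomer_id=protomer_id,
                     anchors=anchors)


class TestPrincipalAxes:
    def test_collinear_beads_flagged_degenerate(self):
        model = BeadModel(np.column_stack([np.linspace(0, 50, 10),
                                           np.zeros(10), np.zeros(10)]))
        with pytest.warns(UserWarning):
            axes = principal_axes(model)
        assert axes.degenerate
        assert abs(axes.axes[2] @ np.array([1.0, 0, 0])) == pytest.approx(1.0)

    def test_planar_square_thin_axis_is_z(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0.0]]) * 50
        with pytest.warns(UserWarning):  # two in-plane eigenvalues degenerate
            axes = principal_axes(BeadModel(pts))
        assert abs(axes.axes[0] @ np.array([0, 0, 1.0])) == pytest.approx(1.0)

    def test_equivariance_under_random_rotations(self):
        rng = np.random.default_rng(8)
        model = BeadModel(rng.normal(0, 1, (60, 3)) * np.array([30.0, 18.0, 6.0]))
        ref = principal_axes(model)
        for state in (1, 2, 3):
            rot = Rotation.random(random_state=state).as_matrix()
            moved = principal_axes(model.transformed(rot, np.zeros(3)))
            for i in range(3):
                cosang = abs(moved.axes[i] @ (rot @ ref.axes[i]))
                assert np.arccos(np.clip(cosang, -1, 1)) < 1e-6


class TestAlphaAngle:
    def test_parallel_vectors_give_180(self):
        res = alpha_angle(tilted_ring_model(180.0))
        assert res.mean_alpha == pytest.approx(180.0, abs=1e-6)

    def test_perpendicular_vectors_give_90(self):
        res = alpha_angle(tilted_ring_model(90.0))
        assert res.mean_alpha == pytest.approx(90.0, abs=1e-6)

    def test_flip_rule_maps_30_to_150(self):
        res = alpha_angle(tilted_ring_model(30.0))
        assert res.mean_alpha == pytest.approx(150.0, abs=1e-6)
        assert res.flipped

    def test_invariant_under_rigid_motion(self):
        model = tilted_ring_model(128.0)
        ref = alpha_angle(model).mean_alpha
        rot = Rotation.random(random_state=5).as_matrix()
        moved = alpha_angle(model.transformed(rot, np.array([5.0, -8.0, 3.0])))
        assert moved.mean_alpha == pytest.approx(ref, abs=1e-6)

    def test_missing_anchor_is_configuration_error(self):
        model = tilted_ring_model(120.0)
        del model.anchors["A402/2"]
        with pytest.raises(KeyError, match="A402/2"):
            alpha_angle(model)

    @pytest.mark.parametrize("alpha_true", [95.0, 128.0, 150.0, 175.0])
    def test_generator_tilt_recovered_within_2_degrees(self, alpha_true):
        truth = make_oligomer(preset("fp3", alpha_true=alpha_true,
                                     beads_per_eye=60,
                                     beads_per_arm_cluster=12))
        res = alpha_angle(truth.model)
        assert res.mean_alpha == pytest.approx(alpha_true, abs=2.0)


class TestModelDistances:
    def test_two_beads(self):
        assert model_dmax(BeadModel([[0, 0, 0], [0, 0, 100.0]])) == 100.0

    def test_unit_cube_diagonal(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        assert model_dmax(BeadModel(corners)) == pytest.approx(np.sqrt(3.0))

    def test_model_pr_two_beads_single_bin_with_pair_mass(self):
        pr = model_pr(BeadModel([[0, 0, 0], [0, 0, 100.0]]), bin_width=1.0)
        # both orderings counted: integral = (sum w)^2 - sum w^2 = 2
        assert np.trapezoid(pr.p, pr.r) == pytest.approx(2.0, rel=0.01)
        assert pr.r[np.argmax(pr.p)] == pytest.approx(100.0, abs=1.0)

    def test_model_pr_uniform_sphere_matches_closed_form(self):
        from test_scattering_calc import halton_ball
        pr = model_pr(BeadModel(halton_ball(2000, 50.0)), bin_width=2.0)
        expected = sphere_pr(pr.r, 50.0)
        a = pr.p / np.max(pr.p)
        b = expected / np.max(expected)
        assert np.sqrt(np.mean((a - b) ** 2)) < 0.02

    def test_model_pr_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(9)
        model = BeadModel(rng.normal(0, 20, (50, 3)))
        ref = model_pr(model, bin_width=1.0)
        rot = Rotation.random(random_state=2).as_matrix()
        moved = model_pr(model.transformed(rot, np.array([3.0, 4.0, 5.0])),
                         bin_width=1.0)
        assert moved.dmax == pytest.approx(ref.dmax, abs=1e-9)
        np.testing.assert_allclose(moved.p, ref.p, atol=1e-9)

    def test_dmax_bounds_peaks_and_matches_histogram_support(self):
        truth = make_oligomer(preset("fp4", beads_per_eye=40,
                                     beads_per_arm_cluster=8))
        dmax = model_dmax(truth.model)
        pr = model_pr(truth.model, bin_width=2.0)
        from ringfit.pair_distribution import find_peaks
        assert all(p.position <= dmax for p in find_peaks(pr))
        assert pr.r[np.flatnonzero(pr.p > 0)[-1]] >= dmax - 2.0
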