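"""CV geometry: values, gradients, periodic arithmetic, metric."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvsteer import cv as cvg
from cvsteer.errors import DegenerateGeometryError


def rand_coords(rng, n=8, scale=1.0):
    return scale * rng.standard_normal((n, 3))


class TestPairDistance:
    def test_unit_displacement(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert cvg.eval_pair_distance(coords, 0, 1) == pytest.approx(1.0)

    def test_matches_componentwise_oracle_and_symmetry(self, rng):
        for _ in range(50):
            c = rand_coords(rng)
            i, j = rng.choice(len(c), size=2, replace=False)
            oracle = math.sqrt(sum((c[i][k] - c[j][k]) ** 2 for k in range(3)))
            assert cvg.eval_pair_distance(c, i, j) == pytest.approx(oracle, abs=1e-12)
            assert cvg.eval_pair_distance(c, j, i) == pytest.approx(oracle, abs=1e-12)

    def test_identical_index_rejected(self, rng):
        with pytest.raises(ValueError):
            cvg.eval_pair_distance(rand_coords(rng), 2, 2)

    def test_coincident_points_give_zero(self):
        coords = np.zeros((2, 3))
        assert cvg.eval_pair_distance(coords, 0, 1) == 0.0


class TestComDistance:
    def test_singletons_reduce_to_pair_distance(self, rng):
        c = rand_coords(rng)
        assert cvg.eval_com_distance(c, [1], [4]) == pytest.approx(
            cvg.eval_pair_distance(c, 1, 4))

    def test_symmetric_pairs_about_origin(self):
        c = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        assert cvg.eval_com_distance(c, [0, 1], [2, 3]) == pytest.approx(0.0)

    def test_matches_centroid_oracle(self, rng):
        for _ in range(25):
            c = rand_coords(rng, 10)
            m = rng.uniform(0.5, 3.0, size=10)
            ga, gb = [0, 2, 5], [1, 7, 8, 9]
            ca = sum(m[i] * c[i] for i in ga) / sum(m[i] for i in ga)
            cb = sum(m[i] * c[i] for i in gb) / sum(m[i] for i in gb)
            oracle = np.linalg.norm(ca - cb)
            got = cvg.eval_com_distance(c, ga, gb, m)
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_zero_total_mass_rejected(self, rng):
        c = rand_coords(rng)
        with pytest.raises(ValueError):
            cvg.eval_com_distance(c, [0], [1], np.zeros(len(c)))


class TestDihedral:
    def test_planar_cis_is_zero(self):
        c = np.array([[1.0, 1.0, 0], [0, 0, 0], [1.0, 0, 0], [2.0, 1.0, 0]])
        assert cvg.eval_dihedral(c, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        c = np.array([[1.0, 1.0, 0], [0, 0, 0], [1.0, 0, 0], [2.0, -1.0, 0]])
        assert cvg.eval_dihedral(c, 0, 1, 2, 3) == pytest.approx(180.0, abs=1e-9)

    def test_agrees_with_mdtraj_convention(self, rng):
        """Cross-check sign and magnitude against an established package."""
        md = pytest.importorskip("mdtraj")
        from mdtraj.core import element as elem
        top = md.Topology()
        ch = top.add_chain()
        res = top.add_residue("GLY", ch)
        for k in range(4):
            top.add_atom(f"A{k}", elem.carbon, res)
        for _ in range(20):
            c = rand_coords(rng, 4)
            traj = md.Trajectory(c[None], top)
            ref = math.degrees(
                md.compute_dihedrals(traj, [[0, 1, 2, 3]])[0, 0])
            got = cvg.eval_dihedral(c, 0, 1, 2, 3)
            assert cvg.wrap_angle_diff(got, ref) == pytest.approx(0.0, abs=1e-4)

    def test_sign_flips_under_mirror_reflection(self, rng):
        for _ in range(10):
            c = rand_coords(rng, 4)
            phi = cvg.eval_dihedral(c, 0, 1, 2, 3)
            mirrored = c * np.array([1.0, 1.0, -1.0])
            phi_m = cvg.eval_dihedral(mirrored, 0, 1, 2, 3)
            assert cvg.wrap_angle_diff(phi_m, -phi) == pytest.approx(0.0, abs=1e-9)

    def test_collinear_geometry_raises(self):
        c = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1.0, 0]])
        with pytest.raises(DegenerateGeometryError):
            cvg.eval_dihedral(c, 0, 1, 2, 3)


SPECS = [
    cvg.CVSpec("d", "pair_distance", ((0,), (3,))),
    cvg.CVSpec("L", "com_distance", ((0, 1, 2), (5, 6))),
    cvg.CVSpec("chi", "dihedral", ((0,), (1,), (2,), (3,))),
]


class TestGradient:
    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind)
    def test_finite_difference_agreement(self, spec, rng):
        h = 1e-6
        for _ in range(20):
            c = rand_coords(rng)
            masses = rng.uniform(0.5, 2.0, len(c))
            grad = cvg.cv_gradient(spec, c, masses)
            if spec.periodic:
                grad = np.degrees(grad)  # FD below is in degrees
            for i in spec.indices:
                for k in range(3):
                    cp, cm = c.copy(), c.copy()
                    cp[i, k] += h
                    cm[i, k] -= h
                    vp = cvg.eval_cv(spec, cp, masses)
                    vm = cvg.eval_cv(spec, cm, masses)
                    if spec.periodic:
                        fd = cvg.wrap_angle_diff(vp, vm) / (2 * h)
                    else:
                        fd = (vp - vm) / (2 * h)
                    denom = max(1.0, abs(fd))
                    assert abs(grad[i, k] - fd) / denom < 1e-5

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind)
    def test_translation_invariance_zero_net_gradient(self, spec, rng):
        c = rand_coords(rng)
        g = cvg.cv_gradient(spec, c)
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-12)

    def test_pair_gradient_is_unit_vector(self, rng):
        c = rand_coords(rng)
        spec = SPECS[0]
        g = cvg.cv_gradient(spec, c)
        u = (c[0] - c[3]) / np.linalg.norm(c[0] - c[3])
        assert np.allclose(g[0], u, atol=1e-12)
        assert np.allclose(g[3], -u, atol=1e-12)


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind)
    def test_value_invariant_under_rotation_translation(self, spec, rng):
        from scipy.spatial.transform import Rotation
        for _ in range(10):
            c = rand_coords(rng)
            val = cvg.eval_cv(spec, c)
            R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            moved = c @ R.T + rng.standard_normal(3)
            val2 = cvg.eval_cv(spec, moved)
            if spec.periodic:
                assert cvg.wrap_angle_diff(val2, val) == pytest.approx(0, abs=1e-9)
            else:
                assert val2 == pytest.approx(val, abs=1e-9)


class TestWrapAngleDiff:
    def test_wrap_cases(self):
        assert cvg.wrap_angle_diff(179.0, -179.0) == pytest.approx(-2.0)
        assert cvg.wrap_angle_diff(13.7, 13.7) == 0.0
        assert cvg.wrap_angle_diff(-170.0, 170.0) == pytest.approx(20.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(-1080, 1080), st.floats(-1080, 1080))
    def test_matches_enumeration_oracle(self, a, b):
        got = cvg.wrap_angle_diff(a, b)
        candidates = [a - b + 360.0 * k for k in range(-7, 8)]
        best = min(candidates, key=abs)
        assert abs(got) <= 180.0 + 1e-9
        assert abs(abs(got) - abs(best)) < 1e-6


class TestCvSpaceDistance:
    def _vec(self, values):
        specs = [cvg.CVSpec("d", "pair_distance", ((0,), (1,))),
                 cvg.CVSpec("chi", "dihedral", ((0,), (1,), (2,), (3,)))]
        return cvg.CVVector(specs, values)

    def test_identity_and_single_cv(self):
        v = self._vec([1.0, 30.0])
        assert cvg.cv_space_distance(v, v, [1.0, 1.0]) == 0.0
        w = self._vec([2.5, 30.0])
        assert cvg.cv_space_distance(v, w, [1.0, 1.0]) == pytest.approx(1.5)

    def test_matches_loop_oracle_with_wrapping(self, rng):
        for _ in range(30):
            a = [rng.uniform(0, 3), rng.uniform(-180, 180)]
            b = [rng.uniform(0, 3), rng.uniform(-180, 180)]
            s = rng.uniform(0.1, 2.0, 2)
            oracle = math.sqrt(((a[0] - b[0]) / s[0]) ** 2
                               + (cvg.wrap_angle_diff(a[1], b[1]) / s[1]) ** 2)
            got = cvg.cv_space_distance(self._vec(a), self._vec(b), s)
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_triangle_inequality(self, rng):
        for _ in range(50):
            vs = [self._vec([rng.uniform(0, 3), rng.uniform(-180, 180)])
                  for _ in range(3)]
            s = rng.uniform(0.1, 2.0, 2)
            d = lambda x, y: cvg.cv_space_distance(x, y, s)
            assert d(vs[0], vs[2]) <= d(vs[0], vs[1]) + d(vs[1], vs[2]) + 1e-9

    def test_mismatched_specs_rejected(self):
        v = self._vec([1.0, 0.0])
        w = cvg.CVVector([cvg.CVSpec("x", "pair_distance", ((0,), (1,)))], [1.0])
        with pytest.raises(ValueError):
            cvg.cv_space_distance(v, w, [1.0])


class TestCVSpecValidation:
    @pytest.mark.parametrize("kind,groups", [
        ("pair_distance", ((0,),)),
        ("pair_distance", ((0, 1), (2,))),
        ("dihedral", ((0,), (1,), (2,))),
        ("dihedral", ((0,), (1,), (2,), (1,))),
        ("com_distance", ((0, 1), (1, 2))),
        ("com_distance", ((), (1,))),
    ])
    def test_invalid_groups_rejected(self, kind, groups):
        with pytest.raises(ValueError):
            cvg.CVSpec("bad", kind, groups)

    def test_periodic_iff_dihedral(self):
        assert cvg.CVSpec("chi", "dihedral", ((0,), (1,), (2,), (3,))).periodic
        assert not cvg.CVSpec("d", "pair_distance", ((0,), (1,))).periodic
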