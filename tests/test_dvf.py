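import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import map_coordinates

from t1moco import dvf as D
from t1moco.errors import ContractError, GenerationError


def random_field(shape, amplitude, seed):
    return D.generate_random_dvf(shape, amplitude, 8.0, seed=seed)


def random_set(shape=(24, 24), amplitude=2.0, seed=0):
    rng = np.random.default_rng(seed)
    return D.DVFSet(tuple(random_field(shape, amplitude, rng) for _ in range(7)))


class TestGenerateRandomDvf:
    def test_zero_amplitude_gives_zero_field(self):
        f = D.generate_random_dvf((32, 32), 0.0, 10.0, seed=1)
        assert np.all(f.u == 0.0)

    def test_jacobian_certificate_against_bruteforce_oracle(self):
        f = D.generate_random_dvf((64, 64), 4.0, 12.0, seed=3)
        # independent per-pixel 2x2 determinant scan via explicit gradients
        u = f.u
        dur_dr, dur_dc = np.gradient(u[..., 0])
        duc_dr, duc_dc = np.gradient(u[..., 1])
        dets = np.empty(u.shape[:2])
        for i in range(u.shape[0]):
            for j in range(u.shape[1]):
                jac = np.array(
                    [[1 + dur_dr[i, j], dur_dc[i, j]], [duc_dr[i, j], 1 + duc_dc[i, j]]]
                )
                dets[i, j] = np.linalg.det(jac)
        assert dets.min() > 0
        assert f.is_topology_preserving()

    def test_determinism_and_seed_sensitivity(self):
        a = D.generate_random_dvf((32, 32), 3.0, 8.0, seed=5)
        b = D.generate_random_dvf((32, 32), 3.0, 8.0, seed=5)
        c = D.generate_random_dvf((32, 32), 3.0, 8.0, seed=6)
        assert np.array_equal(a.u, b.u)
        assert not np.array_equal(a.u, c.u)

    @pytest.mark.parametrize("amplitude", [0.5, 2.0, 5.0])
    def test_max_displacement_never_exceeds_amplitude(self, amplitude):
        f = D.generate_random_dvf((48, 48), amplitude, 6.0, seed=11)
        assert f.max_displacement() <= amplitude + 1e-9

    def test_uncertifiable_field_raises(self):
        # huge amplitude with tiny smoothness folds even after 5 shrinks
        with pytest.raises(GenerationError):
            D.generate_random_dvf((32, 32), 200.0, 1.0, seed=2)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ContractError):
            D.generate_random_dvf((32, 32), -1.0, 5.0, seed=0)
        with pytest.raises(ContractError):
            D.generate_random_dvf((32, 32), 1.0, 0.0, seed=0)


class TestRemoveMeanDisplacement:
    def test_identical_fields_become_zero(self):
        f = random_field((16, 16), 2.0, 0)
        s = D.DVFSet(tuple(D.DVF(f.u.copy()) for _ in range(7)))
        out = D.remove_mean_displacement(s)
        assert out.mean_removed
        for g in out:
            np.testing.assert_allclose(g.u, 0.0, atol=1e-12)

    def test_mean_is_zero_by_direct_summation(self):
        out = D.remove_mean_displacement(random_set(seed=3))
        total = sum(g.u for g in out)
        assert np.abs(total / 7.0).max() < 1e-6

    def test_zero_fields_fixed_point(self):
        s = D.DVFSet(tuple(D.DVF.zero((8, 8)) for _ in range(7)))
        out = D.remove_mean_displacement(s)
        assert out.mean_removed
        for g in out:
            assert np.all(g.u == 0.0)

    def test_idempotent(self):
        once = D.remove_mean_displacement(random_set(seed=9))
        twice = D.remove_mean_displacement(once)
        np.testing.assert_allclose(once.as_array(), twice.as_array(), atol=1e-12)


class TestWarp:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 20))
        out = D.warp(img, D.DVF.zero((20, 20)))
        np.testing.assert_array_equal(out, img)

    def test_integer_shift_equivalence(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        u = np.zeros((16, 16, 2))
        u[..., 1] = 3.0
        out = D.warp(img, u, fill_value=0.0)
        expected = np.zeros_like(img)
        expected[:, :-3] = img[:, 3:]  # index-shift oracle
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_fully_out_of_bounds_gives_fill(self):
        img = np.ones((10, 10))
        u = np.full((10, 10, 2), 100.0)
        out = D.warp(img, u, fill_value=-5.0)
        np.testing.assert_array_equal(out, np.full((10, 10), -5.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            D.warp(np.zeros((8, 8)), D.DVF.zero((9, 9)))

    def test_agrees_with_scipy_map_coordinates(self):
        # dual-route check of the bilinear sampler on interior pixels
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        f = random_field((32, 32), 2.5, 7)
        mine = D.warp(img, f, fill_value=0.0)
        gr, gc = np.meshgrid(np.arange(32.0), np.arange(32.0), indexing="ij")
        ref = map_coordinates(img, [gr + f.u[..., 0], gc + f.u[..., 1]], order=1, cval=0.0)
        np.testing.assert_allclose(mine[4:-4, 4:-4], ref[4:-4, 4:-4], atol=1e-10)

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_image_argument(self, a, b, seed):
        rng = np.random.default_rng(seed)
        i1, i2 = rng.random((2, 12, 12))
        f = random_field((12, 12), 1.5, seed)
        lhs = D.warp(a * i1 + b * i2, f)
        rhs = a * D.warp(i1, f) + b * D.warp(i2, f)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestCompose:
    def test_zero_is_identity_element(self):
        f = random_field((20, 20), 2.0, 4)
        z = D.DVF.zero((20, 20))
        np.testing.assert_allclose(D.compose(z, f).u, f.u, atol=1e-12)
        np.testing.assert_allclose(D.compose(f, z).u, f.u, atol=1e-12)

    def test_constant_fields_add(self):
        a = np.zeros((12, 12, 2)) + [0.7, -0.3]
        b = np.zeros((12, 12, 2)) + [-0.2, 1.1]
        out = D.compose(a, b)
        # closed form for translations: interior samples add exactly
        np.testing.assert_allclose(out.u[2:-2, 2:-2], (a + b)[2:-2, 2:-2], atol=1e-9)

    def test_double_warp_oracle(self):
        # smooth image so double-interpolation error stays below tolerance
        gr, gc = np.meshgrid(np.arange(32.0), np.arange(32.0), indexing="ij")
        img = np.sin(gr / 16.0) * np.cos(gc / 14.0) + 0.02 * gr + 0.01 * gc
        inner = random_field((32, 32), 1.5, 10)
        outer = random_field((32, 32), 1.5, 11)
        direct = D.warp(D.warp(img, outer), inner)
        composed = D.warp(img, D.compose(outer, inner))
        np.testing.assert_allclose(direct[5:-5, 5:-5], composed[5:-5, 5:-5], atol=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            D.compose(D.DVF.zero((8, 8)), D.DVF.zero((10, 10)))


class TestInvert:
    def test_zero_field_self_inverse(self):
        out = D.invert(D.DVF.zero((10, 10)))
        np.testing.assert_array_equal(out.u, 0.0)

    def test_constant_field_negates(self):
        u = np.zeros((16, 16, 2)) + [1.25, -0.75]
        out = D.invert(u)
        np.testing.assert_allclose(out.u[3:-3, 3:-3], -u[3:-3, 3:-3], atol=1e-6)

    def test_composition_residual_small(self):
        f = random_field((48, 48), 3.0, 21)
        v = D.invert(f, tol_px=0.005)
        resid = np.abs(D.compose(f, v).u)[6:-6, 6:-6].max()
        assert resid < 0.05

    def test_invert_twice_is_identity(self):
        f = random_field((48, 48), 3.0, 22)
        back = D.invert(D.invert(f, tol_px=0.002), tol_px=0.002)
        assert np.abs(back.u - f.u)[6:-6, 6:-6].max() < 0.1


class TestDVFSetContracts:
    def test_wrong_count_rejected(self):
        with pytest.raises(ContractError):
            D.DVFSet(tuple(D.DVF.zero((8, 8)) for _ in range(6)))

    def test_mismatched_shapes_rejected(self):
        fields = [D.DVF.zero((8, 8)) for _ in range(6)] + [D.DVF.zero((9, 9))]
        with pytest.raises(ContractError):
            D.DVFSet(tuple(fields))

    def test_non_finite_rejected(self):
        u = np.zeros((8, 8, 2))
        u[0, 0, 0] = np.nan
        with pytest.raises(ContractError):
            D.DVF(u)
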