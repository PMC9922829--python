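"""Vector field, Jacobian variants, augmented system and symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hopfield3 import (
    ControlParams,
    ModelParams,
    augmented_field,
    jacobian_printed,
    jacobian_true,
    mirror,
    vector_field,
)
from hopfield3.model import read_config, write_config

states = st.lists(
    st.floats(-5, 5, allow_nan=False, allow_infinity=False), min_size=3, max_size=3
).map(np.array)


class TestVectorField:
    def test_origin_is_equilibrium_when_unbiased(self, p0):
        assert np.array_equal(vector_field((0, 0, 0), p0), np.zeros(3))

    def test_hand_evaluated_unit_state(self, p0):
        # x=(1,0,0): dx = (-1 + 2 tanh(0.9), 3.6 tanh(0.9), -9 tanh(0.9))
        th = np.tanh(0.9)
        expected = np.array([-1 + 2 * th, 3.6 * th, -9 * th])
        np.testing.assert_allclose(vector_field((1, 0, 0), p0), expected, rtol=1e-12)
        np.testing.assert_allclose(expected, [0.432596, 2.578672, -6.446681], atol=5e-7)

    def test_tabulated_equilibrium_near_zero_field(self, p0):
        f = vector_field((-0.4023, 0.0930, 3.1233), p0)
        assert np.all(np.abs(f) < 5e-4)

    def test_rejects_non_finite_state(self, p0):
        with pytest.raises(ValueError):
            vector_field((np.nan, 0, 0), p0)
        with pytest.raises(ValueError):
            vector_field((np.inf, 0, 0), p0)

    def test_bias_enters_first_component_only(self, p0):
        p = p0.updated(i1=0.4)
        diff = vector_field((0.3, -0.2, 1.0), p) - vector_field((0.3, -0.2, 1.0), p0)
        np.testing.assert_allclose(diff, [0.4, 0, 0], atol=1e-15)


class TestParams:
    def test_defaults_match_standard_weights(self, p0):
        np.testing.assert_array_equal(
            p0.w, [[2, -1.2, 0.48], [3.6, 1.7, 1.076], [-9, 0, 0]]
        )
        np.testing.assert_array_equal(p0.beta, [0.9, 1.7, 1.4])
        assert p0.i1 == 0.0 and p0.c == 1.0 and p0.r == 1.0

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError):
            ModelParams(beta=(0.9, -1.0, 1.4))

    def test_updated_flat_keys(self, p0):
        p = p0.updated(beta2=1.182, w11=2.33, i1=0.001)
        assert p.beta[1] == 1.182 and p.w[0, 0] == 2.33 and p.i1 == 0.001
        assert p0.beta[1] == 1.7  # original untouched
        with pytest.raises(KeyError):
            p0.updated(w44=1.0)

    def test_config_roundtrip(self, p0, tmp_path):
        p = p0.updated(beta2=1.206, w23=1.0, i1=0.4)
        c = ControlParams(phi=0.12, eps=0.5, gamma=8.0)
        path = tmp_path / "model.cfg"
        write_config(path, p, c)
        p2, c2 = read_config(path)
        np.testing.assert_array_equal(p.w, p2.w)
        np.testing.assert_array_equal(p.beta, p2.beta)
        assert p.i1 == p2.i1 and c2 == c


class TestJacobians:
    def test_true_variant_at_origin(self, p0):
        expected = np.array(
            [[0.8, -2.04, 0.672], [3.24, 1.89, 1.5064], [-8.1, 0, -1]]
        )
        np.testing.assert_allclose(jacobian_true((0, 0, 0), p0), expected, atol=1e-12)

    def test_printed_variant_at_origin(self, p0):
        expected = np.array(
            [[0.8, -2.04, 0.672], [3.24, -3.89, 1.5064], [-8.1, 0, -1]]
        )
        np.testing.assert_allclose(jacobian_printed((0, 0, 0), p0), expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(s=states)
    def test_true_matches_finite_differences(self, s):
        p = ModelParams()
        jac = jacobian_true(s, p)
        h = 1e-6
        fd = np.empty((3, 3))
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            fd[:, k] = (vector_field(s + e, p) - vector_field(s - e, p)) / (2 * h)
        np.testing.assert_allclose(jac, fd, rtol=1e-5, atol=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(s=states)
    def test_third_row_depends_on_x1_only(self, s):
        jac = jacobian_true(s, ModelParams())
        assert jac[2, 1] == 0.0 and jac[2, 2] == -1.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(s=states)
    def test_variants_differ_only_in_recurrent_entry(self, s):
        p = ModelParams()
        diff = jacobian_true(s, p) - jacobian_printed(s, p)
        expected_22 = 2 * p.w[1, 1] * p.beta[1] * (1 - np.tanh(p.beta[1] * s[1]) ** 2)
        assert diff[1, 1] == pytest.approx(expected_22, rel=1e-12)
        diff[1, 1] = 0.0
        assert np.all(diff == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(s=states)
    def test_divergence_bounded_above(self, s):
        # trace <= w11*b1 + w22*b2 - 3 since each sech^2 <= 1
        p = ModelParams()
        bound = p.w[0, 0] * p.beta[0] + p.w[1, 1] * p.beta[1] - 3.0
        assert np.trace(jacobian_true(s, p)) <= bound + 1e-12


class TestAugmented:
    def test_decouples_at_zero_coupling(self, p0, rng):
        c = ControlParams(phi=0.0, eps=0.5, gamma=8.0)
        for _ in range(10):
            s = rng.uniform(-2, 2, 4)
            d4 = augmented_field(s, p0, c)
            np.testing.assert_allclose(d4[:3], vector_field(s[:3], p0), atol=1e-15)
            assert d4[3] == pytest.approx(-c.eps * s[3])

    def test_hand_value_at_rest(self, p0):
        c = ControlParams(phi=0.2, eps=0.5, gamma=8.0)
        np.testing.assert_allclose(
            augmented_field((0, 0, 0, 0), p0, c), [0, 0, 0, 1.6], atol=1e-15
        )

    def test_coupling_feeds_second_neuron(self, p0):
        c = ControlParams(phi=0.1, eps=0.5, gamma=8.0)
        d = augmented_field((0, 0, 0, 2.0), p0, c) - augmented_field((0, 0, 0, 0), p0, c)
        np.testing.assert_allclose(d, [0, 0.2, 0, -1.0], atol=1e-15)

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            ControlParams(phi=-0.1)


class TestSymmetry:
    def test_mirror_is_point_reflection(self):
        np.testing.assert_array_equal(mirror((0.1, 0.2, 0.3)), [-0.1, -0.2, -0.3])

    def test_equivariance_unbiased(self, p0, rng):
        # f(-s) = -f(s) for i1 = 0, machine precision, many random states
        s = rng.uniform(-5, 5, (1000, 3))
        for row in s:
            resid = vector_field(mirror(row), p0) + vector_field(row, p0)
            assert np.linalg.norm(resid) < 1e-13

    def test_bias_breaks_equivariance(self, p0):
        p = p0.updated(i1=0.4)
        resid = vector_field(mirror((1, 0, 0)), p) + vector_field((1, 0, 0), p)
        np.testing.assert_allclose(resid, [0.8, 0, 0], atol=1e-14)
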