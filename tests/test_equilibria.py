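"""Scalar equilibrium reduction, root finding and stability classification."""

import numpy as np
import pytest

from hopfield3 import ModelParams, classify, find_equilibria, scalar_residual, vector_field
from hopfield3.equilibria import (
    ReductionDomainError,
    inadmissible_intervals,
    reduce_coordinates,
)


def _x1_values(records):
    return np.array([r.x[0] for r in records])


class TestScalarResidual:
    def test_origin_root_when_unbiased(self, p0):
        assert scalar_residual(0.0, p0) == pytest.approx(0.0, abs=1e-14)

    def test_small_at_tabulated_root(self, p0):
        assert abs(scalar_residual(-0.4023, p0)) < 1e-3

    def test_odd_under_unbiased_reduction(self, p0):
        for x1 in np.linspace(0.01, 0.5, 20):
            assert scalar_residual(-x1, p0) == pytest.approx(-scalar_residual(x1, p0), abs=1e-12)

    def test_domain_error_carries_offending_value(self, p0):
        # far from the origin the artanh argument leaves (-1, 1)
        with pytest.raises(ReductionDomainError) as err:
            scalar_residual(5.5, p0)
        assert abs(err.value.argument) >= 1.0
        assert err.value.x1e == 5.5

    def test_inadmissible_intervals_flank_the_roots(self, p0):
        gaps = inadmissible_intervals(p0)
        assert len(gaps) >= 2
        # the large-|x1| complex-continued region is excluded
        assert any(lo > 0.5 for lo, _ in gaps) and any(hi < -0.5 for _, hi in gaps)


class TestFindEquilibria:
    def test_unbiased_roots_match_tabulated_coordinates(self, p0):
        recs = find_equilibria(p0)
        x1 = _x1_values(recs)
        np.testing.assert_allclose(np.sort(x1), [-0.4023, 0.0, 0.4023], atol=5e-4)
        neg = [r for r in recs if r.x[0] < -0.1][0]
        np.testing.assert_allclose(neg.x, [-0.4023, 0.0930, 3.1233], atol=5e-4)

    def test_residuals_refined_below_tolerance(self, p0):
        for r in find_equilibria(p0):
            assert np.linalg.norm(vector_field(r.x, p0)) < 1e-8

    def test_unbiased_set_closed_under_mirror(self, p0):
        x1 = _x1_values(find_equilibria(p0))
        np.testing.assert_allclose(np.sort(x1), np.sort(-x1), atol=1e-10)

    @pytest.mark.parametrize(
        "i1, expected_x1",
        [(0.4, [-0.5112, 0.0292, 0.2962]), (0.8, [-0.6008, 0.0692, 0.1914])],
    )
    def test_biased_roots(self, p0, i1, expected_x1):
        recs = find_equilibria(p0.updated(i1=i1))
        x1 = np.sort(_x1_values(recs))
        for want in expected_x1:
            assert np.min(np.abs(x1 - want)) < 5e-4

    def test_every_sign_change_has_a_root_and_vice_versa(self, p0):
        # brute-force oracle on a dense grid
        xs = np.linspace(-6, 6, 10_000)
        vals = np.full_like(xs, np.nan)
        for i, x in enumerate(xs):
            try:
                vals[i] = scalar_residual(x, p0)
            except ReductionDomainError:
                pass
        cell = xs[1] - xs[0]
        sign_changes = [
            0.5 * (xs[i] + xs[i + 1])
            for i in range(len(xs) - 1)
            if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0
        ]
        roots = _x1_values(find_equilibria(p0))
        assert len(sign_changes) == len(roots)
        for sc in sign_changes:
            assert np.min(np.abs(roots - sc)) < cell
        for r in roots:
            assert np.min(np.abs(np.array(sign_changes) - r)) < cell

    def test_rejects_sparse_scan(self, p0):
        with pytest.raises(ValueError):
            find_equilibria(p0, n_scan=50)

    def test_bias_asymmetry_grows_monotonically(self, p0):
        # max |S(x) + S(-x)| on a fixed grid grows with the bias current
        grid = np.linspace(0.01, 0.35, 40)
        asym = []
        for i1 in (0.0, 0.4, 0.8):
            p = p0.updated(i1=i1)
            vals = [abs(scalar_residual(x, p) + scalar_residual(-x, p)) for x in grid]
            asym.append(max(vals))
        assert asym[0] < asym[1] < asym[2]


class TestClassify:
    def test_printed_variant_reproduces_published_origin_spectrum(self, p0):
        rec = classify((0, 0, 0), p0, variant="printed")
        lam = rec.eigvals
        real = lam[np.abs(lam.imag) < 1e-9]
        pair = lam[lam.imag > 1e-9]
        assert real[0].real == pytest.approx(0.0182, abs=1e-4)
        assert pair[0].real == pytest.approx(-2.0541, abs=1e-4)
        assert abs(pair[0].imag) == pytest.approx(2.8082, abs=1e-4)
        assert rec.stability == "unstable"

    def test_printed_variant_reproduces_published_nontrivial_spectrum(self, p0):
        eq = [r for r in find_equilibria(p0, variant="printed") if r.x[0] < -0.1][0]
        lam = eq.eigvals
        real = lam[np.abs(lam.imag) < 1e-9]
        pair = lam[lam.imag > 1e-9]
        assert real[0].real == pytest.approx(-0.9959, abs=1e-4)
        assert pair[0].real == pytest.approx(-1.6199, abs=1e-4)
        assert abs(pair[0].imag) == pytest.approx(0.9119, abs=1e-4)
        assert eq.stable

    def test_true_variant_differs_in_stability_verdict(self, p0):
        # under the analytic Jacobian the nontrivial pair is a saddle-focus
        eq = [r for r in find_equilibria(p0, variant="true") if r.x[0] < -0.1][0]
        assert not eq.stable

    @pytest.mark.parametrize("variant", ["true", "printed"])
    def test_spectral_identities(self, p0, variant):
        from hopfield3 import jacobian_printed, jacobian_true

        jac_fn = jacobian_true if variant == "true" else jacobian_printed
        for rec in find_equilibria(p0, variant=variant):
            trace = np.trace(jac_fn(rec.x, p0))
            assert rec.eigvals.sum().real == pytest.approx(trace, abs=1e-8)
            assert abs(rec.eigvals.sum().imag) < 1e-8
            # characteristic polynomial reproduces the eigenvalues
            np.testing.assert_allclose(
                np.sort_complex(np.roots(rec.charpoly)), np.sort_complex(rec.eigvals),
                atol=1e-8,
            )

    def test_mirrored_equilibria_share_spectra_when_unbiased(self, p0):
        for variant in ("true", "printed"):
            recs = find_equilibria(p0, variant=variant)
            neg = [r for r in recs if r.x[0] < -0.1][0]
            pos = [r for r in recs if r.x[0] > 0.1][0]
            np.testing.assert_allclose(
                np.sort_complex(neg.eigvals), np.sort_complex(pos.eigvals), atol=1e-8
            )

    def test_rejects_non_equilibrium_point(self, p0):
        with pytest.raises(ValueError):
            classify((1.0, 1.0, 1.0), p0)

    def test_reduce_coordinates_satisfies_full_system(self, p0):
        p = p0.updated(i1=0.4)
        for r in find_equilibria(p):
            x = reduce_coordinates(r.x[0], p)
            assert np.linalg.norm(vector_field(x, p)) < 1e-8
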