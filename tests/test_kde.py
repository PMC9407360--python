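import math

import numpy as np
import pytest
from scipy import integrate

from albtest import (
    CombinedSample,
    build_kernel_matrix,
    gaussian_kernel,
    hall_kernel,
    kde_eval,
    kde_eval_bivariate,
    loo_log_density,
    loo_log_density_reflected,
    reflect_unit_square,
    student_t_kernel,
)

PHI0 = 0.3989422804014327
PHI1 = 0.24197072451914337


class TestKdeEval:
    def test_single_point_equals_kernel(self):
        assert kde_eval(0.0, 1.0, [0.0], gaussian_kernel()) == pytest.approx(PHI0)

    def test_two_point_average(self):
        # (phi(1) + phi(-1)) / 2 = phi(1)
        assert kde_eval(1.0, 1.0, [0.0, 2.0], gaussian_kernel()) == pytest.approx(PHI1)

    @pytest.mark.parametrize("h", [0.3, 1.0, 4.0])
    def test_scale_equivariance(self, rng, h):
        pts = rng.standard_normal(7)
        u = 0.4
        direct = kde_eval(u, h, pts, hall_kernel())
        rescaled = kde_eval(u / h, 1.0, pts / h, hall_kernel()) / h
        assert direct == pytest.approx(rescaled, rel=1e-12)

    def test_log_variant_matches(self, rng):
        pts = rng.standard_normal(5)
        val = kde_eval(0.2, 0.5, pts, hall_kernel())
        assert kde_eval(0.2, 0.5, pts, hall_kernel(), log=True) == pytest.approx(
            math.log(val)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            kde_eval(0.0, 0.0, [0.0], gaussian_kernel())
        with pytest.raises(ValueError, match="at least one"):
            kde_eval(0.0, 1.0, [], gaussian_kernel())


class TestBivariateKde:
    def test_single_point_is_kernel_product(self):
        val = kde_eval_bivariate((0.0, 0.0), 1.0, 1.0, [(0.0, 0.0)], gaussian_kernel())
        assert val == pytest.approx(PHI0**2)  # 0.1591549

    def test_product_of_univariate_values(self):
        u, pt = (0.3, -0.2), (0.1, 0.4)
        val = kde_eval_bivariate(u, 0.7, 1.3, [pt], student_t_kernel(3.0))
        want = kde_eval(u[0], 0.7, [pt[0]], student_t_kernel(3.0)) * kde_eval(
            u[1], 1.3, [pt[1]], student_t_kernel(3.0)
        )
        assert val == pytest.approx(want, rel=1e-12)

    def test_coordinate_swap_invariance(self, rng):
        pts = rng.random((6, 2))
        u = np.array([0.5, 0.2])
        a = kde_eval_bivariate(u, 0.4, 0.9, pts, gaussian_kernel())
        b = kde_eval_bivariate(u[::-1], 0.9, 0.4, pts[:, ::-1], gaussian_kernel())
        assert a == pytest.approx(b, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kde_eval_bivariate((0.0, 0.0), 1.0, 1.0, [(0.0,)], gaussian_kernel())


class TestCombinedSample:
    def test_labels_and_groups(self):
        s = CombinedSample.from_groups([0.0, 1.0, 2.0], [3.0, 4.0])
        assert s.m == 3 and s.n == 2 and s.size == 5
        assert s.labels.tolist() == [True, True, True, False, False]
        np.testing.assert_array_equal(s.x, [0.0, 1.0, 2.0])

    @pytest.mark.parametrize("m,n", [(1, 5), (5, 1)])
    def test_singleton_group_rejected(self, m, n):
        with pytest.raises(ValueError, match="at least 2"):
            CombinedSample.from_groups(np.zeros(m), np.ones(n))


class TestKernelMatrix:
    def test_two_point_off_diagonal(self):
        s = CombinedSample.from_groups([0.0, 1.0], [0.0, 1.0])
        mat = build_kernel_matrix(s, 1.0, gaussian_kernel())
        assert math.exp(mat.log_entries[0, 1]) == pytest.approx(PHI1)

    def test_symmetry_and_label_blindness(self, rng):
        z = rng.standard_normal(9)
        a = build_kernel_matrix(CombinedSample(z, 4, 5), 0.6, hall_kernel())
        b = build_kernel_matrix(CombinedSample(z, 6, 3), 0.6, hall_kernel())
        np.testing.assert_array_equal(a.log_entries, b.log_entries)
        le = a.log_entries
        np.testing.assert_allclose(le, le.T)
        assert np.all(np.isneginf(np.diag(le)))
        off = ~np.eye(9, dtype=bool)
        assert np.all(np.isfinite(le[off]))

    def test_loo_equals_direct_kde(self, rng, any_kernel):
        """Matrix LOO log-density == explicit leave-one-out kde (oracle)."""
        z = rng.standard_normal(8)
        s = CombinedSample(z, 4, 4)
        mat = build_kernel_matrix(s, 0.45, any_kernel)
        full = np.ones(8, dtype=bool)
        for i in range(8):
            rest = np.delete(z, i)
            want = kde_eval(z[i], 0.45, rest, any_kernel, log=True)
            assert loo_log_density(i, full, mat) == pytest.approx(want, abs=1e-10)
        # and on a proper subset
        subset = np.array([True, True, True, False, True, False, False, True])
        rest = z[np.flatnonzero(subset & (np.arange(8) != 1))]
        want = kde_eval(z[1], 0.45, rest, any_kernel, log=True)
        assert loo_log_density(1, subset, mat) == pytest.approx(want, abs=1e-10)

    def test_loo_decreases_with_far_point(self):
        z = np.array([0.0, 0.1, 0.2, 50.0])
        s = CombinedSample(z, 2, 2)
        mat = build_kernel_matrix(s, 1.0, gaussian_kernel())
        near = np.array([True, True, True, False])
        with_far = np.ones(4, dtype=bool)
        assert loo_log_density(0, with_far, mat) < loo_log_density(0, near, mat)

    def test_empty_subset_rejected(self):
        s = CombinedSample.from_groups([0.0, 1.0], [2.0, 3.0])
        mat = build_kernel_matrix(s, 1.0, gaussian_kernel())
        only_self = np.array([True, False, False, False])
        with pytest.raises(ValueError, match="empty"):
            loo_log_density(0, only_self, mat)


class TestReflection:
    def test_reflection_rule(self):
        aug, idx = reflect_unit_square([(0.2, 0.3)])
        np.testing.assert_allclose(
            aug, [(0.2, 0.3), (0.2, -0.3), (-0.2, -0.3), (-0.2, 0.3)]
        )
        assert idx.shape == (1, 4)

    def test_origin_fixed_point_and_count(self, rng):
        aug, _ = reflect_unit_square([(0.0, 0.0)])
        np.testing.assert_array_equal(aug, np.zeros((4, 2)))
        pts = rng.random((7, 2))
        aug, idx = reflect_unit_square(pts)
        assert aug.shape == (28, 2) and idx.shape == (7, 4)

    def test_outside_unit_square_rejected(self):
        with pytest.raises(ValueError, match="unit square"):
            reflect_unit_square([(1.2, 0.5)])

    def test_reflected_matches_plain_for_interior_data(self, rng):
        pts = 0.4 + 0.2 * rng.random((8, 2))  # well inside [0,1]^2
        s = CombinedSample(pts, 4, 4)
        plain = build_kernel_matrix(s, (0.02, 0.02), gaussian_kernel())
        full = np.ones(8, dtype=bool)
        for i in range(8):
            a = loo_log_density_reflected(i, full, s, 0.02, 0.02, gaussian_kernel())
            b = loo_log_density(i, full, plain)
            assert a == pytest.approx(b, abs=1e-6)

    def test_coincident_origin_reflections(self):
        """All 4 reflected copies of a point at the origin coincide."""
        pts = np.zeros((4, 2))
        s = CombinedSample(pts, 2, 2)
        mat = build_kernel_matrix(s, (0.5, 0.7), gaussian_kernel(), reflect=True)
        want = 4.0 * gaussian_kernel()(0.0) ** 2 / (0.5 * 0.7)
        assert math.exp(mat.log_entries[0, 1]) == pytest.approx(want, rel=1e-12)

    def test_corrected_estimate_integrates_to_one(self):
        """4 x (kde from reflected copies) has unit mass on the unit square."""
        pts = np.array([[0.05, 0.3], [0.4, 0.02], [0.25, 0.45], [0.1, 0.1]])
        aug, _ = reflect_unit_square(pts)
        b1 = b2 = 0.04

        def corrected(y, x):
            return 4.0 * kde_eval_bivariate((x, y), b1, b2, aug, gaussian_kernel())

        total, _ = integrate.dblquad(corrected, 0, 1, 0, 1, epsabs=1e-7)
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_reflected_loo_matches_brute_force(self, rng):
        """Matrix path equals the explicit 4x-augmented evaluation."""
        from conftest import brute_force_alb
        from albtest import alb_statistic

        pts = rng.random((10, 2))
        s = CombinedSample(pts, 5, 5)
        res = alb_statistic(s, (0.15, 0.2), student_t_kernel(3.0), reflect=True)
        want, want_bf = brute_force_alb(
            s, (0.15, 0.2), student_t_kernel(3.0), reflect=True
        )
        assert res.alb == pytest.approx(want, abs=1e-10)
        np.testing.assert_allclose(res.log_bf, want_bf, atol=1e-10)

    def test_reflection_needs_bivariate(self):
        s = CombinedSample.from_groups([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match="bivariate"):
            build_kernel_matrix(s, 0.1, gaussian_kernel(), reflect=True)
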