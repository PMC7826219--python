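import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choroidseg import lqfit
from choroidseg.lqfit import (
    DesignMatrix,
    build_design_matrix,
    fit_l2lq,
    lower_bound,
    omp_init,
    phi,
    phi_smooth,
    purify,
    select_degree,
    sg_refine,
    smoothing_grad,
    smoothing_value,
)


def one_d_problem(yv):
    return DesignMatrix(X=np.array([[1.0]]), y=np.array([float(yv)]),
                        degree=0, center=0.0, halfwidth=1.0)


class TestSelectDegree:
    # thresholds are on 1-based columns 1..600
    @pytest.mark.parametrize(
        "x1, xm, expected",
        [(10, 590, 10), (120, 480, 3), (60, 560, 6), (50, 570, 10),
         (100, 590, 3), (10, 500, 3), (51, 569, 6)],
    )
    def test_printed_rules(self, x1, xm, expected):
        xs = np.array([x1, (x1 + xm) // 2, xm], dtype=float)
        assert select_degree(xs, one_based=True) == expected

    def test_zero_based_columns_shifted(self):
        # 0-based column 49 is 1-based column 50
        assert select_degree(np.array([49, 300, 569]), one_based=False) == 10

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_degree(np.array([]))


class TestDesignMatrix:
    def test_shape_and_ones_column(self):
        dm = build_design_matrix(np.array([0.0, 10, 20, 30]), np.zeros(4), 3)
        assert dm.X.shape == (4, 4)
        assert np.all(dm.X[:, -1] == 1.0)

    def test_symmetric_points_scale_symmetrically(self):
        x = np.array([100.0, 200.0, 400.0, 500.0])
        dm = build_design_matrix(x, np.zeros(4), 3)
        t = dm.scale(x)
        assert np.allclose(t, -t[::-1])
        assert t.min() == -1.0 and t.max() == 1.0

    def test_degree_ten_design_is_well_conditioned(self):
        x = np.arange(600, dtype=float)
        dm = build_design_matrix(x, np.zeros(600), 10)
        assert np.isfinite(np.linalg.cond(dm.X))
        assert np.linalg.cond(dm.X) < 1e6

    def test_too_few_points_instructs_degree_reduction(self):
        with pytest.raises(ValueError, match="reduce the degree"):
            build_design_matrix(np.arange(5.0), np.zeros(5), 10)


class TestSmoothing:
    def test_value_at_zero_is_half_xi(self):
        assert smoothing_value(0.0, 0.2) == pytest.approx(0.1)

    def test_linear_branch_equals_absolute_value(self):
        for xi in (0.05, 0.1, 1.0):
            assert smoothing_value(2 * xi, xi) == pytest.approx(2 * xi)
            assert smoothing_value(-2 * xi, xi) == pytest.approx(2 * xi)

    def test_branches_and_derivatives_agree_at_seam(self):
        xi = 0.1
        quad = xi**2 / (2 * xi) + xi / 2
        assert quad == pytest.approx(xi)  # value continuity at |t| = xi
        assert smoothing_grad(xi, xi) == pytest.approx(1.0)  # t/xi -> 1
        assert smoothing_grad(-xi, xi) == pytest.approx(-1.0)

    @settings(max_examples=100, deadline=None)
    @given(t=st.floats(-50, 50), xi=st.floats(0.01, 2.0))
    def test_majorizes_absolute_value(self, t, xi):
        s = smoothing_value(t, xi)
        assert s >= abs(t) - 1e-12
        if abs(t) >= xi:
            assert s == pytest.approx(abs(t))

    def test_nonpositive_xi_rejected(self):
        with pytest.raises(ValueError):
            smoothing_value(1.0, 0.0)


class TestOMP:
    def test_single_atom_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = 3.0 * X[:, 2]
        dm = DesignMatrix(X=X, y=y, degree=4, center=0, halfwidth=1)
        beta, sup = omp_init(dm)
        assert sup == [2]
        assert beta[2] == pytest.approx(3.0)
        assert np.linalg.norm(X @ beta - y) < 1e-9

    def test_two_atom_recovery_on_orthonormal_columns(self):
        Q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(30, 6)))
        y = 2.0 * Q[:, 1] + 1.0 * Q[:, 4]
        dm = DesignMatrix(X=Q, y=y, degree=5, center=0, halfwidth=1)
        beta, sup = omp_init(dm)
        assert set(sup) == {1, 4}
        assert beta[1] == pytest.approx(2.0) and beta[4] == pytest.approx(1.0)

    def test_cap_zero_returns_zero_vector(self):
        dm = one_d_problem(2.0)
        beta, sup = omp_init(dm, cap=0)
        assert sup == [] and np.all(beta == 0)


class TestSG:
    def test_stationary_point_returned_unchanged(self):
        dm = one_d_problem(0.0)
        beta = sg_refine(dm, np.array([0.0]), 1.0, 0.1, 0.1)
        assert beta[0] == pytest.approx(0.0)

    def test_one_dimensional_descent_matches_grid_oracle(self):
        dm = one_d_problem(2.0)
        beta = sg_refine(dm, np.array([2.0]), lam=1.0, q=0.1, xi=0.1)
        grid = np.concatenate([np.arange(-3, 3, 1e-4), [0.0]])
        oracle = np.min((grid - 2.0) ** 2 + np.abs(grid) ** 0.1)
        assert phi(dm, beta, 1.0, 0.1) <= oracle + 1e-3
        assert beta[0] == pytest.approx(1.974, abs=2e-3)

    def test_smoothed_objective_never_increases(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        dm = DesignMatrix(X=X, y=y, degree=5, center=0, halfwidth=1)
        beta0 = rng.normal(size=6)
        beta = sg_refine(dm, beta0, 1.0, 0.1, 0.1)
        assert phi_smooth(dm, beta, 1.0, 0.1, 0.1) <= phi_smooth(dm, beta0, 1.0, 0.1, 0.1) + 1e-12

    def test_invalid_parameters_rejected(self):
        dm = one_d_problem(1.0)
        with pytest.raises(ValueError):
            sg_refine(dm, np.array([1.0]), lam=-1.0, q=0.1, xi=0.1)
        with pytest.raises(ValueError):
            sg_refine(dm, np.array([1.0]), lam=1.0, q=1.5, xi=0.1)


class TestLowerBound:
    def test_printed_constant_example(self):
        L, _ = lower_bound(np.array([[1.0]]), lam=1.0, q=0.1, phi0=1.0)
        assert L == pytest.approx(0.05 ** (1 / 0.9), rel=1e-12)
        assert L == pytest.approx(0.0358, abs=5e-4)

    def test_vanishes_as_q_approaches_one(self):
        X = np.array([[1.0]])
        Ls = [lower_bound(X, 1.0, q, 4.0)[0] for q in (0.5, 0.9, 0.99)]
        assert Ls[0] > Ls[1] > Ls[2]
        assert Ls[2] < 1e-10

    def test_monotone_in_lambda(self):
        X = np.random.default_rng(3).normal(size=(30, 5))
        Ls = [lower_bound(X, lam, 0.1, 10.0)[0] for lam in (0.5, 1.0, 2.0)]
        assert Ls[0] < Ls[1] < Ls[2]

    def test_exact_fit_special_case(self):
        L, bound = lower_bound(np.array([[1.0]]), 1.0, 0.1, 0.0)
        assert np.isinf(L) and bound == 0.0


class TestPurify:
    @settings(max_examples=60, deadline=None)
    @given(
        beta=st.lists(st.floats(-10, 10), min_size=1, max_size=12),
        L=st.floats(0.0, 5.0),
    )
    def test_thresholds_exactly(self, beta, L):
        beta = np.array(beta)
        out = purify(beta, L)
        for b_in, b_out in zip(beta, out):
            assert b_out == (0.0 if abs(b_in) <= L else b_in)

    def test_idempotent(self):
        beta = np.array([0.01, -5.0, 0.2, 0.0])
        assert np.array_equal(purify(purify(beta, 0.1), 0.1), purify(beta, 0.1))


class TestFit:
    def test_noise_free_cubic_through_degree_ten_basis(self):
        x = np.arange(0, 600, 2.0)
        y = 100.0 + 10.0 * ((x - 300.0) / 300.0) ** 3
        fr = fit_l2lq(x, y, degree=10)
        pred = fr(np.arange(600))
        truth = 100.0 + 10.0 * ((np.arange(600) - 300.0) / 300.0) ** 3
        assert len(fr.support) <= 4
        assert np.max(np.abs(pred - truth)) <= 0.5

    def test_sparse_support_recovered_under_noise(self):
        rs = np.random.default_rng(0)
        x = np.sort(rs.choice(600, size=400, replace=False)).astype(float)
        t = (x - (x.min() + x.max()) / 2) / ((x.max() - x.min()) / 2)
        y = 20 * t**5 + 30 * t**2 + 100 + rs.normal(0, 1, size=400)
        fr = fit_l2lq(x, y, degree=10)
        assert set(fr.support.tolist()) == {5, 8, 10}  # x^5, x^2, 1 (descending powers)

    def test_interpolation_in_the_small_lambda_limit(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.choice(600, size=4, replace=False)).astype(float)
        y = rng.uniform(60, 120, size=4)
        fr = fit_l2lq(x, y, lam=1e-10, degree=3)
        assert np.max(np.abs(fr(x) - y)) < 1e-5

    def test_theorem_invariants_hold_on_random_problems(self):
        for seed in range(15):
            rng = np.random.default_rng(2000 + seed)
            n = int(rng.integers(1, 11))
            m = int(rng.integers(n + 1, 200))
            x = np.sort(rng.uniform(0, 600, size=m))
            y = 80 + 30 * np.sin(x / 150) + rng.normal(0, 2, size=m)
            fr = fit_l2lq(x, y, degree=n)
            nz = np.abs(fr.beta[fr.support])
            assert fr.objective <= fr.phi0 + 1e-9
            if nz.size:
                assert nz.min() > fr.L
            assert len(fr.support) <= fr.support_bound + 1e-9

    def test_degree_rule_used_when_unspecified(self):
        x = np.linspace(0, 599, 300)
        y = 90 + 0.01 * x
        fr = fit_l2lq(x, y)
        assert fr.degree == 10  # x spans both borders

    def test_serialization_round_trip(self, tmp_path):
        x = np.linspace(0, 599, 50)
        fr = fit_l2lq(x, 90 + 0.01 * x, degree=3)
        fr.to_json(tmp_path / "fit.json")
        import json

        data = json.loads((tmp_path / "fit.json").read_text())
        assert data["degree"] == 3
        assert np.allclose(data["beta_scaled_desc"], fr.beta)
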