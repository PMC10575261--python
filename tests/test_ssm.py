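"""State-space core: construction formulas, discretization, and the
recurrent-vs-convolutional equivalence oracle."""
import numpy as np
import pytest

from ecgdiff.ssm import (DiscreteSSM, SSMParams, build_hippo, discretize,
                         hippo_matrix, ssm_apply_conv, ssm_apply_recurrent)


def _hippo_reference(N, form):
    """Independent element-by-element evaluation of the printed formulas."""
    A = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                ds = 0.5 if form == "printed" else -0.5
            elif i > j:
                ds = -np.sqrt((i + 0.5) * (j + 0.5))
            else:
                ds = -np.sqrt((i + 0.5) * (j + 0.5)) if form == "printed" \
                    else np.sqrt((i + 0.5) * (j + 0.5))
            A[i, j] = ds - np.sqrt(i + 0.5) * np.sqrt(j + 0.5)
    B = np.array([np.sqrt(2 * i + 1) for i in range(N)])
    return A, B


class TestBuildHippo:
    def test_n1_scalar_case(self):
        # P_0 = sqrt(1/2), B_0 = 1, A_00 = 1/2 - 1/2 = 0
        p = build_hippo(1)
        assert p.A[0, 0] == pytest.approx(0.0)
        assert p.B[0] == pytest.approx(1.0)

    def test_n2_input_map(self):
        p = build_hippo(2)
        np.testing.assert_allclose(p.B, [1.0, np.sqrt(3)])

    @pytest.mark.parametrize("form", ["printed", "legs"])
    @pytest.mark.parametrize("N", [2, 4, 7])
    def test_full_matrix_against_reference(self, N, form):
        A, B = hippo_matrix(N, form=form)
        A_ref, B_ref = _hippo_reference(N, form)
        np.testing.assert_allclose(A, A_ref, atol=1e-14)
        np.testing.assert_allclose(B, B_ref, atol=1e-14)

    def test_legs_form_is_the_legs_matrix(self):
        # A = A^(ds) - P Pᵀ collapses to the lower-triangular LegS matrix
        N = 5
        A, _ = hippo_matrix(N, form="legs")
        expected = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                if i > j:
                    expected[i, j] = -np.sqrt((2 * i + 1) * (2 * j + 1))
                elif i == j:
                    expected[i, j] = -(i + 1)
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_seeded_c_reproducible(self):
        assert np.array_equal(build_hippo(4, seed=9).C, build_hippo(4, seed=9).C)
        assert not np.array_equal(build_hippo(4, seed=9).C,
                                  build_hippo(4, seed=10).C)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            build_hippo(0)

    def test_d_defaults_to_zero(self):
        assert build_hippo(3).D == 0.0


class TestDiscretize:
    def test_zero_matrix(self, rng):
        N, delta = 3, 0.37
        B = rng.standard_normal(N)
        p = SSMParams(A=np.zeros((N, N)), B=B, C=rng.standard_normal(N),
                      delta=delta)
        d = discretize(p, L=4)
        np.testing.assert_allclose(d.A_bar, np.eye(N), atol=1e-14)
        np.testing.assert_allclose(d.B_bar, delta * B, atol=1e-14)

    @pytest.mark.parametrize("a,delta", [(-1.0, 0.1), (0.5, 0.01), (-3.0, 0.05)])
    def test_scalar_closed_form(self, a, delta):
        p = SSMParams(A=np.array([[a]]), B=np.ones(1), C=np.ones(1),
                      delta=delta)
        d = discretize(p, L=2)
        assert d.A_bar[0, 0] == pytest.approx(
            (1 + delta * a / 2) / (1 - delta * a / 2), abs=1e-14)

    def test_random_system_against_explicit_inverse(self, rng):
        N, delta = 3, 0.07
        A = rng.standard_normal((N, N))
        B = rng.standard_normal(N)
        p = SSMParams(A=A, B=B, C=rng.standard_normal(N), delta=delta)
        d = discretize(p, L=5)
        Minv = np.linalg.inv(np.eye(N) - delta / 2 * A)
        np.testing.assert_allclose(
            d.A_bar, Minv @ (np.eye(N) + delta / 2 * A), atol=1e-10)
        np.testing.assert_allclose(d.B_bar, Minv @ (delta * B), atol=1e-10)

    def test_c_passes_through(self, rng):
        p = build_hippo(4, seed=3)
        np.testing.assert_array_equal(discretize(p, 8).C_bar, p.C)

    def test_singular_raises_with_delta_in_message(self):
        p = SSMParams(A=np.array([[2.0]]), B=np.ones(1), C=np.ones(1),
                      delta=1.0)  # I - (1/2)*2 = 0
        with pytest.raises(np.linalg.LinAlgError, match="delta=1.0"):
            discretize(p, L=2)

    def test_kernel_matches_matrix_powers(self, rng):
        p = build_hippo(4, delta=0.05, seed=1, form="legs")
        d = discretize(p, L=10)
        for k in range(10):
            expected = d.C_bar @ np.linalg.matrix_power(d.A_bar, k) @ d.B_bar
            assert d.K_bar[k] == pytest.approx(expected, abs=1e-10)


def _random_stable_system(rng, N, L):
    A = rng.standard_normal((N, N))
    A = A - (np.abs(np.linalg.eigvals(A)).max() + 0.5) * np.eye(N)  # shift left
    p = SSMParams(A=A, B=rng.standard_normal(N), C=rng.standard_normal(N),
                  delta=float(rng.uniform(0.01, 0.3)))
    return discretize(p, L)


class TestApply:
    def test_zero_input(self, rng):
        d = _random_stable_system(rng, 4, 12)
        np.testing.assert_array_equal(ssm_apply_recurrent(d, np.zeros(12)),
                                      np.zeros(12))

    def test_impulse_returns_kernel(self, rng):
        d = _random_stable_system(rng, 5, 16)
        u = np.zeros(16)
        u[0] = 1.0
        np.testing.assert_allclose(ssm_apply_recurrent(d, u), d.K_bar,
                                   atol=1e-12)
        np.testing.assert_allclose(ssm_apply_conv(d, u), d.K_bar, atol=1e-9)

    def test_recurrent_matches_expanded_sum(self, rng):
        # y_k = C̄Ā^k B̄ u_0 + ... + C̄B̄ u_k, term by term
        d = _random_stable_system(rng, 4, 16)
        u = rng.standard_normal(16)
        y = ssm_apply_recurrent(d, u)
        for k in range(16):
            expected = sum(
                (d.C_bar @ np.linalg.matrix_power(d.A_bar, k - j) @ d.B_bar)
                * u[j] for j in range(k + 1))
            assert y[k] == pytest.approx(expected, abs=1e-9)

    def test_scalar_geometric_sum(self):
        d = DiscreteSSM(A_bar=np.array([[0.5]]), B_bar=np.array([2.0]),
                        C_bar=np.array([3.0]), L=8)
        u = np.arange(8.0)
        y = ssm_apply_conv(d, u)
        expected = [sum(3.0 * 0.5 ** (k - j) * 2.0 * u[j]
                        for j in range(k + 1)) for k in range(8)]
        np.testing.assert_allclose(y, expected, atol=1e-10)

    def test_oracle_equivalence_100_systems(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            N = int(rng.integers(1, 9))
            L = int(rng.integers(4, 65))
            d = _random_stable_system(rng, N, L)
            assert np.abs(np.linalg.eigvals(d.A_bar)).max() < 1
            u = rng.standard_normal(L)
            diff = np.abs(ssm_apply_conv(d, u)
                          - ssm_apply_recurrent(d, u)).max()
            worst = max(worst, diff)
        assert worst < 1e-6

    def test_linearity(self, rng):
        d = _random_stable_system(rng, 4, 24)
        u, v = rng.standard_normal(24), rng.standard_normal(24)
        a, b = 1.7, -0.4
        lhs = ssm_apply_conv(d, a * u + b * v)
        rhs = a * ssm_apply_conv(d, u) + b * ssm_apply_conv(d, v)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_length_mismatch(self, rng):
        d = _random_stable_system(rng, 3, 8)
        with pytest.raises(ValueError):
            ssm_apply_recurrent(d, np.zeros(9))
        with pytest.raises(ValueError):
            ssm_apply_conv(d, np.zeros(7))

    def test_feedthrough_adds_du(self, rng):
        d = _random_stable_system(rng, 3, 8)
        u = rng.standard_normal(8)
        base = ssm_apply_recurrent(d, u)
        d.D = 2.5
        np.testing.assert_allclose(ssm_apply_recurrent(d, u), base + 2.5 * u,
                                   atol=1e-12)


class TestStability:
    @pytest.mark.parametrize("delta", [1e-3, 1e-2, 1e-1])
    def test_legs_kernel_finite_to_1024(self, delta):
        p = build_hippo(16, delta=delta, seed=0, form="legs")
        d = discretize(p, L=1024)
        assert np.isfinite(d.K_bar).all()

    def test_printed_form_unstable_as_documented(self):
        # the literal printed construction has unstable spectrum for N >= 2;
        # documented behavior, which is why the neural layers use "legs"
        A, _ = hippo_matrix(8, form="printed")
        assert np.linalg.eigvals(A).real.max() > 0
        A_legs, _ = hippo_matrix(8, form="legs")
        assert np.linalg.eigvals(A_legs).real.max() < 0
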