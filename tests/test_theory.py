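"""Rate matrix, drift, stationary profiles, null spaces, and the
exhaustive-enumeration oracles validating the closed-form drift."""

import itertools

import numpy as np
import pytest

from smtr import (
    AutocorrelationProfile,
    CircularSequence,
    MutationModel,
    build_rate_matrix,
    circular_autocorrelation,
    drift,
    duplication_period,
    lag_class_vector,
    null_space_basis,
    oracle_duplication_drift,
    oracle_substitution_drift,
    stationary_profile,
)


def model_from(pairs, size):
    q = np.zeros(size)
    for i, p in pairs:
        q[i] = p
    return MutationModel(q)


class TestRateMatrix:
    def test_row_zero_is_zero(self, rng):
        m = model_from([(0, 0.3), (2, 0.7)], 3)
        assert not build_rate_matrix(m, 8).A[0].any()

    def test_hand_computed_entries(self):
        A = build_rate_matrix(MutationModel([0.2, 0.8]), 3).A
        expected = [
            [0.0, 0.0, 0.0],
            [0.93333, -1.33333, 0.0],
            [0.13333, 1.6, -2.13333],
        ]
        np.testing.assert_allclose(A, expected, atol=1e-5)

    def test_pure_substitution_structure(self):
        # q0 = 1: every row r > 0 reads 2/3 in column 0, -8/3 on the
        # diagonal, zero elsewhere, so the fixed point is rho = 1/4
        A = build_rate_matrix(MutationModel([1.0]), 5).A
        for r in range(1, 5):
            assert A[r, 0] == pytest.approx(2 / 3)
            assert A[r, r] == pytest.approx(-8 / 3)
            off = [A[r, j] for j in range(1, 5) if j != r]
            assert np.allclose(off, 0.0)

    def test_m_too_small(self):
        with pytest.raises(ValueError):
            build_rate_matrix(MutationModel([1.0]), 1)


class TestDrift:
    def test_constant_profile_pure_substitution(self):
        rho = AutocorrelationProfile(np.ones(5))
        np.testing.assert_allclose(drift(MutationModel([1.0]), rho)[1:], -2.0)

    def test_iid_profile_is_substitution_fixed_point(self):
        rho = AutocorrelationProfile(np.r_[1.0, np.full(6, 0.25)])
        np.testing.assert_allclose(drift(MutationModel([1.0]), rho), 0.0,
                                   atol=1e-12)

    def test_drift_equals_rate_matrix_product(self, rng):
        # Algebraic identity between the componentwise ODE and A rho,
        # for random models and random valid profiles with rho^0 = 1
        for _ in range(25):
            size = int(rng.integers(2, 9))
            q = rng.dirichlet(np.ones(size))
            m = MutationModel(q)
            mm = int(rng.integers(m.K + 1, m.K + 8))
            if mm < 2:
                mm = 2
            rho = AutocorrelationProfile(
                np.r_[1.0, rng.uniform(0, 1, mm - 1)]
            )
            np.testing.assert_allclose(
                drift(m, rho), build_rate_matrix(m, mm).A @ rho.rho, atol=1e-12
            )


class TestOracles:
    def test_substitution_oracle_constant_sequence(self):
        d = oracle_substitution_drift(CircularSequence("AAAAAA"), 3)
        assert d[1] == pytest.approx(-2.0)
        assert d[2] == pytest.approx(-2.0)

    def test_substitution_oracle_period_four(self):
        d = oracle_substitution_drift(CircularSequence("ACGTACGT"), 5)
        assert d[4] == pytest.approx(-2.0)

    def test_substitution_oracle_exact_closed_form(self, rng):
        # closed form -8/3 rho^r + 2/3 matches enumeration exactly,
        # including the boundary lag r = L/2
        for L in (5, 6, 9, 12):
            s = CircularSequence.from_codes(rng.integers(0, 4, L))
            rho = circular_autocorrelation(s, L).rho
            got = oracle_substitution_drift(s, L)
            np.testing.assert_allclose(
                got[1:], -8 / 3 * rho[1:] + 2 / 3, atol=1e-12
            )

    def test_duplication_oracle_constant_sequence(self):
        d = oracle_duplication_drift(CircularSequence("AAAAAAA"), 3, 4)
        np.testing.assert_allclose(d, 3.0, atol=1e-12)

    def test_duplication_oracle_period_two(self):
        d = oracle_duplication_drift(CircularSequence("ACAC"), 2, 3)
        assert d[2] == pytest.approx(2.0)

    def test_duplication_oracle_matches_closed_form(self, rng):
        # |enumeration - (r rho^{r-l} - r rho^r + l rho^r)| <= c/L; the
        # measured error is in fact at the floating-point floor: the
        # identity holds exactly on the unnormalized counts, the O(1/L)
        # remainder arising only from the length normalization
        for L in (20, 40, 80):
            worst = 0.0
            for _ in range(5):
                s = CircularSequence.from_codes(rng.integers(0, 4, L))
                rho = circular_autocorrelation(s, L)
                for ell in (1, 3):
                    got = oracle_duplication_drift(s, ell, 8)
                    pred = np.array(
                        [
                            r * rho.at(r - ell) - r * rho.at(r)
                            + ell * rho.at(r)
                            for r in range(8)
                        ]
                    )
                    worst = max(worst, np.max(np.abs(got - pred)))
            assert worst <= 12.0 / L
            assert worst < 1e-12

    def test_oracle_preconditions(self):
        with pytest.raises(ValueError):
            oracle_substitution_drift(CircularSequence("AC"), 2)
        with pytest.raises(ValueError):
            oracle_duplication_drift(CircularSequence("ACGT"), 5, 2)


class TestStationaryProfile:
    def test_hand_solved_two_by_two(self):
        rho = stationary_profile(MutationModel([0.2, 0.8]), 3)
        np.testing.assert_allclose(rho.rho, [1.0, 0.7, 0.5875], atol=1e-9)

    def test_off_period_lags_are_quarter(self, rng):
        # with q0 > 0 and support on multiples of d, every entry at a lag
        # not divisible by d equals the i.i.d. value 1/4
        for _ in range(50):
            d = int(rng.integers(1, 5))
            k = int(rng.integers(1, 4))
            q0 = float(rng.uniform(0.05, 0.9))
            w = rng.dirichlet(np.ones(k))
            q = np.zeros(k * d + 1)
            q[0] = q0
            q[np.arange(1, k + 1) * d] = (1 - q0) * w
            rho = stationary_profile(MutationModel(q), 3 * k * d + 2).rho
            off = [v for j, v in enumerate(rho) if j % d != 0]
            if off:
                np.testing.assert_allclose(off, 0.25, atol=1e-8)

    def test_substitution_dominated_limit_approaches_iid(self):
        q = np.zeros(3)
        q[0], q[2] = 1 - 1e-6, 1e-6
        rho = stationary_profile(MutationModel(q), 6).rho
        np.testing.assert_allclose(rho[1:], 0.25, atol=1e-4)

    def test_profile_is_in_null_space(self, rng):
        for _ in range(20):
            size = int(rng.integers(2, 8))
            q = rng.dirichlet(np.ones(size))
            q[0] += 0.05  # ensure q0 > 0
            m = MutationModel(q / q.sum())
            mm = int(rng.integers(max(2, m.K + 1), m.K + 10))
            rho = stationary_profile(m, mm)
            A = build_rate_matrix(m, mm).A
            assert np.max(np.abs(A @ rho.rho)) < 1e-9
            assert rho.rho[0] == 1.0

    def test_pure_duplication_regime_rejected(self):
        with pytest.raises(ValueError, match="null_space_basis"):
            stationary_profile(MutationModel([0.0, 1.0]), 4)


class TestNullSpace:
    @pytest.mark.parametrize(
        "pairs,size,expected_d,expected_dim",
        [
            ([(4, 0.5), (6, 0.5)], 7, 2, 2),
            ([(3, 1.0)], 4, 3, 2),
            ([(2, 0.5), (3, 0.5)], 4, 1, 1),
        ],
    )
    def test_dimension_matches_gcd_rule(self, pairs, size, expected_d,
                                        expected_dim):
        m = model_from(pairs, size)
        assert duplication_period(m) == expected_d
        basis = null_space_basis(m, 12)
        assert len(basis) == expected_dim  # floor(d/2) + 1

    def test_span_matches_lag_class_vectors(self):
        # Null(A) for q3=1 is spanned by the indicator vectors of lag
        # classes {0 mod 3} and {+-1 mod 3}
        basis = np.column_stack(null_space_basis(model_from([(3, 1.0)], 4), 12))
        for i in (0, 1):
            v = lag_class_vector(i, 3, 12)
            proj = basis @ (basis.T @ v)
            np.testing.assert_allclose(proj, v, atol=1e-8)

    def test_pure_duplication_required(self):
        with pytest.raises(ValueError, match="stationary_profile"):
            null_space_basis(MutationModel([0.5, 0.5]), 6)

    def test_all_ones_vector_when_d_is_one(self):
        basis = null_space_basis(model_from([(2, 0.5), (3, 0.5)], 4), 12)
        v = basis[0]
        np.testing.assert_allclose(v / v[0], np.ones(12), atol=1e-8)


class TestDuplicationPeriod:
    def test_requires_duplication_support(self):
        with pytest.raises(ValueError):
            duplication_period(MutationModel([1.0]))
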