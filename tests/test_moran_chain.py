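"""Single-clone chain: operators, master-equation evolution, queries."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pnhdrift.moran_chain import (
    NEUTRAL,
    PoolModel,
    SelectionModel,
    StateDistribution,
    build_birth_death_operator,
    build_division_only_operator,
    clinical_probability,
    evolve,
    first_passage_pmf,
    point_mass,
    selection_division_probability,
)
from pnhdrift.ontogeny import GrowthSchedule

from conftest import constant_pool_model


def brute_force_birth_death(N, mu, m):
    """Exact one-event outcome distribution by enumerating individual cells.

    Independent of the operator code: each of the N cells is a candidate
    parent (1/N), normal parents branch on mutation, and each of the N+1
    post-division cells is a candidate for differentiation (1/(N+1)).
    Computed in exact rational arithmetic.
    """
    out = {}
    mu = Fraction(mu).limit_denominator(10**6)
    for parent_is_mutant, n_parents in ((True, m), (False, N - m)):
        if n_parents == 0:
            continue
        p_div = Fraction(n_parents, N)
        branches = (
            [(Fraction(1), True)]
            if parent_is_mutant
            else [(mu, True), (1 - mu, False)]
        )
        for p_mut, daughter_mutant in branches:
            m_after = m + daughter_mutant
            for removed_mutant, n_cand in ((True, m_after), (False, N + 1 - m_after)):
                if n_cand == 0:
                    continue
                m_final = m_after - removed_mutant
                p = p_div * p_mut * Fraction(n_cand, N + 1)
                out[m_final] = out.get(m_final, Fraction(0)) + p
    return out


class TestBirthDeathOperator:
    def test_printed_formula_example(self):
        # N=4, m=1, mu=0: up = down = (N m - m^2)/(N(N+1)) = 3/20
        T = build_birth_death_operator(4, 0.0)
        assert T[2, 1] == pytest.approx(0.15, abs=1e-15)
        assert T[0, 1] == pytest.approx(0.15, abs=1e-15)
        assert T[1, 1] == pytest.approx(0.70, abs=1e-15)

    @given(N=st.integers(2, 40), m=st.integers(1, 39))
    def test_neutral_symmetry_formula(self, N, m):
        m = m % N
        T = build_birth_death_operator(N, 0.0)
        expected = (N * m - m * m) / (N * (N + 1))
        assert T[m + 1, m] == pytest.approx(expected, abs=1e-15)
        assert T[m - 1, m] == pytest.approx(expected, abs=1e-15)

    def test_updown_rate_maximal_at_half_pool(self):
        N = 60
        T = build_birth_death_operator(N, 0.0).toarray()
        up = np.array([T[m + 1, m] for m in range(N)])
        assert np.argmax(up) == N // 2

    def test_absorbing_boundaries_without_mutation(self):
        T = build_birth_death_operator(7, 0.0)
        assert T[0, 0] == 1.0
        assert T[7, 7] == 1.0

    @given(
        N=st.integers(1, 60),
        mu=st.sampled_from([0.0, 1e-7, 1e-3, 0.3]),
        r=st.sampled_from([1.0, 0.5, 2.0]),
        weighted=st.booleans(),
    )
    def test_column_stochastic_and_tridiagonal(self, N, mu, r, weighted):
        sel = SelectionModel(r_pig_a=r, weighted_differentiation=weighted)
        T = build_birth_death_operator(N, mu, sel)
        cols = np.asarray(T.sum(axis=0)).ravel()
        assert np.abs(cols - 1.0).max() <= 1e-12
        dense = T.toarray()
        for k in range(N + 1):
            for m in range(N + 1):
                if abs(m - k) > 1:
                    assert dense[m, k] == 0.0

    @given(
        N=st.integers(1, 12),
        m=st.integers(0, 12),
        mu=st.sampled_from([0.0, 0.1, 0.5]),
    )
    def test_matches_cell_level_enumeration(self, N, m, mu):
        m = m % (N + 1)
        T = build_birth_death_operator(N, mu).toarray()
        exact = brute_force_birth_death(N, mu, m)
        for target in range(N + 1):
            assert T[target, m] == pytest.approx(
                float(exact.get(target, 0)), abs=1e-12
            )

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_birth_death_operator(0, 0.0)


class TestDivisionOnlyOperator:
    def test_shape_extends_state_space(self):
        T = build_division_only_operator(10, 0.0)
        assert T.shape == (12, 11)

    def test_no_mutants_no_mutation_stays(self):
        T = build_division_only_operator(5, 0.0)
        assert T[0, 0] == 1.0

    @given(N=st.integers(1, 30), mu=st.sampled_from([0.0, 0.2]))
    def test_up_probability_and_stochasticity(self, N, mu):
        T = build_division_only_operator(N, mu)
        cols = np.asarray(T.sum(axis=0)).ravel()
        assert np.abs(cols - 1.0).max() <= 1e-12
        for m in range(N + 1):
            expected_up = m / N + (1 - m / N) * mu
            assert T[m + 1, m] == pytest.approx(expected_up, abs=1e-15)


class TestSelection:
    def test_reduces_to_neutral_fraction(self):
        assert selection_division_probability(3, 10, NEUTRAL) == pytest.approx(0.3)

    def test_printed_selection_formula(self):
        sel = SelectionModel(r_pig_a=2.0, r_healthy=1.0)
        assert selection_division_probability(200, 400, sel) == pytest.approx(2 / 3)

    def test_boundaries(self):
        sel = SelectionModel(r_pig_a=3.0)
        assert selection_division_probability(0, 10, sel) == 0.0
        assert selection_division_probability(10, 10, sel) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            selection_division_probability(11, 10)

    @given(N=st.integers(1, 30), mu=st.sampled_from([0.0, 1e-3]))
    def test_equal_fitness_operators_identical_to_neutral(self, N, mu):
        sel = SelectionModel(r_pig_a=1.7, r_healthy=1.7)
        for build in (build_birth_death_operator, build_division_only_operator):
            a = build(N, mu, NEUTRAL).toarray()
            b = build(N, mu, sel).toarray()
            np.testing.assert_array_equal(a, b)

    def test_positive_fitness_required(self):
        with pytest.raises(ValueError):
            SelectionModel(r_pig_a=0.0)


class TestEvolve:
    def test_identity_when_ages_equal(self, default_model):
        d = point_mass(20, 0, 0.0)
        out = evolve(default_model, d, 0.0, 0.0)
        np.testing.assert_array_equal(out.probabilities, d.probabilities)

    def test_pool_size_mismatch_rejected(self, default_model):
        with pytest.raises(ValueError):
            evolve(default_model, point_mass(30, 0), 0.0, 1.0)

    def test_mass_conserved_over_lifetime(self, default_model):
        out = evolve(default_model, point_mass(20, 0), 0.0, 100.0)
        assert abs(out.probabilities.sum() - 1.0) <= 1e-10
        assert out.pool_size == 400

    @given(m0=st.integers(1, 9))
    def test_neutral_martingale_exact(self, m0):
        """With mu=0 the expected mutant count is conserved exactly."""
        model = constant_pool_model(10, 0.0)
        out = evolve(model, point_mass(10, m0), 0.0, 20.0)
        ev = float(np.arange(11) @ out.probabilities)
        assert ev == pytest.approx(m0, abs=1e-9)

    def test_fixation_probability_is_m_over_N(self):
        """Classical neutral result recovered from the operator by linear solve."""
        for N in (5, 9, 12):
            T = build_birth_death_operator(N, 0.0).toarray()
            # solve f(m) = sum_target T[target, m] f(target), f(0)=0, f(N)=1
            A = np.eye(N - 1) - T[1:N, 1:N].T
            b = T[N, 1:N]
            f = np.linalg.solve(A, b)
            np.testing.assert_allclose(f, np.arange(1, N) / N, atol=1e-8)


class TestClinicalProbability:
    def test_point_mass_at_zero(self):
        assert clinical_probability(point_mass(400, 0), 0.2) == 0.0

    def test_tiny_threshold_counts_any_mutant(self):
        d = StateDistribution(np.array([0.4, 0.35, 0.25]), 0.0)
        assert clinical_probability(d, 1e-9) == pytest.approx(0.6)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            clinical_probability(point_mass(10, 5), 0.0)
        with pytest.raises(ValueError):
            clinical_probability(point_mass(10, 5), 1.5)

    def test_ceil_rounding_at_least_semantics(self):
        # N=10, threshold 0.25 -> clinical means m >= 3
        d = StateDistribution(np.r_[np.zeros(3), 1.0, np.zeros(7)], 0.0)
        assert clinical_probability(d, 0.25) == 1.0
        assert clinical_probability(d, 0.31) == 0.0


@pytest.fixture(scope="module")
def pmf20():
    return first_passage_pmf(PoolModel(), 0.2, max_age=40)


class TestFirstPassage:

    def test_entries_nonnegative_cumulative_bounded(self, pmf20):
        assert (pmf20 >= 0).all()
        cum = pmf20.cumsum()
        assert (cum.diff().fillna(cum.iloc[0]) >= 0).all()
        assert cum.iloc[-1] <= 1.0

    def test_first_year_bounded_by_mutation_probability(self, pmf20):
        from pnhdrift.ontogeny import cumulative_replications
        mu_budget = 5e-7 * cumulative_replications(GrowthSchedule(), 1.0)
        assert pmf20.iloc[0] <= mu_budget

    def test_lower_threshold_dominates(self):
        model = constant_pool_model(30, 1e-4)
        lo = first_passage_pmf(model, 0.1, max_age=15).cumsum()
        hi = first_passage_pmf(model, 0.3, max_age=15).cumsum()
        assert (lo + 1e-15 >= hi).all()
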