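"""Absorbing-chain analysis against closed forms (geometric lifetimes),
power-series and recursion oracles, Monte-Carlo simulation, and the
cross-module death-ledger identity."""

import numpy as np
import pytest

from povdyn.fundamental import (build_absorbing_chain, expected_years_below,
                                fundamental_matrix, life_table,
                                remaining_life_expectancy,
                                variance_remaining_life)
from povdyn.markov import assemble_L, project_cohort
from povdyn.rates import RateSet
from povdyn.simulation import simulate_cohort


def _L(rs, ages):
    return assemble_L(rs, ages=ages, padding="none")


class TestAbsorbingChain:
    def test_full_chain_is_column_stochastic(self, random_rateset):
        rs = random_rateset(ages=range(0, 8), seed=0)
        L = _L(rs, range(0, 8))
        chain = build_absorbing_chain(L)
        np.testing.assert_allclose(chain.P.sum(axis=0),
                                   np.ones(L.dim + 1), atol=1e-12)

    def test_zero_matrix_means_immediate_death(self):
        rs = RateSet.constant(range(0, 4), 0.0, 0.0, 0.3, 0.9)
        L = _L(rs, range(0, 4))
        chain = build_absorbing_chain(L)
        np.testing.assert_array_equal(chain.mortality, np.ones(L.dim))
        np.testing.assert_array_equal(fundamental_matrix(L), np.eye(L.dim))

    def test_supra_stochastic_column_rejected(self, random_rateset):
        rs = random_rateset(ages=range(0, 4), seed=1)
        L = _L(rs, range(0, 4))
        L.matrix[2, 0] = 1.5
        with pytest.raises(ValueError, match="sum"):
            build_absorbing_chain(L)


class TestFundamentalMatrix:
    def test_matches_truncated_power_series_on_random_chains(
            self, random_rateset):
        for seed in range(5):
            rs = random_rateset(ages=range(0, 5), seed=seed)
            L = _L(rs, range(0, 5))
            N = fundamental_matrix(L)
            S = np.zeros_like(N)
            P = np.eye(L.dim)
            for _ in range(201):
                S += P
                P = P @ L.matrix
            np.testing.assert_allclose(N, S, atol=1e-10)

    def test_back_substitution_equals_dense_inverse(self, random_rateset):
        rs = random_rateset(ages=range(0, 20), seed=11)
        L = _L(rs, range(0, 20))
        N = fundamental_matrix(L)
        N_dense = np.linalg.inv(np.eye(L.dim) - L.matrix)
        np.testing.assert_allclose(N, N_dense, atol=1e-10)

    def test_diagonal_is_exactly_one_for_age_advancing_chains(
            self, random_rateset):
        rs = random_rateset(ages=range(0, 6), seed=2)
        N = fundamental_matrix(_L(rs, range(0, 6)))
        np.testing.assert_array_equal(np.diag(N), np.ones(N.shape[0]))
        assert (N >= 0).all()


class TestExpectancy:
    def test_immediate_death_expectancy_is_one_counting_current_year(self):
        rs = RateSet.constant(range(0, 4), 0.0, 0.0, 0.3, 0.9)
        L = _L(rs, range(0, 4))
        N = fundamental_matrix(L)
        assert remaining_life_expectancy(L, N, (0, 1)) == 1.0
        assert remaining_life_expectancy(L, N, (0, 1),
                                         include_current=False) == 0.0

    def test_constant_survival_geometric_closed_form(self):
        # frozen states isolate a single-state chain; s = 0.9 over enough
        # ages that truncation is far below tolerance: E = 1/(1-s) = 10
        rs = RateSet.constant(range(0, 200), 0.9, 0.9, 0.0, 1.0)
        L = assemble_L(rs, ages=range(0, 200), padding="none")
        N = fundamental_matrix(L)
        assert remaining_life_expectancy(L, N, (0, 2)) == \
            pytest.approx(10.0, abs=1e-6)

    def test_one_step_recursion_oracle(self, random_rateset):
        rs = random_rateset(ages=range(0, 6), seed=3)
        L = _L(rs, range(0, 6))
        N = fundamental_matrix(L)
        eta = N.sum(axis=0)
        np.testing.assert_allclose(eta, 1.0 + L.matrix.T @ eta, atol=1e-12)

    def test_conventions_differ_by_exactly_one_everywhere(
            self, random_rateset):
        rs = random_rateset(ages=range(0, 6), seed=4)
        L = _L(rs, range(0, 6))
        N = fundamental_matrix(L)
        for j in range(L.dim):
            a = remaining_life_expectancy(L, N, j, include_current=True)
            b = remaining_life_expectancy(L, N, j, include_current=False)
            assert a - b == pytest.approx(1.0, abs=1e-12)

    def test_expectancy_equals_cohort_mean_age_at_death(self, random_rateset):
        rs = random_rateset(ages=range(0, 8), seed=5)
        L = _L(rs, range(0, 8))
        N = fundamental_matrix(L)
        for state in (1, 2):
            n0 = np.zeros(L.dim)
            j = L.cell_index(0, state)
            n0[j] = 1.0
            masses = [1.0]
            for x in range(1, 10):
                masses.append(project_cohort(L, n0, x).sum())
            deaths = -np.diff(masses + [0.0])
            mean_years = float((np.arange(1, len(deaths) + 1) * deaths).sum())
            assert mean_years == pytest.approx(
                remaining_life_expectancy(L, N, j), abs=1e-10)

    def test_lower_survival_lowers_expectancy_everywhere(self):
        hi = RateSet.constant(range(0, 30), 0.95, 0.97, 0.2, 0.9)
        lo = RateSet.constant(range(0, 30), 0.90, 0.93, 0.2, 0.9)
        Lh, Ll = _L(hi, range(0, 30)), _L(lo, range(0, 30))
        eta_h = fundamental_matrix(Lh).sum(axis=0)
        eta_l = fundamental_matrix(Ll).sum(axis=0)
        assert (eta_h[:-2] > eta_l[:-2]).all()


class TestYearsBelowAndVariance:
    def test_frozen_states_split_years_below_all_or_nothing(self):
        rs = RateSet.constant(range(0, 40), 0.9, 0.9, 0.0, 1.0)
        L = _L(rs, range(0, 40))
        N = fundamental_matrix(L)
        total = remaining_life_expectancy(L, N, (0, 1))
        assert expected_years_below(L, N, (0, 2)) == pytest.approx(0.0)
        assert expected_years_below(L, N, (0, 1)) == pytest.approx(total)

    def test_immediate_death_has_zero_variance(self):
        rs = RateSet.constant(range(0, 4), 0.0, 0.0, 0.3, 0.9)
        L = _L(rs, range(0, 4))
        _, var, _ = variance_remaining_life(L, fundamental_matrix(L))
        np.testing.assert_allclose(var, 0.0, atol=1e-12)

    def test_constant_survival_geometric_variance(self):
        # lifetime from any cell is geometric: var = s / (1-s)^2
        s = 0.7
        rs = RateSet.constant(range(0, 120), s, s, 0.0, 1.0)
        L = assemble_L(rs, ages=range(0, 120), padding="none")
        N = fundamental_matrix(L)
        eta, var, cv = variance_remaining_life(L, N)
        j = L.cell_index(0, 1)
        assert var[j] == pytest.approx(s / (1 - s) ** 2, abs=1e-9)
        assert cv[j] == pytest.approx(np.sqrt(var[j]) / eta[j], abs=1e-12)

    def test_monte_carlo_agrees_with_moments(self, random_rateset):
        rs = random_rateset(ages=range(0, 12), seed=6, s_lo=0.6, s_hi=0.95)
        L = _L(rs, range(0, 12))
        N = fundamental_matrix(L)
        eta, var, _ = variance_remaining_life(L, N)
        j = L.cell_index(0, 1)
        traj = simulate_cohort(rs, n=60_000, start_age=0, seed=0,
                               terminal_age=11,
                               initial_states=np.ones(60_000, dtype=int))
        life = traj.lifespan_years
        assert abs(life.mean() - eta[j]) < 3 * life.std(ddof=1) / np.sqrt(
            life.size)
        below = (traj.states == 1).sum(axis=1)
        target = expected_years_below(L, N, j)
        assert abs(below.mean() - target) < 3 * below.std(ddof=1) / np.sqrt(
            below.size)
        # sample variance vs chain variance (SE of variance via 4th moment)
        m = life.mean()
        se_var = np.sqrt(((life - m) ** 4).mean()
                         - life.var(ddof=0) ** 2) / np.sqrt(life.size)
        assert abs(life.var(ddof=1) - var[j]) < 3 * se_var

    def test_life_table_shape_and_internal_consistency(self, truth_1x):
        from povdyn.synthetic import true_rateset
        rs = true_rateset(truth_1x)
        L = assemble_L(rs, ages=range(22, 101), padding="clamp")
        lt = life_table(L, ages=rs.ages)
        assert set(lt.columns) >= {"age", "state", "expectancy", "years_below",
                                   "proportion_below", "variance", "cv"}
        assert len(lt) == 2 * rs.ages.size
        assert (lt["years_below"] <= lt["expectancy"] + 1e-9).all()
        assert (lt["variance"] >= 0).all()
        ok = lt["expectancy"] > 0
        np.testing.assert_allclose(
            lt.loc[ok, "cv"],
            np.sqrt(lt.loc[ok, "variance"]) / lt.loc[ok, "expectancy"])
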