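"""Agent-based simulator: determinism, conservation laws, and cross-validation
against the exact fixation analytics and an exact small-mutation oracle."""

import numpy as np
import pytest
from scipy import linalg

from phenocoop import (
    FixationQuery,
    ModelParams,
    Population,
    Strain,
    StrainSpace,
    Strategy,
    fixation_frequency,
    fixation_probability,
    moran_step,
    payoffs,
    run_simulation,
    state_payoffs,
)

C, D = Strategy.C, Strategy.D


def label_refined_stationary(params: ModelParams) -> np.ndarray:
    """Independent small-mutation oracle tracking (strain, expressed label) states.

    Unlike the strain-level chain, this keeps the resident's actual expressed
    label, so the correlation between a founder's label and its fixation odds
    is represented exactly. Returns the strain-marginal stationary vector.
    """
    space = StrainSpace(params.M)
    states = [(st, g) for st in space.strains for g in range(1, st.K + 1)]
    n = len(states)
    A = np.zeros((n, n))
    for i, (X, gx) in enumerate(states):
        for j, (Y, gy) in enumerate(states):
            if X == Y and gx == gy:
                continue
            if X == Y:
                rho = 1.0 / params.N  # same strain, distinct neutral lineage
            else:
                delta = 1 if gy == gx else 0
                rho = fixation_probability(FixationQuery(Y, X, delta, params))
            A[i, j] = rho / (2 * params.M * Y.K)
        A[i, i] = 1.0 - A[i].sum() + A[i, i]
    eigvals, eigvecs = linalg.eig(A.T)
    pi = np.real(eigvecs[:, np.argmin(np.abs(eigvals - 1.0))])
    if pi.sum() < 0:
        pi = -pi
    pi = np.clip(pi, 0, None)
    pi /= pi.sum()
    marginal = np.zeros(2 * params.M)
    for k, (st, _) in enumerate(states):
        marginal[space.position(st)] += pi[k]
    return marginal


class TestPopulation:
    def test_random_init_respects_repertoires(self):
        pop = Population.random(ModelParams(N=200, M=7), seed=5)
        assert pop.N == 200
        assert np.all(pop.phenotype >= 1)
        assert np.all(pop.phenotype <= pop.repertoire)
        assert np.all(pop.repertoire <= 7)

    def test_strain_counts_sum_to_population_size(self):
        pop = Population.random(ModelParams(N=50, M=4), seed=1)
        counts = pop.strain_counts(4)
        assert counts.sum() == 50
        assert counts.shape == (8,)

    def test_agentwise_payoffs_match_the_two_type_kernel(self):
        # i matched cooperators (C, K=2) against N-i defectors (D, K=1)
        params = ModelParams(N=12, theta=0.1)
        i = 4
        pop = Population(
            phenotype=np.ones(12, dtype=np.int64),
            is_coop=np.array([1] * i + [0] * (12 - i), dtype=np.int64),
            repertoire=np.array([2] * i + [1] * (12 - i), dtype=np.int64),
            rng=np.random.default_rng(0),
        )
        pay = payoffs(pop, params)
        P_A, P_B = state_payoffs(i, Strain(C, 2), Strain(D, 1), 1, params)
        np.testing.assert_allclose(pay[:i], P_A)
        np.testing.assert_allclose(pay[i:], P_B)


class TestMoranStep:
    def test_homogeneous_population_is_absorbing_without_mutation(self):
        params = ModelParams(N=10, mu=0.0, M=5)
        pop = Population.homogeneous(Strain(C, 3), phenotype=2, N=10, seed=3)
        for _ in range(200):
            moran_step(pop, params)
        assert set(pop.phenotype) == {2}
        assert set(pop.is_coop) == {1}
        assert set(pop.repertoire) == {3}

    def test_population_size_is_conserved(self):
        params = ModelParams(N=15, M=5)
        pop = Population.random(params, seed=8)
        for _ in range(300):
            moran_step(pop, params)
            assert pop.N == 15
            assert pop.strain_counts(5).sum() == 15

    def test_without_mutation_the_strain_set_only_shrinks(self):
        params = ModelParams(N=30, M=5, mu=0.0)
        pop = Population.random(params, seed=21)
        present = pop.strains_present()
        for _ in range(500):
            moran_step(pop, params)
            now = pop.strains_present()
            assert now <= present
            present = now


class TestRunSimulation:
    def test_identical_seeds_give_identical_runs(self):
        params = ModelParams(N=10, M=3)
        a = run_simulation(params, steps=20_000, seed=42, record_every=50)
        b = run_simulation(params, steps=20_000, seed=42, record_every=50)
        assert a.trajectory.equals(b.trajectory)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        c = run_simulation(params, steps=20_000, seed=43, record_every=50)
        assert not a.trajectory.equals(c.trajectory)

    def test_occupancy_is_a_distribution_and_counts_sum_to_N(self):
        params = ModelParams(N=10, M=3)
        res = run_simulation(params, steps=10_000, seed=7, record_every=10, store_counts=True)
        assert res.occupancy.sum() == pytest.approx(1.0)
        assert np.all(res.counts.sum(axis=1) == 10)
        assert res.trajectory.n_coop.between(0, 10).all()

    def test_everything_mutating_neutrally_visits_strains_uniformly(self):
        # mu=1, beta=0: every offspring is a uniform strain resample
        params = ModelParams(N=10, M=3, mu=1.0, beta=0.0)
        res = run_simulation(params, steps=300_000, seed=11, record_every=10)
        assert np.max(np.abs(res.occupancy - 1 / 6)) < 0.01


class TestAgainstAnalytics:
    def test_neutral_single_mutant_fixes_with_probability_one_over_N(self):
        params = ModelParams(N=10, beta=0.0, M=5)
        est = fixation_frequency(
            Strain(C, 2), Strain(D, 4), params, replicates=20_000, seed=5, delta=0
        )
        assert abs(est.frequency - 0.1) < 3 * est.std_error

    @pytest.mark.parametrize("delta", [0, 1])
    def test_invasion_frequency_matches_exact_fixation_probability(self, delta):
        params = ModelParams(N=10)
        mutant, resident = Strain(C, 2), Strain(D, 1)
        est = fixation_frequency(mutant, resident, params, replicates=20_000, seed=9, delta=delta)
        exact = fixation_probability(FixationQuery(mutant, resident, delta, params))
        assert abs(est.frequency - exact) < 3 * est.std_error

    def test_long_run_occupancy_matches_label_refined_small_mutation_oracle(self):
        """Strain occupancy over 2e7 updates at mu=0.002 agrees with the exact
        (strain, label) embedded chain within total variation 0.05."""
        params = ModelParams(N=10, M=3, mu=0.002)
        oracle = label_refined_stationary(params)
        sim = run_simulation(params, steps=20_000_000, seed=1, record_every=50)
        tv = 0.5 * float(np.abs(sim.occupancy - oracle).sum())
        assert tv < 0.05
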