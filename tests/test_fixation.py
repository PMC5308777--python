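"""Fixation probabilities: product formula, linear-solve oracle, defector closed form."""

import math

import numpy as np
import pytest

from phenocoop import (
    FixationQuery,
    ModelParams,
    Strain,
    StrainSpace,
    Strategy,
    brute_force_fixation,
    dvsd_closed_form,
    fixation_matrices,
    fixation_probability,
)
from conftest import random_strain

C, D = Strategy.C, Strategy.D


def test_neutral_drift_fixes_with_probability_one_over_N(rng):
    params = ModelParams(N=20, beta=0.0)
    for _ in range(10):
        q = FixationQuery(random_strain(rng), random_strain(rng), int(rng.integers(2)), params)
        assert fixation_probability(q) == pytest.approx(1 / 20, abs=1e-14)


def test_near_neutral_limit_is_continuous(rng):
    params = ModelParams(N=20, beta=1e-12)
    for _ in range(10):
        q = FixationQuery(random_strain(rng), random_strain(rng), int(rng.integers(2)), params)
        assert fixation_probability(q) == pytest.approx(1 / 20, abs=1e-6)


class TestDefectorClosedForm:
    def test_equal_repertoires_are_neutral(self):
        params = ModelParams(N=20)
        assert dvsd_closed_form(5, 5, params) == pytest.approx(1 / 20)

    @pytest.mark.parametrize("delta", [0, 1])
    def test_matches_direct_evaluation(self, delta):
        # mutant defector with one extra phenotype: rho = (1-e^{0.01})/(1-e^{0.2})
        params = ModelParams(N=20, beta=0.1, theta=0.1)
        expected = (1 - math.exp(0.01)) / (1 - math.exp(0.2))
        assert dvsd_closed_form(2, 1, params) == pytest.approx(expected, rel=1e-12)
        q = FixationQuery(Strain(D, 2), Strain(D, 1), delta, params)
        assert fixation_probability(q) == pytest.approx(expected, rel=1e-12)

    def test_lean_mutant_invading_bloated_residents(self):
        params = ModelParams(N=20, beta=0.1, theta=0.1)
        expected = (1 - math.exp(-0.49)) / (1 - math.exp(-9.8))
        assert dvsd_closed_form(1, 50, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("delta", [0, 1])
    def test_agrees_with_product_formula_on_repertoire_grid(self, delta):
        params = ModelParams(N=20, beta=0.1, theta=0.1)
        worst = 0.0
        for k_mut in range(1, 11):
            for k_res in range(1, 11):
                q = FixationQuery(Strain(D, k_mut), Strain(D, k_res), delta, params)
                worst = max(worst, abs(fixation_probability(q) - dvsd_closed_form(k_mut, k_res, params)))
        assert worst < 1e-12

    def test_monotone_in_both_repertoires_under_costly_selection(self):
        params = ModelParams(N=20, beta=0.1, theta=0.1)
        ks = range(1, 21)
        by_mutant = [dvsd_closed_form(k, 10, params) for k in ks]
        by_resident = [dvsd_closed_form(10, k, params) for k in ks]
        assert np.all(np.diff(by_mutant) < 0)
        assert np.all(np.diff(by_resident) > 0)

    def test_stable_under_extreme_selection(self):
        params = ModelParams(N=20, beta=1e3, theta=0.1)
        assert dvsd_closed_form(1, 50, params) == pytest.approx(1.0, abs=1e-12)
        assert dvsd_closed_form(50, 1, params) == pytest.approx(0.0, abs=1e-300)
        q = FixationQuery(Strain(D, 1), Strain(D, 50), 0, params)
        assert fixation_probability(q) == pytest.approx(1.0, abs=1e-12)


class TestBruteForceOracle:
    def test_rejects_large_populations(self):
        q = FixationQuery(Strain(C, 1), Strain(D, 1), 0, ModelParams(N=13))
        with pytest.raises(ValueError):
            brute_force_fixation(q)

    def test_neutral_small_chain(self):
        q = FixationQuery(Strain(C, 2), Strain(D, 5), 1, ModelParams(N=6, beta=0.0))
        assert brute_force_fixation(q) == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_strains_fix_neutrally(self):
        params = ModelParams(N=8)
        q = FixationQuery(Strain(C, 3), Strain(C, 3), 1, params)
        assert brute_force_fixation(q) == pytest.approx(1 / 8, abs=1e-12)
        assert fixation_probability(q) == pytest.approx(1 / 8, abs=1e-12)

    def test_product_formula_equals_linear_solve_on_randomized_cases(self, rng):
        """The two routes are algebraically identical; 200 randomized cases, N <= 8."""
        for _ in range(200):
            params = ModelParams(
                N=int(rng.integers(2, 9)),
                b=float(rng.uniform(0.5, 2.0)),
                c=float(rng.uniform(0.05, 0.45)),
                beta=float(rng.uniform(0.0, 1.0)),
                theta=float(rng.uniform(0.0, 0.5)),
            )
            q = FixationQuery(
                random_strain(rng), random_strain(rng), int(rng.integers(2)), params
            )
            assert fixation_probability(q) == pytest.approx(
                brute_force_fixation(q), abs=1e-10
            )


def test_escaping_exploitation_helps_invading_cooperators(standard_params):
    """A cooperator invading defectors does better when phenotypes mismatch."""
    for k_mut in (1, 5, 10, 25, 50):
        for k_res in (1, 5, 10, 25, 50):
            rho_d = fixation_probability(
                FixationQuery(Strain(C, k_mut), Strain(D, k_res), 0, standard_params)
            )
            rho_s = fixation_probability(
                FixationQuery(Strain(C, k_mut), Strain(D, k_res), 1, standard_params)
            )
            assert rho_d >= rho_s


def test_vectorized_matrices_match_scalar_evaluations(rng):
    params = ModelParams(M=6, N=10)
    space = StrainSpace(6)
    rho_s, rho_d = fixation_matrices(params, space)
    for _ in range(25):
        y = int(rng.integers(12))
        x = int(rng.integers(12))
        mutant, resident = space.strains[y], space.strains[x]
        assert rho_s[y, x] == pytest.approx(
            fixation_probability(FixationQuery(mutant, resident, 1, params)), abs=1e-13
        )
        assert rho_d[y, x] == pytest.approx(
            fixation_probability(FixationQuery(mutant, resident, 0, params)), abs=1e-13
        )


def test_invalid_queries_rejected(standard_params):
    with pytest.raises(ValueError):
        FixationQuery(Strain(C, 1), Strain(D, 1), 2, standard_params)
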