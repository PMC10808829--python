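"""Bernoulli mixture EM, information criteria and model selection."""

import itertools
import math

import numpy as np
import pytest

from sretlca import (
    DataError,
    bic,
    fit_em,
    fit_range,
    icl,
    kmax_bezdek,
    nec,
    select_model,
)
from sretlca.mixture import make_solution


def grid_search_loglik(X, resolution=0.05):
    """Independent oracle: best 2-component mixture log-likelihood on a grid.

    Dense grid over the mixing weight and both probability rows at the given
    resolution; feasible for J <= 2.
    """
    X = np.asarray(X, dtype=float)
    J = X.shape[1]
    grid = np.arange(resolution, 1.0 - resolution / 2, resolution)
    P = np.array(list(itertools.product(grid, repeat=J)))
    lp = X @ np.log(P).T + (1 - X) @ np.log1p(-P).T   # (n, n_combos)
    best = -np.inf
    for pi in grid:
        a = np.log(pi) + lp[:, :, None]
        b = np.log1p(-pi) + lp[:, None, :]
        ll = np.logaddexp(a, b).sum(axis=0)
        best = max(best, float(ll.max()))
    return best


class TestFitEm:
    def test_single_class_closed_form(self):
        X = np.array([[1], [1], [0], [0]])
        model = fit_em(X, 1, seed=0)
        assert model.P[0, 0] == pytest.approx(0.5)
        assert model.loglik == pytest.approx(4 * math.log(0.5), abs=1e-9)
        assert model.nu == 1

    def test_single_class_responsibilities_are_one(self):
        X = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        solution = make_solution(fit_em(X, 1, seed=0), X)
        np.testing.assert_array_equal(solution.responsibilities, np.ones((4, 1)))
        assert solution.entropy == pytest.approx(0.0)

    def test_two_separated_blocks_recovered(self):
        """All-ones rows vs all-zeros rows: K=2 recovers the blocks exactly.

        The component densities are ~1 after clamping, so the optimum
        log-likelihood is the pure assignment cost 6 * ln(1/2).
        """
        X = np.vstack([np.ones((3, 4)), np.zeros((3, 4))]).astype(int)
        model = fit_em(X, 2, seed=1)
        solution = make_solution(model, X)
        labels = solution.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert model.loglik == pytest.approx(6 * math.log(0.5), abs=1e-3)
        assert solution.entropy == pytest.approx(0.0, abs=1e-6)

    def test_loglik_never_decreases_and_converges(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(40, 10))
        model = fit_em(X, 3, seed=5)         # monotonicity asserted internally
        assert model.converged
        assert model.nu == 2 + 3 * 10

    @pytest.mark.parametrize("bad_K, bad_n", [(0, 10), (5, 4)])
    def test_preconditions(self, bad_K, bad_n):
        X = np.zeros((bad_n, 2), dtype=int)
        with pytest.raises(DataError):
            fit_em(X, bad_K, seed=0)

    def test_non_binary_matrix_raises(self):
        with pytest.raises(DataError, match="binary"):
            fit_em(np.array([[0.5, 1.0]]), 1, seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_em_attains_grid_search_optimum(self, seed):
        """EM with restarts matches a dense-grid oracle on tiny problems."""
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(8, 2))
        oracle = grid_search_loglik(X)
        model = fit_em(X, 2, seed=seed)
        assert model.loglik >= oracle - 1e-6

    def test_em_attains_grid_search_optimum_1d(self):
        X = np.array([[1], [1], [1], [0], [0], [1]])
        assert fit_em(X, 2, seed=0).loglik >= grid_search_loglik(X) - 1e-6


class TestCriteria:
    def test_bic_hand_value_for_one_column(self):
        """-2 * loglik + nu * ln(n) = 2 * 2.7726 + ln(4) = 6.9315 at K=1, J=1."""
        X = np.array([[1], [1], [0], [0]])
        model = fit_em(X, 1, seed=0)
        assert bic(model, 4) == pytest.approx(6.9315, abs=1e-4)
        assert bic(model, 4) == pytest.approx(-2 * model.loglik + 1 * math.log(4))

    def test_zero_entropy_makes_icl_equal_bic_and_nec_zero(self):
        X = np.vstack([np.ones((3, 4)), np.zeros((3, 4))]).astype(int)
        solution = make_solution(fit_em(X, 2, seed=0), X)
        loglik1 = fit_em(X, 1, seed=0).loglik
        assert icl(solution, 6) == pytest.approx(bic(solution.model, 6), abs=1e-6)
        assert nec(solution, loglik1) == pytest.approx(0.0, abs=1e-6)

    def test_nec_is_one_at_k1_by_convention(self):
        X = np.array([[1, 0], [0, 1], [1, 1]])
        solution = make_solution(fit_em(X, 1, seed=0), X)
        assert nec(solution, solution.model.loglik) == 1.0

    def test_nec_infinite_when_no_likelihood_gain(self):
        X = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        solution = make_solution(fit_em(X, 2, seed=0), X)
        with pytest.warns(UserWarning, match="NEC undefined"):
            assert nec(solution, solution.model.loglik + 10.0) == np.inf

    def test_criteria_invariant_under_component_relabeling(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(30, 6))
        model = fit_em(X, 3, seed=2)
        solution = make_solution(model, X)
        perm = [2, 0, 1]
        permuted = type(model)(
            K=3, pi=model.pi[perm], P=model.P[perm], loglik=model.loglik,
            nu=model.nu, converged=model.converged, n_iter=model.n_iter,
            seed=model.seed,
        )
        perm_solution = make_solution(permuted, X)
        loglik1 = fit_em(X, 1, seed=0).loglik
        _, ll = permuted.log_responsibilities(X.astype(float))
        assert ll == pytest.approx(model.loglik, abs=1e-8)
        assert icl(perm_solution, 30) == pytest.approx(icl(solution, 30), abs=1e-6)
        assert nec(perm_solution, loglik1) == pytest.approx(nec(solution, loglik1), abs=1e-8)


@pytest.mark.parametrize(
    "n, expected",
    [(119, 5), (234, 7), (8, 3), (27, 4), (125, 6), (1000, 11)],
)
def test_kmax_bezdek(n, expected):
    """Smallest integer strictly above the cube root of n."""
    assert kmax_bezdek(n) == expected


class TestSelectModel:
    def test_range_of_one_returns_that_k(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(20, 5))
        for criterion in ("bic", "icl", "nec"):
            assert select_model(X, criterion, seed=1, kmin=2, kmax=2).model.K == 2

    def test_same_seed_gives_identical_solution(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(30, 8))
        a = select_model(X, "bic", seed=7, kmax=3)
        b = select_model(X, "bic", seed=7, kmax=3)
        assert a.model.K == b.model.K
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.model.P, b.model.P, atol=0)

    def test_bic_recovers_true_k_on_separated_three_class_data(self):
        """Majority of seeds select K=3 on strongly separated classes."""
        from conftest import block_probs_3class, make_spec
        from sretlca import build_endorsement_matrix, default_word_bank

        cohort_spec = make_spec(block_probs_3class(), n=150, seed=10)
        from sretlca import generate_cohort

        cohort = generate_cohort(cohort_spec)
        matrix = build_endorsement_matrix(cohort.trials, default_word_bank())
        selected = [
            select_model(matrix, "bic", seed=s, kmax=5).model.K for s in range(1, 6)
        ]
        assert sum(k == 3 for k in selected) >= 3

    def test_fit_range_contains_reference_and_criteria(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(25, 4))
        solutions = fit_range(X, seed=0, kmin=2, kmax=3)
        assert set(solutions) == {1, 2, 3}
        for sol in solutions.values():
            assert {"bic", "icl", "nec"} <= set(sol.criteria)
            np.testing.assert_allclose(sol.responsibilities.sum(axis=1), 1.0, atol=1e-8)
            assert sol.cluster_sizes().sum() == 25
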