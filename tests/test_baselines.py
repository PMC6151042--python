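import itertools

import numpy as np
import pandas as pd
import pytest

import bayescce as b
from bayescce.baselines import admissible_c_max
from conftest import make_random_factorization


class TestReferenceBasedEstimate:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0.1, 0.9, size=(40, 3))
        R = rng.dirichlet([2.0, 1.0, 3.0], size=12)
        R_hat = b.reference_based_estimate(M @ R.T, M)
        np.testing.assert_allclose(R_hat, R, atol=1e-6)

    def test_matches_simplex_grid_search(self):
        """1-sample, 5-site, k=3 toy: the QP solution agrees with an
        exhaustive simplex grid (step 0.001) within one step."""
        rng = np.random.default_rng(1)
        M = rng.uniform(0.1, 0.9, size=(5, 3))
        y = rng.uniform(0.2, 0.8, size=5)
        R_hat = b.reference_based_estimate(y[:, None], M)[0]

        step = 0.001
        grid = np.arange(0.0, 1.0 + step / 2, step)
        best, best_val = None, np.inf
        for p1 in grid:
            p2 = np.arange(0.0, 1.0 - p1 + step / 2, step)
            p3 = 1.0 - p1 - p2
            cand = np.column_stack([np.full_like(p2, p1), p2, p3])
            vals = ((y[None, :] - cand @ M.T) ** 2).sum(axis=1)
            j = int(np.argmin(vals))
            if vals[j] < best_val:
                best_val, best = vals[j], cand[j]
        assert np.all(np.abs(R_hat - best) <= step + 1e-9)

    def test_rows_on_simplex(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(0.1, 0.9, size=(30, 4))
        O = rng.uniform(size=(30, 8))
        R_hat = b.reference_based_estimate(O, M)
        np.testing.assert_allclose(R_hat.sum(axis=1), 1.0, atol=1e-8)
        assert R_hat.min() >= -1e-8

    def test_site_intersection_and_empty_error(self):
        Mdf = pd.DataFrame(np.full((3, 2), 0.5), index=["a", "b", "c"])
        Odf = pd.DataFrame(np.full((2, 2), 0.5), index=["x", "y"])
        with pytest.raises(b.ValidationError):
            b.reference_based_estimate(Odf, Mdf)


class TestFitNNMF:
    def test_objective_monotone_nonincreasing(self, k3_dataset):
        _, _, traj = b.fit_nnmf(k3_dataset.O, 3, seed=0, max_rounds=30)
        assert all(a >= c - 1e-9 * max(a, 1.0) for a, c in zip(traj, traj[1:]))
        assert len(traj) > 1

    def test_k1_gives_all_ones_proportions(self):
        rng = np.random.default_rng(3)
        O = rng.uniform(0.2, 0.8, size=(25, 10))
        M, R, traj = b.fit_nnmf(O, 1)
        np.testing.assert_array_equal(R, np.ones((10, 1)))

    def test_variable_site_prefilter(self):
        rng = np.random.default_rng(4)
        O = rng.uniform(0.3, 0.7, size=(50, 12))
        M, R, _ = b.fit_nnmf(O, 2, max_sites=20, seed=0, max_rounds=5)
        assert M.shape == (20, 2) and R.shape == (12, 2)

    def test_factors_respect_their_constraint_sets(self, k3_dataset):
        M, R, _ = b.fit_nnmf(k3_dataset.O, 3, seed=1, max_rounds=15)
        assert M.min() >= 0 and M.max() <= 1
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-8)


class TestEquivalentSolution:
    def test_equal_objective_over_many_instances(self):
        """100 random factorizations, 5 admissible mixing values each:
        the transformed solution keeps the Frobenius objective to 1e-10
        relative and satisfies the simplex and open-box constraints."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            M, R, O = make_random_factorization(rng)
            c_max, _ = admissible_c_max(M)
            base = np.linalg.norm(O - M @ R.T) ** 2
            for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
                sol = b.construct_equivalent_solution(M, R, frac * c_max)
                new = np.linalg.norm(O - sol.M_tilde @ sol.R_tilde.T) ** 2
                assert abs(new - base) <= 1e-10 * base
                np.testing.assert_allclose(sol.R_tilde.sum(axis=1), 1.0, atol=1e-12)
                assert sol.R_tilde.min() >= -1e-15
                assert 0 < sol.M_tilde.min() and sol.M_tilde.max() < 1

    def test_transform_differs_from_original(self):
        rng = np.random.default_rng(6)
        M, R, O = make_random_factorization(rng)
        c_max, _ = admissible_c_max(M)
        sol = b.construct_equivalent_solution(M, R, 0.5 * c_max)
        assert np.linalg.norm(sol.R_tilde - R) > 1e-3

    def test_small_c_limit_approaches_identity(self):
        rng = np.random.default_rng(7)
        M, R, _ = make_random_factorization(rng)
        sol = b.construct_equivalent_solution(M, R, 1e-10)
        np.testing.assert_allclose(sol.Q, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(sol.R_tilde, R, atol=1e-9)

    def test_out_of_range_c_reports_bound(self):
        rng = np.random.default_rng(8)
        M, R, _ = make_random_factorization(rng)
        c_max, _ = admissible_c_max(M)
        with pytest.raises(b.ValidationError, match="admissible") as exc:
            b.construct_equivalent_solution(M, R, c_max + 0.5)
        assert f"{c_max:.4f}"[:5] in str(exc.value)

    def test_identical_columns_are_degenerate(self):
        rng = np.random.default_rng(9)
        M, R, _ = make_random_factorization(rng)
        M[:, 1] = M[:, 0]
        with pytest.raises(b.ValidationError, match="indistinguishable"):
            b.construct_equivalent_solution(M, R, 0.1)

    def test_first_bound_already_admissible_when_columns_differ(self):
        """Whenever the first two profile columns differ at any site, one
        of the two ratio bounds at that site is below 1, so the primary
        bound is always in (0,1) and the column-swap branch is a safety
        net only."""
        rng = np.random.default_rng(10)
        for _ in range(50):
            M, R, O = make_random_factorization(rng)
            M[:, 0] = np.clip(M[:, 1] + rng.uniform(0.01, 0.2), 0.01, 0.99)
            c_max, swapped = admissible_c_max(M)
            assert not swapped and 0 < c_max < 1
            sol = b.construct_equivalent_solution(M, R, 0.5 * c_max)
            base = np.linalg.norm(O - M @ R.T) ** 2
            new = np.linalg.norm(O - sol.M_tilde @ sol.R_tilde.T) ** 2
            assert abs(new - base) <= 1e-10 * base

    def test_applied_to_an_nnmf_fit(self, k3_dataset):
        """The alternating factorization is non-identifiable: a distinct
        factorization with identical objective exists."""
        M, R, _ = b.fit_nnmf(k3_dataset.O, 3, seed=2, max_rounds=10)
        Ov = k3_dataset.O.to_numpy()  # below the pre-filter size: no filtering
        M_in = np.clip(M, 1e-3, 1 - 1e-3)
        c_max, _ = admissible_c_max(M_in)
        sol = b.construct_equivalent_solution(M_in, R, 0.5 * c_max)
        assert np.linalg.norm(sol.R_tilde - R) > 0
        base = np.linalg.norm(Ov - M_in @ R.T) ** 2
        new = np.linalg.norm(Ov - sol.M_tilde @ sol.R_tilde.T) ** 2
        assert abs(new - base) <= 1e-8 * base

    def test_json_serialization(self, tmp_path):
        rng = np.random.default_rng(11)
        M, R, _ = make_random_factorization(rng)
        sol = b.construct_equivalent_solution(M, R, 0.01)
        sol.to_json(tmp_path / "sol.json")
        assert (tmp_path / "sol.json").stat().st_size > 0
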