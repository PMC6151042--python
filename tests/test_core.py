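import numpy as np
import pandas as pd
import pytest

import bayescce as b
from bayescce.core import _augment, estimate_sigma2
from bayescce.simulator import recover_sigma


class TestEstimateSigma2:
    def test_perfect_fit_returns_zero(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 2))
        coef = rng.normal(size=(4, 3))  # 4 sites x (intercept + 2 scores + ...)
        O = (np.column_stack([np.ones(10), P]) @ coef[:3]).T
        assert estimate_sigma2(O, P) == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        O = rng.uniform(size=(3, 4))
        P = rng.normal(size=(4, 2))
        got = estimate_sigma2(O, P)
        D = np.column_stack([np.ones(4), P])
        beta = np.linalg.solve(D.T @ D, D.T @ O.T)
        expect = float(np.mean((O.T - D @ beta) ** 2))
        assert got == pytest.approx(expect, rel=1e-10)

    def test_recovers_generating_noise_from_estimated_basis(self, k3_shared_dataset):
        ds = k3_shared_dataset
        sites = b.select_informative_sites(ds.O, k=3, t=150)
        basis = b.compute_components(ds.O, sites, d=3)
        s2 = estimate_sigma2(ds.O.loc[list(sites)], basis.P)
        assert s2 == pytest.approx(0.01**2, rel=0.25)

    def test_collinear_design_is_reported(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(8, 2))
        P = np.column_stack([P, P[:, 0]])  # duplicated column
        with pytest.raises(b.ValidationError, match="collinear"):
            estimate_sigma2(rng.uniform(size=(5, 8)), P)


class TestEstimateMFromReference:
    def test_noiseless_interior_recovery(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(0.2, 0.8, size=(30, 3))
        R0 = rng.dirichlet([3.0, 2.0, 2.0], size=8)
        M_hat = b.estimate_M_from_reference(M @ R0.T, R0)
        assert np.abs(M_hat - M).max() < 1e-6

    def test_matches_box_grid_search_when_optimum_clips(self):
        """1-site, k=2, n0=3 toy whose unconstrained optimum falls outside
        [0,1]; a dense grid over the box is the oracle."""
        R0 = np.array([[0.8, 0.2], [0.6, 0.4], [0.9, 0.1]])
        y = np.array([1.05, 0.95, 1.1])  # pushes the estimate past 1
        M_hat = b.estimate_M_from_reference(y[None, :], R0)[0]
        grid = np.arange(0.0, 1.0001, 0.001)
        G1, G2 = np.meshgrid(grid, grid, indexing="ij")
        vals = ((y[None, None, :] - (G1[..., None] * R0[:, 0] + G2[..., None] * R0[:, 1])) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert np.all(np.abs(M_hat - [grid[i], grid[j]]) <= 0.001 + 1e-9)

    def test_estimates_stay_in_box(self):
        rng = np.random.default_rng(4)
        R0 = rng.dirichlet(np.ones(3), size=6)
        O0 = rng.uniform(-0.2, 1.2, size=(20, 6))
        M_hat = b.estimate_M_from_reference(O0, R0)
        assert M_hat.min() >= 0 and M_hat.max() <= 1

    def test_underdetermined_raises(self):
        with pytest.raises(b.ValidationError, match="underdetermined"):
            b.estimate_M_from_reference(np.zeros((5, 2)), np.full((2, 3), 1 / 3))

    def test_rank_deficient_warns(self):
        R0 = np.tile([0.5, 0.3, 0.2], (5, 1))
        with pytest.warns(UserWarning, match="rank deficient"):
            b.estimate_M_from_reference(np.full((4, 5), 0.4), R0)


@pytest.fixture(scope="module")
def k3_fit(k3_dataset, k3_basis):
    O_trunc = k3_dataset.O.loc[list(k3_basis.selected_sites)]
    prior = b.estimate_noisy_prior(b.WHOLE_BLOOD_K3, 50, seed=40)
    return b.fit_bayescce(
        k3_basis, O_trunc, prior, options=b.SolverOptions(n_starts=2, seed=1)
    )


class TestFitBayesCCE:
    def test_constraints_satisfied(self, k3_fit):
        R = k3_fit.R_hat.to_numpy()
        assert R.min() >= 1e-4 - 1e-12
        assert np.abs(R.sum(axis=1) - 1.0).max() <= 0.05 + 1e-9

    def test_objective_not_worse_than_start(self, k3_fit):
        assert k3_fit.objective <= k3_fit.start_objective + 1e-6

    def test_components_beat_raw_scores(self, k3_dataset, k3_basis, k3_fit):
        _, _, mac_fit = b.match_and_mac(k3_fit.R_hat, k3_dataset.R_true)
        _, _, mac_raw = b.match_and_mac(k3_basis.P[:, :3], k3_dataset.R_true)
        assert mac_fit > mac_raw

    def test_assignment_flagged_heuristic(self, k3_fit):
        assert k3_fit.assignment_is_heuristic
        assert set(k3_fit.assignment.values()) == set(b.WHOLE_BLOOD_K3.cell_type_names)

    def test_noninformative_prior_cannot_worsen_start(self, k3_dataset, k3_basis):
        O_trunc = k3_dataset.O.loc[list(k3_basis.selected_sites)]
        fit = b.fit_bayescce(
            k3_basis, O_trunc, b.uniform_prior(3),
            options=b.SolverOptions(n_starts=1, seed=2),
        )
        assert fit.objective <= fit.start_objective + 1e-6

    def test_sample_permutation_equivariance(self, k3_dataset):
        O = k3_dataset.O
        rng = np.random.default_rng(9)
        perm = rng.permutation(O.shape[1])
        opts = b.SolverOptions(n_starts=1, seed=3, jitter=0.0)
        prior = b.WHOLE_BLOOD_K3
        sites = b.select_informative_sites(O, k=3, t=100)
        basis = b.compute_components(O, sites, d=3)
        fit = b.fit_bayescce(basis, O.loc[sites], prior, options=opts)
        O_p = O.iloc[:, perm]
        basis_p = b.compute_components(O_p, sites, d=3)
        fit_p = b.fit_bayescce(basis_p, O_p.loc[sites], prior, options=opts)
        np.testing.assert_allclose(
            fit_p.R_hat.to_numpy(),
            fit.R_hat.to_numpy()[perm],
            atol=2e-4,
        )

    def test_solvers_agree_on_small_instance(self, k3_shared_dataset):
        ds = k3_shared_dataset
        sites = b.select_informative_sites(ds.O, k=3, t=100)
        basis = b.compute_components(ds.O, sites, d=3)
        O_trunc = ds.O.loc[list(sites)]
        prior = b.WHOLE_BLOOD_K3
        f_bar = b.fit_bayescce(
            basis, O_trunc, prior, options=b.SolverOptions(n_starts=1, seed=4)
        )
        f_tc = b.fit_bayescce(
            basis, O_trunc, prior,
            options=b.SolverOptions(n_starts=1, seed=4, solver="trust-constr",
                                    gtol=1e-5, xtol=1e-8),
        )
        assert f_bar.objective == pytest.approx(f_tc.objective, rel=1e-3)

    def test_shape_mismatch_raises(self, k3_dataset, k3_basis):
        with pytest.raises(b.ValidationError):
            b.fit_bayescce(k3_basis, k3_dataset.O.iloc[:10], b.WHOLE_BLOOD_K3)

    def test_small_d_warns(self, k3_shared_dataset):
        ds = k3_shared_dataset
        sites = b.select_informative_sites(ds.O, k=3, t=80)
        basis = b.compute_components(ds.O, sites, d=2)
        with pytest.warns(UserWarning, match="span"):
            b.fit_bayescce(basis, ds.O.loc[list(sites)], b.WHOLE_BLOOD_K3,
                           options=b.SolverOptions(n_starts=1, max_iter=50))


@pytest.fixture(scope="module")
def impute_setting(k3_shared_dataset):
    ds = k3_shared_dataset
    sites = b.select_informative_sites(ds.O, k=3, t=150)
    ref_ids = list(ds.R_true.index[:10])
    imp = b.ImputationInput(R0=ds.R_true.loc[ref_ids])
    basis = b.feasible_impute_basis(ds.O, sites, imp, d_start=3)
    O_trunc = ds.O.loc[list(sites)]
    return ds, basis, O_trunc, imp, ref_ids


class TestFitBayesCCEImpute:
    def test_reference_rows_match_measured_counts(self, impute_setting):
        ds, basis, O_trunc, imp, ref_ids = impute_setting
        fit = b.fit_bayescce_impute(
            basis, O_trunc, b.WHOLE_BLOOD_K3, imp,
            options=b.SolverOptions(n_starts=1, seed=5),
        )
        dev = np.abs(
            fit.R_hat.loc[ref_ids].to_numpy() - ds.R_true.loc[ref_ids].to_numpy()
        )
        assert dev.max() <= 0.01 + 1e-9
        assert not fit.assignment_is_heuristic

    def test_two_starts_reach_same_objective(self, impute_setting):
        """Stage 2 is convex given these concentration parameters, so
        different random starts must agree."""
        ds, basis, O_trunc, imp, _ = impute_setting
        f1 = b.fit_bayescce_impute(basis, O_trunc, b.WHOLE_BLOOD_K3, imp,
                                   options=b.SolverOptions(n_starts=1, seed=6))
        f2 = b.fit_bayescce_impute(basis, O_trunc, b.WHOLE_BLOOD_K3, imp,
                                   options=b.SolverOptions(n_starts=1, seed=77))
        assert f1.objective == pytest.approx(f2.objective, rel=1e-6)

    def test_fully_observed_limit(self, k3_shared_dataset):
        ds = k3_shared_dataset
        sites = b.select_informative_sites(ds.O, k=3, t=150)
        imp = b.ImputationInput(R0=ds.R_true)
        basis = b.feasible_impute_basis(ds.O, sites, imp, d_start=3)
        fit = b.fit_bayescce_impute(
            basis, ds.O.loc[list(sites)], b.WHOLE_BLOOD_K3, imp,
            options=b.SolverOptions(n_starts=1, seed=7),
        )
        dev = np.abs(fit.R_hat.to_numpy() - ds.R_true.to_numpy())
        assert dev.max() <= 0.01 + 1e-9

    def test_unknown_reference_ids_raise(self, impute_setting):
        ds, basis, O_trunc, _, _ = impute_setting
        bad = b.ImputationInput(
            R0=pd.DataFrame(
                np.full((2, 3), 1 / 3), index=["nope1", "nope2"],
                columns=ds.R_true.columns,
            )
        )
        with pytest.raises(b.ValidationError, match="nope1"):
            b.fit_bayescce_impute(basis, O_trunc, b.WHOLE_BLOOD_K3, bad)

    def test_infeasible_basis_raises(self, k3_dataset):
        """Per-individual biological noise makes the measured-count band
        unreachable from a 2-component basis."""
        ds = k3_dataset
        sites = b.select_informative_sites(ds.O, k=3, t=150)
        basis = b.compute_components(ds.O, sites, d=2)
        imp = b.ImputationInput(R0=ds.R_true.iloc[:10])
        with pytest.raises(b.ValidationError, match="infeasible"):
            b.fit_bayescce_impute(basis, ds.O.loc[list(sites)],
                                  b.WHOLE_BLOOD_K3, imp)

    def test_measured_rows_validated(self, k3_dataset):
        bad = k3_dataset.R_true.iloc[:5] * 1.5
        with pytest.raises(b.ValidationError):
            b.ImputationInput(R0=bad)
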