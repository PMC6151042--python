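import numpy as np
import pandas as pd
import pytest

import bayescce as b


@pytest.fixture()
def random_pair():
    rng = np.random.default_rng(0)
    R_true = rng.dirichlet([2.0, 1.0, 3.0], size=40)
    R_est = R_true + rng.normal(0, 0.05, size=R_true.shape)
    return R_est, R_true


class TestMatchAndMac:
    def test_self_match_is_identity_with_mac_one(self, random_pair):
        _, R_true = random_pair
        perm, per, mac = b.match_and_mac(R_true, R_true)
        assert perm == (0, 1, 2) and mac == pytest.approx(1.0)

    def test_cyclic_shift_recovered(self, random_pair):
        _, R_true = random_pair
        shifted = R_true[:, [1, 2, 0]]
        perm, per, mac = b.match_and_mac(shifted, R_true)
        assert perm == (1, 2, 0) and mac == pytest.approx(1.0)

    def test_hand_computed_anticorrelation(self):
        R_true = np.column_stack([[0.1, 0.2, 0.3, 0.4], [0.9, 0.8, 0.7, 0.6]])
        R_est = np.column_stack([[0.4, 0.3, 0.2, 0.1], [0.6, 0.7, 0.8, 0.9]])
        perm, per, mac = b.match_and_mac(R_est, R_true)
        # Pearson r of (0.4,0.3,0.2,0.1) with (0.1,0.2,0.3,0.4) is exactly -1
        assert per[0] == pytest.approx(1.0) and mac == pytest.approx(1.0)

    def test_permutation_never_hurts(self, random_pair):
        R_est, R_true = random_pair
        shuffled = R_est[:, [2, 0, 1]]
        _, _, mac_perm = b.match_and_mac(shuffled, R_true, allow_permutation=True)
        _, _, mac_id = b.match_and_mac(shuffled, R_true, allow_permutation=False)
        assert mac_perm >= mac_id

    def test_zero_variance_column_warns_not_raises(self, random_pair):
        R_est, R_true = random_pair
        R_est = R_est.copy()
        R_est[:, 1] = 0.25
        with pytest.warns(UserWarning, match="zero-variance"):
            perm, per, mac = b.match_and_mac(R_est, R_true)
        assert np.isfinite(mac)

    def test_large_k_uses_hungarian_and_matches_shift(self):
        rng = np.random.default_rng(5)
        R_true = rng.dirichlet(np.ones(9), size=50)
        shifted = np.roll(R_true, 2, axis=1)
        perm, per, mac = b.match_and_mac(shifted, R_true)
        assert mac == pytest.approx(1.0)


class TestMae:
    def test_zero_for_identical(self, random_pair):
        _, R_true = random_pair
        per, mean = b.mae(R_true, R_true)
        assert mean == 0.0

    def test_direct_arithmetic(self):
        truth = np.array([[0.2], [0.4], [0.6]])
        est = np.array([[0.3], [0.5], [0.7]])
        per, mean = b.mae(est, truth)
        assert mean == pytest.approx(0.1)

    def test_invariant_to_sample_order(self, random_pair):
        R_est, R_true = random_pair
        _, m1 = b.mae(R_est, R_true)
        _, m2 = b.mae(R_est[::-1], R_true[::-1])
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_rescaling_maps_affine_estimates_back(self):
        rng = np.random.default_rng(1)
        truth = rng.uniform(size=(30, 1))
        lo, hi = truth.min(), truth.max()
        scaled = 5.0 * truth - 2.0  # affine distortion
        per, mean = b.mae(scaled, (truth - lo) / (hi - lo), rescale=True)
        assert mean < 1e-12

    def test_constant_column_with_rescale_warns(self):
        truth = np.linspace(0, 1, 10)[:, None]
        est = np.full((10, 1), 0.5)
        with pytest.warns(UserWarning, match="unscaled"):
            b.mae(est, truth, rescale=True)


class TestExplainedVariance:
    def test_perfect_predictor(self, random_pair):
        _, R_true = random_pair
        r2 = b.explained_variance_per_celltype(R_true, R_true)
        np.testing.assert_allclose(r2, 1.0, atol=1e-10)

    def test_orthogonal_predictor_explains_nothing(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(50, 1))
        X = rng.normal(size=(50, 2))
        # residualise y against X (and intercept) to construct orthogonality
        D = np.column_stack([np.ones(50), X])
        y_res = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        r2 = b.explained_variance_per_celltype(X, y_res)
        assert r2[0] < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=(5, 1))
        r2 = b.explained_variance_per_celltype(X, y)
        D = np.column_stack([np.ones(5), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        resid = y - D @ beta
        expect = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2[0] == pytest.approx(expect, abs=1e-10)

    def test_joint_r2_at_least_best_single_component(self, random_pair):
        R_est, R_true = random_pair
        perm, per, _ = b.match_and_mac(R_est, R_true)
        r2 = b.explained_variance_per_celltype(R_est, R_true)
        for est_col, true_col in enumerate(perm):
            assert r2[true_col] >= per[est_col] ** 2 - 1e-10


class TestEvaluateReport:
    def test_report_is_consistent_and_serializable(self, tmp_path, random_pair):
        R_est, R_true = random_pair
        rep = b.evaluate(R_est, R_true)
        assert rep.mac == pytest.approx(np.mean(rep.per_cell_type_abs_corr))
        assert sorted(rep.permutation) == [0, 1, 2]
        rep.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists()
        assert "mean" in rep.to_table()

    def test_reference_samples_are_excluded(self, random_pair):
        R_est, R_true = random_pair
        ids = [f"S{i}" for i in range(len(R_true))]
        est = pd.DataFrame(R_est, index=ids)
        tru = pd.DataFrame(R_true, index=ids)
        rep = b.evaluate(est, tru, exclude_samples=("S0", "S1"))
        assert rep.excluded_samples == ("S0", "S1")
        manual = b.evaluate(est.iloc[2:], tru.iloc[2:])
        assert rep.mac == pytest.approx(manual.mac)

    def test_metrics_invariant_under_joint_reordering(self, random_pair):
        R_est, R_true = random_pair
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(R_true))
        r1 = b.evaluate(R_est, R_true)
        r2 = b.evaluate(R_est[perm], R_true[perm])
        assert r1.mac == pytest.approx(r2.mac, rel=1e-10)
        assert r1.mae == pytest.approx(r2.mae, rel=1e-10)
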