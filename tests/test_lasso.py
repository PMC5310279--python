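import numpy as np
import pytest

from coxsislasso import (SurvivalDataset, cv_select_lambda, fit_cox,
                         fit_lasso_path, kkt_residuals, lambda_max,
                         lasso_select, simulate_dataset, strong_signal_config)

from conftest import random_survival


@pytest.fixture(scope="module")
def mid_ds():
    return simulate_dataset(strong_signal_config(
        n=80, p=20, n_active=3, censoring=0.25, seed=21)).dataset


def test_solution_is_zero_at_and_above_lambda_max(mid_ds):
    lm = lambda_max(mid_ds)
    path = fit_lasso_path(mid_ds, lambdas=np.array([lm * 1.01, lm * 0.999]))
    assert path.nonzero_counts[0] == 0
    # just below the boundary at most one coefficient activates
    assert path.nonzero_counts[1] <= 1


def test_lambda_max_invariant_to_duplicated_covariate(mid_ds):
    ds2 = SurvivalDataset(
        X=np.column_stack([mid_ds.X, mid_ds.X[:, 0]]),
        time=mid_ds.time, event=mid_ds.event,
        feature_ids=mid_ds.feature_ids + ["dup"],
        sample_ids=mid_ds.sample_ids)
    assert lambda_max(ds2) == pytest.approx(lambda_max(mid_ds), rel=1e-12)


def test_every_path_solution_satisfies_kkt(mid_ds):
    path = fit_lasso_path(mid_ds, n_lambda=40)
    assert np.all(np.diff(path.lambdas) < 0)
    for li, lam in enumerate(path.lambdas):
        slack_zero, stat_active = kkt_residuals(mid_ds, lam, path.coefs_std[li])
        assert slack_zero.max(initial=0.0) <= 1e-5
        assert stat_active.max(initial=0.0) <= 1e-5


def test_small_lambda_limit_recovers_unpenalized_mle():
    ds = simulate_dataset(strong_signal_config(
        n=100, p=3, n_active=2, censoring=0.2, seed=22)).dataset
    path = fit_lasso_path(ds, n_lambda=40, lambda_min_ratio=1e-6)
    mle = fit_cox(ds)
    assert np.max(np.abs(path.coefs[-1] - mle.beta)) < 1e-3


def test_scale_equivariance_of_reported_coefficients(mid_ds):
    c = 7.0
    X2 = mid_ds.X.copy()
    X2[:, 3] *= c
    ds2 = SurvivalDataset(X=X2, time=mid_ds.time, event=mid_ds.event,
                          feature_ids=mid_ds.feature_ids,
                          sample_ids=mid_ds.sample_ids)
    p1 = fit_lasso_path(mid_ds, n_lambda=20)
    p2 = fit_lasso_path(ds2, lambdas=p1.lambdas)
    np.testing.assert_allclose(p2.coefs[:, 3], p1.coefs[:, 3] / c,
                               rtol=1e-8, atol=1e-12)


def test_path_matches_independent_coxnet_solver(mid_ds):
    """Cross-check against the glmnet-family solver in scikit-survival."""
    sksurv = pytest.importorskip("sksurv.linear_model")
    from sksurv.util import Surv

    path = fit_lasso_path(mid_ds, n_lambda=25, lambda_min_ratio=0.05)
    Xstd = (mid_ds.X - mid_ds.X.mean(0)) / mid_ds.X.std(0)
    y = Surv.from_arrays(event=mid_ds.event.astype(bool), time=mid_ds.time)
    m = sksurv.CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=path.lambdas,
                                      normalize=False, tol=1e-9,
                                      fit_baseline_model=False)
    m.fit(Xstd, y)
    assert np.max(np.abs(m.coef_.T - path.coefs_std)) < 5e-4


class TestCV:
    def test_deterministic_and_aligned(self, mid_ds):
        cv1 = cv_select_lambda(mid_ds, n_folds=5, seed=3, n_lambda=30)
        cv2 = cv_select_lambda(mid_ds, n_folds=5, seed=3, n_lambda=30)
        np.testing.assert_array_equal(cv1.fold_ids, cv2.fold_ids)
        assert cv1.lambda_selected == cv2.lambda_selected
        assert len(cv1.cv_deviance) == len(cv1.lambdas) == 30
        assert len(cv1.cv_se) == 30
        assert cv1.lambda_selected in cv1.lambdas

    def test_different_seed_changes_folds(self, mid_ds):
        cv1 = cv_select_lambda(mid_ds, n_folds=5, seed=3, n_lambda=20)
        cv2 = cv_select_lambda(mid_ds, n_folds=5, seed=4, n_lambda=20)
        assert not np.array_equal(cv1.fold_ids, cv2.fold_ids)

    def test_folds_stratified_by_event(self, mid_ds):
        cv = cv_select_lambda(mid_ds, n_folds=5, seed=0, n_lambda=10)
        counts = [mid_ds.event[cv.fold_ids == k].sum() for k in range(5)]
        assert min(counts) >= 1
        assert max(counts) - min(counts) <= 1

    def test_fold_count_validation(self, mid_ds):
        with pytest.raises(ValueError, match="n_folds"):
            cv_select_lambda(mid_ds, n_folds=2)
        with pytest.raises(ValueError, match="n_folds"):
            cv_select_lambda(mid_ds, n_folds=10 ** 6)

    def test_one_se_rule_selects_no_smaller_lambda(self, mid_ds):
        cv_min = cv_select_lambda(mid_ds, n_folds=5, seed=1, n_lambda=25)
        cv_1se = cv_select_lambda(mid_ds, n_folds=5, seed=1, n_lambda=25,
                                  rule="1se")
        assert cv_1se.lambda_selected >= cv_min.lambda_selected


def test_lasso_select_recovers_strong_signal_and_is_deterministic():
    sim = simulate_dataset(strong_signal_config(
        n=200, p=50, n_active=3, censoring=0.25, seed=23))
    sel1 = lasso_select(sim.dataset, n_folds=5, seed=2, n_lambda=40,
                        lambda_min_ratio=0.05)
    sel2 = lasso_select(sim.dataset, n_folds=5, seed=2, n_lambda=40,
                        lambda_min_ratio=0.05)
    np.testing.assert_array_equal(sel1, sel2)
    assert set(sim.truth.support) <= set(sel1.tolist())


def test_constant_covariate_rejected():
    ds = random_survival(30, 2, seed=1)
    ds.X[:, 1] = 4.2
    with pytest.raises(ValueError, match="constant"):
        lambda_max(ds)
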