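import numpy as np
import pytest

from coxsislasso import (CoxSingularError, SurvivalDataset, concordance,
                         fit_cox, format_report, generalized_r2,
                         partial_loglik, wald_report)

from conftest import random_survival


def _two_group(n=50, seed=0):
    """Binary covariate with a genuine group effect on exponential times."""
    rng = np.random.default_rng(seed)
    x = (np.arange(n) % 2).astype(float)
    time = rng.exponential(scale=np.exp(-0.8 * x)) + 1e-4
    return SurvivalDataset(
        X=x[:, None], time=time, event=np.ones(n, dtype=int),
        feature_ids=["grp"], sample_ids=[f"s{i}" for i in range(n)])


def test_null_loglik_is_sum_of_log_risk_set_sizes():
    ds = random_survival(3, 2, seed=1, censor_frac=0.0)
    ll, grad = partial_loglik(ds, None, np.zeros(2))
    assert ll == pytest.approx(-np.log(6), abs=1e-12)
    # general form: -sum over events of log |R_k|
    ds2 = random_survival(25, 3, seed=2)
    order = np.argsort(ds2.time)
    sizes = [np.sum(ds2.time >= t) for t, e in
             zip(ds2.time[order], ds2.event[order]) if e == 1]
    ll2, _ = partial_loglik(ds2, None, np.zeros(3))
    assert ll2 == pytest.approx(-np.sum(np.log(sizes)), rel=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_gradient_matches_central_finite_differences(seed):
    ds = random_survival(20, 3, seed=seed)
    rng = np.random.default_rng(seed + 100)
    beta = rng.normal(scale=0.5, size=3)
    _, grad = partial_loglik(ds, None, beta)
    h = 1e-5
    for j in range(3):
        e = np.eye(3)[j] * h
        fd = (partial_loglik(ds, None, beta + e)[0]
              - partial_loglik(ds, None, beta - e)[0]) / (2 * h)
        assert abs(fd - grad[j]) <= 1e-6 * max(abs(fd), 1.0)


def test_fit_gradient_vanishes_and_beats_null():
    ds = random_survival(40, 3, seed=3)
    fit = fit_cox(ds)
    assert fit.converged
    _, grad = partial_loglik(ds, None, fit.beta)
    assert np.max(np.abs(grad)) < 1e-6
    assert fit.loglik >= fit.loglik_null


def test_single_covariate_fit_matches_bruteforce_maximizer():
    ds = _two_group()
    fit = fit_cox(ds)
    # golden-section search over the same partial likelihood
    f = lambda b: partial_loglik(ds, [0], [b])[0]
    lo, hi = -5.0, 5.0
    inv = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - inv * (b - a), a + inv * (b - a)
    for _ in range(200):
        if f(c) > f(d):
            b, d = d, c
            c = b - inv * (b - a)
        else:
            a, c = c, d
            d = a + inv * (b - a)
    assert abs(fit.beta[0] - (a + b) / 2) < 1e-4


def test_multivariate_fit_matches_lifelines():
    """Independent solver cross-check (no tied times, so tie conventions
    coincide)."""
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    ds = random_survival(80, 4, seed=13)
    fit = fit_cox(ds)
    df = pd.DataFrame(ds.X, columns=ds.feature_ids)
    df["T"], df["E"] = ds.time, ds.event
    cph = lifelines.CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)
    np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-5)
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_empty_feature_set_is_null_model():
    ds = random_survival(20, 2, seed=4)
    fit = fit_cox(ds, [])
    assert fit.loglik == fit.loglik_null
    assert fit.beta.size == 0


def test_duplicate_feature_raises_singularity():
    ds = random_survival(30, 2, seed=5)
    ds2 = SurvivalDataset(X=np.column_stack([ds.X[:, 0], ds.X[:, 0]]),
                          time=ds.time, event=ds.event,
                          feature_ids=["a", "a_copy"],
                          sample_ids=ds.sample_ids)
    with pytest.raises(CoxSingularError, match="a"):
        fit_cox(ds2)


def test_loglik_invariant_to_covariate_rescaling():
    ds = random_survival(40, 2, seed=6)
    fit = fit_cox(ds)
    ds_scaled = SurvivalDataset(X=ds.X * np.array([10.0, 0.2]),
                                time=ds.time, event=ds.event,
                                feature_ids=ds.feature_ids,
                                sample_ids=ds.sample_ids)
    fit2 = fit_cox(ds_scaled)
    assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)
    np.testing.assert_allclose(fit2.beta, fit.beta / [10.0, 0.2], rtol=1e-6)


def test_identifiability_guard_and_constant_column():
    with pytest.raises(ValueError, match="identifiability|events"):
        fit_cox(random_survival(6, 8, seed=8, censor_frac=0.0), None)
    dsc = SurvivalDataset(X=np.ones((20, 1)), time=np.arange(1, 21.0),
                          event=np.ones(20, int), feature_ids=["const"],
                          sample_ids=[f"s{i}" for i in range(20)])
    with pytest.raises(ValueError, match="constant"):
        fit_cox(dsc)


class TestWald:
    def test_null_coefficient(self):
        fit = fit_cox(random_survival(30, 1, seed=9), [0])
        fit.beta = np.array([0.0])
        w = wald_report(fit)
        assert w.z[0] == 0 and w.p_value[0] == 1 and w.hazard_ratio[0] == 1

    def test_z_quantile(self):
        fit = fit_cox(random_survival(30, 1, seed=9), [0])
        fit.beta, fit.se = np.array([1.959964]), np.array([1.0])
        assert wald_report(fit).p_value[0] == pytest.approx(0.05, abs=1e-6)

    def test_agrees_with_independent_cdf(self):
        from scipy.stats import norm
        ds = random_survival(200, 1, seed=10)
        fit = fit_cox(ds)
        w = wald_report(fit)
        expected = 2 * norm.cdf(-abs(fit.beta[0] / fit.se[0]))
        assert w.p_value[0] == pytest.approx(expected, abs=1e-10)


class TestConcordance:
    def test_perfect_and_constant(self):
        t = np.array([3.0, 1.0, 2.0, 5.0])
        e = np.ones(4, int)
        assert concordance(-t, t, e) == 1.0
        assert concordance(np.zeros(4), t, e) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        s = rng.normal(size=n)
        t = rng.exponential(size=n) + 1e-3
        e = rng.integers(0, 2, n); e[:2] = 1
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if t[i] < t[j] and e[i] == 1:
                    den += 1
                    num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
        assert concordance(s, t, e) == num / den

    def test_sign_flip_complements(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=25)
        t = rng.exponential(size=25) + 1e-3
        e = np.ones(25, int)
        assert concordance(-s, t, e) == pytest.approx(
            1 - concordance(s, t, e), abs=1e-12)

    def test_no_permissible_pairs_raises(self):
        with pytest.raises(ValueError, match="permissible"):
            concordance([1.0, 2.0], [1.0, 2.0], [0, 1])


def test_generalized_r2_closed_forms():
    ds = random_survival(40, 2, seed=11)
    fit = fit_cox(ds)
    assert generalized_r2(fit) == pytest.approx(
        1 - np.exp(-2 / 40 * (fit.loglik - fit.loglik_null)), abs=1e-14)
    fit.loglik = fit.loglik_null
    assert generalized_r2(fit) == 0
    fit.loglik = fit.loglik_null + fit.n_samples / 2
    assert generalized_r2(fit) == pytest.approx(1 - np.exp(-1), abs=1e-12)


def test_format_report_layout():
    ds = random_survival(60, 2, seed=12)
    fit = fit_cox(ds)
    txt = format_report(fit, r2=0.33, concordance_value=0.7)
    assert "coef" in txt and "exp(coef)" in txt and "p-value" in txt
    assert "R^2 = 0.330, Concordance = 0.700" in txt
    assert "Significance codes" in txt
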