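import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coxsislasso import (auc_over_time, simulate_dataset, SimulationConfig,
                         time_dependent_roc, train_test_split)


def _uncensored(n, seed):
    rng = np.random.default_rng(seed)
    s = rng.normal(size=n)
    t = rng.exponential(size=n) + 1e-3
    return s, t, np.ones(n, dtype=int)


def _pairwise_auc(s, t, e, at):
    case = (t <= at) & (e == 1)
    ctrl = t > at
    vals = [(s[i] > s[j]) + 0.5 * (s[i] == s[j])
            for i in np.flatnonzero(case) for j in np.flatnonzero(ctrl)]
    return float(np.mean(vals))


def test_constant_score_gives_half_auc():
    s, t, e = _uncensored(30, 0)
    for est in ("naive", "km_cd"):
        r = time_dependent_roc(np.zeros(30), t, e, np.median(t), estimator=est)
        assert r.auc == pytest.approx(0.5, abs=1e-12)


def test_perfect_separation_gives_auc_one():
    s, t, e = _uncensored(30, 1)
    r = time_dependent_roc(-t, t, e, np.median(t))
    assert r.auc == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(8))
def test_naive_auc_equals_bruteforce_pairwise_and_km_matches(seed):
    s, t, e = _uncensored(40, seed)
    at = np.quantile(t, 0.4)
    r_naive = time_dependent_roc(s, t, e, at, estimator="naive")
    r_km = time_dependent_roc(s, t, e, at, estimator="km_cd")
    assert r_naive.auc == pytest.approx(_pairwise_auc(s, t, e, at), abs=1e-12)
    assert r_km.auc == pytest.approx(r_naive.auc, abs=1e-12)


def test_roc_curve_is_monotone_staircase():
    rng = np.random.default_rng(5)
    s = rng.normal(size=60)
    t = rng.exponential(size=60) + 1e-3
    e = rng.integers(0, 2, 60); e[:5] = 1
    r = time_dependent_roc(s, t, e, np.median(t))
    assert np.all(np.diff(r.sensitivity) >= -1e-12)
    assert np.all(np.diff(r.one_minus_specificity) >= -1e-12)
    assert (r.sensitivity[0], r.one_minus_specificity[0]) == (0, 0)
    assert (r.sensitivity[-1], r.one_minus_specificity[-1]) == (1, 1)
    assert 0 <= r.auc <= 1


def test_sign_flip_complements_auc_without_ties():
    s, t, e = _uncensored(35, 7)
    at = np.median(t)
    a1 = time_dependent_roc(s, t, e, at).auc
    a2 = time_dependent_roc(-s, t, e, at).auc
    assert a2 == pytest.approx(1 - a1, abs=1e-12)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_auc_invariant_under_monotone_transform(seed):
    s, t, e = _uncensored(25, seed)
    at = np.median(t)
    a1 = time_dependent_roc(s, t, e, at).auc
    a2 = time_dependent_roc(np.exp(2 * s) + 1, t, e, at).auc
    assert a2 == pytest.approx(a1, abs=1e-12)


def test_errors_state_missing_group():
    s, t, e = _uncensored(10, 3)
    e[np.argmin(t)] = 0  # the earliest observation is censored
    with pytest.raises(ValueError, match="no cases"):
        time_dependent_roc(s, t, e, t.min())
    with pytest.raises(ValueError, match="no controls"):
        time_dependent_roc(s, t, e, t.max())


def test_auc_over_time_matches_pointwise_and_flags_unusable():
    sim = simulate_dataset(SimulationConfig(
        n=80, p=3, support=(0,), beta_true=(1.0,),
        censoring_rate_target=0.3, seed=4))
    ds = sim.dataset
    scores = ds.X[:, 0]
    grid = np.quantile(ds.time[ds.event == 1], [0.25, 0.5, 0.75])
    curve = auc_over_time(scores, ds.time, ds.event, grid)
    for i, t in enumerate(curve.t_grid):
        assert curve.auc[i] == time_dependent_roc(scores, ds.time, ds.event,
                                                  t).auc
    # a grid point outside the usable range is reported missing, not fatal
    grid2 = np.r_[ds.time.min() / 2, grid]
    curve2 = auc_over_time(scores, ds.time, ds.event, grid2)
    assert np.isnan(curve2.auc[0]) and float(grid2[0]) in curve2.reasons


def test_km_correction_changes_auc_under_censoring_only():
    sim = simulate_dataset(SimulationConfig(
        n=120, p=2, support=(0,), beta_true=(1.2,),
        censoring_rate_target=0.4, seed=9))
    ds = sim.dataset
    at = np.quantile(ds.time[ds.event == 1], 0.6)
    naive = time_dependent_roc(ds.X[:, 0], ds.time, ds.event, at, "naive")
    km = time_dependent_roc(ds.X[:, 0], ds.time, ds.event, at, "km_cd")
    assert naive.auc != km.auc  # weights actually engage


class TestSplit:
    def test_partition_contract(self, small_sim):
        tr, te = train_test_split(small_sim.dataset, n_train=80, seed=0)
        assert tr.n == 80 and te.n == small_sim.dataset.n - 80
        assert not set(tr.sample_ids) & set(te.sample_ids)
        assert set(tr.sample_ids) | set(te.sample_ids) == \
            set(small_sim.dataset.sample_ids)

    def test_seeded_determinism(self, small_sim):
        tr1, _ = train_test_split(small_sim.dataset, 60, seed=5)
        tr2, _ = train_test_split(small_sim.dataset, 60, seed=5)
        assert tr1.sample_ids == tr2.sample_ids

    def test_size_validation(self, small_sim):
        with pytest.raises(ValueError):
            train_test_split(small_sim.dataset, 1, seed=0)
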