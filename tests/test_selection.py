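import math

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor

from keraspec import selection as sel


def _linear_data(rng, n=30, p=6, informative=(0,), noise=0.0):
    X = rng.normal(size=(n, p))
    y = sum(X[:, j] for j in informative) + rng.normal(size=n) * noise
    cols = [f"d{j + 1}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y, [cols[j] for j in informative]


# -- retention schedule -----------------------------------------------------

def test_schedule_from_902_follows_ceiling_recursion():
    sizes = sel.retention_schedule(902)
    assert sizes[:4] == [902, 812, 731, 658]
    # independent arithmetic oracle
    oracle = [902]
    while True:
        nxt = min(oracle[-1] - 1, math.ceil(0.9 * oracle[-1]))
        if nxt < 2:
            break
        oracle.append(nxt)
    assert sizes == oracle
    assert sizes[-1] == 2


def test_half_retention_of_four_descriptors():
    assert sel.retention_schedule(4, retention=0.5) == [4, 2]


def test_schedule_always_decreases():
    for p in (2, 3, 9, 10, 11, 37):
        sizes = sel.retention_schedule(p)
        assert all(b < a for a, b in zip(sizes, sizes[1:]))


# -- repeated CV ------------------------------------------------------------

def test_constant_response_is_an_error(rng):
    X, _, _ = _linear_data(rng)
    spec = sel.ModelSpec(algo="plsr", seed=0)
    with pytest.raises(ValueError, match="constant"):
        sel.repeated_cv_evaluate(spec, X, np.ones(30), k=5, repeats=2)


def test_too_few_samples_for_folds(rng):
    X, y, _ = _linear_data(rng, n=5)
    spec = sel.ModelSpec(algo="plsr", seed=0)
    with pytest.raises(ValueError, match="folds"):
        sel.repeated_cv_evaluate(spec, X, y, k=10, repeats=1)


def test_noiseless_linear_relation_recovered_by_plsr(rng):
    X, y, _ = _linear_data(rng, n=40, p=1, informative=(0,))
    spec = sel.ModelSpec(algo="plsr", seed=1)
    result = sel.repeated_cv_evaluate(spec, X, y, k=10, repeats=3)
    assert result.r2_mean >= 0.999


def test_pooled_r2_matches_logged_predictions(rng):
    X, y, _ = _linear_data(rng, n=20, p=4, informative=(0, 1), noise=0.4)
    spec = sel.ModelSpec(algo="plsr", seed=3)
    result = sel.repeated_cv_evaluate(spec, X, y, k=10, repeats=2,
                                      keep_predictions=True)
    for r, frame in enumerate(result.predictions):
        sse = ((frame.y_true - frame.y_pred) ** 2).sum()
        sst = ((frame.y_true - frame.y_true.mean()) ** 2).sum()
        assert result.repeat_metrics["r2"].iloc[r] == \
            pytest.approx(1 - sse / sst, abs=1e-12)
        assert result.repeat_metrics["rmse"].iloc[r] == \
            pytest.approx(np.sqrt(sse / len(frame)), abs=1e-12)


def test_cv_result_reproducible_for_fixed_seed(rng):
    X, y, _ = _linear_data(rng, n=25, p=5, noise=0.3)
    spec = sel.ModelSpec(algo="rf", n_trees=20, importance="impurity",
                         seed=11)
    a = sel.repeated_cv_evaluate(spec, X, y, k=5, repeats=2)
    b = sel.repeated_cv_evaluate(spec, X, y, k=5, repeats=2)
    assert a.r2_mean == b.r2_mean
    pd.testing.assert_series_equal(a.importance_mean, b.importance_mean)


# -- RF permutation importance ---------------------------------------------

def test_response_copy_dominates_importance(rng):
    n = 60
    X = rng.normal(size=(n, 5))
    y = X[:, 2].copy()
    model = RandomForestRegressor(n_estimators=100, random_state=0)
    model.fit(X[:40], y[:40])
    imp = sel.rf_permutation_importance(model, X[40:], y[40:],
                                        np.random.default_rng(0))
    assert np.argmax(imp) == 2


def test_constant_column_has_exactly_zero_importance(rng):
    n = 50
    X = rng.normal(size=(n, 4))
    X[:, 3] = 7.0
    y = X[:, 0]
    model = RandomForestRegressor(n_estimators=50, random_state=0)
    model.fit(X[:35], y[:35])
    imp = sel.rf_permutation_importance(model, X[35:], y[35:],
                                        np.random.default_rng(1))
    assert imp[3] == 0.0


def test_noise_columns_have_near_zero_importance(rng):
    n, p = 80, 10
    null_imps = []
    for trial in range(25):
        r = np.random.default_rng(trial)
        X = r.normal(size=(n, p))
        y = 3.0 * X[:, 0] + r.normal(size=n) * 0.1
        model = RandomForestRegressor(n_estimators=60, random_state=trial)
        model.fit(X[:60], y[:60])
        imp = sel.rf_permutation_importance(model, X[60:], y[60:],
                                            np.random.default_rng(trial))
        null_imps.extend(imp[1:])
        assert np.argmax(imp) == 0
    null = np.asarray(null_imps)
    assert abs(null.mean()) <= 2 * null.std(ddof=1) / np.sqrt(null.size) + \
        0.02 * 9.0  # tolerance scaled to var(y)


# -- PLSR importance --------------------------------------------------------

def _fit_pls(X, y, a):
    pls = PLSRegression(n_components=a, scale=False)
    pls.fit(X - X.mean(0), y - y.mean())
    return pls


def test_single_component_importance_tracks_weights(rng):
    X = rng.normal(size=(30, 4))
    y = X[:, 0] + 0.5 * X[:, 1]
    pls = _fit_pls(X, y, 1)
    imp = sel.plsr_importance(pls, 1)
    w = pls.x_weights_[:, 0]
    np.testing.assert_allclose(imp, w ** 2, rtol=1e-9)


def test_duplicate_columns_share_importance(rng):
    base = rng.normal(size=(40, 3))
    X = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 2]])
    y = base[:, 0] + 0.3 * base[:, 1]
    imp = sel.plsr_importance(_fit_pls(X, y, 2), 2)
    assert imp[0] == pytest.approx(imp[1], abs=1e-9)


def test_importance_matches_hand_computed_weighted_sum(rng):
    X = rng.normal(size=(5, 3))
    y = rng.normal(size=5)
    pls = _fit_pls(X, y, 2)
    W = pls.x_weights_[:, :2]
    T = pls.x_scores_[:, :2]
    Q = pls.y_loadings_[0, :2]
    ssy = Q ** 2 * (T ** 2).sum(axis=0)
    expected = (W ** 2) @ (ssy / ssy.sum())
    np.testing.assert_allclose(sel.plsr_importance(pls, 2), expected,
                               rtol=1e-9)


# -- recursive selection ----------------------------------------------------

def test_planted_descriptor_survives_to_the_floor(rng):
    X, y, informative = _linear_data(rng, n=40, p=12, informative=(4,),
                                     noise=0.05)
    spec = sel.ModelSpec(algo="rf", n_trees=60, importance="impurity",
                         seed=5)
    trace = sel.recursive_select(spec, X, y, k=5, repeats=2)
    for step in trace.steps:
        assert informative[0] in step.descriptor_ids
    assert trace.sizes[-1] == 2


def test_trace_sets_are_strictly_nested(rng):
    X, y, _ = _linear_data(rng, n=30, p=20, informative=(0, 1), noise=0.3)
    spec = sel.ModelSpec(algo="plsr", seed=2)
    trace = sel.recursive_select(spec, X, y, k=5, repeats=1)
    assert trace.sizes == sel.retention_schedule(20)
    for a, b in zip(trace.steps, trace.steps[1:]):
        assert set(b.descriptor_ids) < set(a.descriptor_ids)


def test_trace_is_bit_identical_under_fixed_seed(rng):
    X, y, _ = _linear_data(rng, n=25, p=10, informative=(0,), noise=0.2)
    spec = sel.ModelSpec(algo="rf", n_trees=15, importance="impurity",
                         seed=9)
    t1 = sel.recursive_select(spec, X, y, k=5, repeats=2)
    t2 = sel.recursive_select(spec, X, y, k=5, repeats=2)
    assert [s.descriptor_ids for s in t1.steps] == \
        [s.descriptor_ids for s in t2.steps]
    assert [s.result.r2_mean for s in t1.steps] == \
        [s.result.r2_mean for s in t2.steps]


# -- best set and consensus -------------------------------------------------

def _trace_from_r2(r2s, importances=None):
    steps = []
    p = len(r2s) + 8
    for i, r2 in enumerate(r2s):
        ids = tuple(f"d{j}" for j in range(p - i))
        imp = pd.Series(np.linspace(1, 0, len(ids)), index=ids) \
            if importances is None else importances[i]
        steps.append(sel.SelectionStep(ids, sel.CVResult(
            rmse_mean=1.0, rmse_sd=0.0, r2_mean=r2, r2_sd=0.0,
            importance_mean=imp, n_repeats=1, k=2)))
    return sel.SelectionTrace(steps=steps, property="breaking_force_N",
                              algo="rf")


def test_monotone_increasing_r2_selects_last_step():
    trace = _trace_from_r2([0.1, 0.2, 0.3, 0.4])
    ids, result = sel.best_set(trace)
    assert result.r2_mean == 0.4
    assert trace.best_index == 3


def test_tied_maxima_prefer_smaller_set():
    trace = _trace_from_r2([0.5, 0.9, 0.9, 0.2])
    assert trace.best_index == 2


def test_best_index_matches_bruteforce_argmax(rng):
    r2s = rng.uniform(0, 1, size=12).round(6).tolist()
    trace = _trace_from_r2(r2s)
    assert trace.steps[trace.best_index].result.r2_mean == max(r2s)


def test_identical_traces_share_full_consensus():
    trace = _trace_from_r2([0.3, 0.6, 0.5])
    out = sel.consensus_topk(trace, trace, k=5)
    assert len(out.common) == 5


def test_adversarial_orderings_share_nothing():
    ids = tuple(f"d{j}" for j in range(40))
    imp_rf = pd.Series(np.arange(40, dtype=float), index=ids)
    imp_pls = pd.Series(np.arange(40, dtype=float)[::-1], index=ids)
    step_rf = sel.SelectionStep(ids, sel.CVResult(
        1.0, 0.0, 0.5, 0.0, imp_rf, 1, 2))
    step_pls = sel.SelectionStep(ids, sel.CVResult(
        1.0, 0.0, 0.5, 0.0, imp_pls, 1, 2))
    t_rf = sel.SelectionTrace([step_rf], property="p", algo="rf")
    t_pls = sel.SelectionTrace([step_pls], property="p", algo="plsr")
    out = sel.consensus_topk(t_rf, t_pls, k=20)
    assert len(out.common) == 0
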