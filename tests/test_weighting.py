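"""Importance estimation and the w = 1 + lambda * imp**gamma weighting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppcsurv import (
    apply_weights,
    compute_feature_weights,
    compute_mean_abs_shap,
    default_schema,
    encode_cohort,
    fit_normalization,
    fit_preliminary_rf,
    generate_cohort,
    make_config,
    normalize_importance,
)
from ppcsurv.weighting import ImportanceWeights


# -- normalization ----------------------------------------------------------

def test_max_normalization_examples():
    np.testing.assert_allclose(normalize_importance(np.array([2.0, 1.0, 0.0])), [1.0, 0.5, 0.0])
    np.testing.assert_allclose(normalize_importance(np.array([3.0, 3.0])), [1.0, 1.0])
    with pytest.warns(UserWarning):
        np.testing.assert_allclose(normalize_importance(np.zeros(2)), [0.0, 0.0])
    with pytest.raises(ValueError):
        normalize_importance(np.array([1.0, -0.1]))


# -- weight formula ---------------------------------------------------------

def test_weight_formula_anchor_points():
    w = compute_feature_weights(np.array([0.0, 1.0, 0.5]), ("a", "b", "c"))
    assert w.w[0] == 1.0
    assert w.w[1] == pytest.approx(1.27, abs=1e-12)
    oracle = 1.0 + 0.27 * math.exp(0.82 * math.log(0.5))
    assert w.w[2] == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        compute_feature_weights(np.array([1.2]), ("a",))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    imp=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8),
    lam=st.floats(0.0, 3.0),
    gam=st.floats(0.05, 4.0),
)
def test_weight_bounds_and_monotonicity(imp, lam, gam):
    imp = np.asarray(imp)
    names = tuple(f"f{i}" for i in range(imp.size))
    w = compute_feature_weights(imp, names, lam, gam).w
    assert np.all(w >= 1.0) and np.all(w <= 1.0 + lam + 1e-12)
    if lam > 0:
        order = np.argsort(imp)
        assert np.all(np.diff(w[order]) >= -1e-12)  # higher imp, higher w


def test_formula_linear_in_lambda():
    imp = np.array([0.2, 0.7, 1.0])
    names = ("a", "b", "c")
    w1 = compute_feature_weights(imp, names, 0.27, 0.82).w
    w2 = compute_feature_weights(imp, names, 0.54, 0.82).w
    np.testing.assert_allclose(w2 - 1.0, 2.0 * (w1 - 1.0), atol=1e-12)


# -- applying weights -------------------------------------------------------

@pytest.fixture(scope="module")
def encoded_cohort():
    schema = default_schema()
    table = generate_cohort(make_config(200, 0.2, seed=8))
    stats = fit_normalization(table, schema)
    return encode_cohort(table, schema, stats)


def test_apply_weights_identity_at_lambda_zero(encoded_cohort):
    uniform = ImportanceWeights.uniform(encoded_cohort.feature_order)
    out = apply_weights(encoded_cohort, uniform)
    np.testing.assert_array_equal(out.numeric, encoded_cohort.numeric)
    np.testing.assert_array_equal(out.code_weights, np.ones(len(encoded_cohort.code_names)))


def test_apply_weights_elementwise(encoded_cohort):
    d = len(encoded_cohort.feature_order)
    imp = np.zeros(d)
    j = encoded_cohort.numeric_names.index("PR_max")
    imp[j] = 1.0
    weights = compute_feature_weights(imp, encoded_cohort.feature_order)
    out = apply_weights(encoded_cohort, weights)
    np.testing.assert_allclose(out.numeric[:, j], 1.27 * encoded_cohort.numeric[:, j])
    others = [i for i in range(len(encoded_cohort.numeric_names)) if i != j]
    np.testing.assert_array_equal(out.numeric[:, others], encoded_cohort.numeric[:, others])


def test_apply_weights_dimension_mismatch(encoded_cohort):
    with pytest.raises(ValueError):
        apply_weights(encoded_cohort, ImportanceWeights.uniform(("just", "two")))


# -- preliminary forest + SHAP importance -----------------------------------

def test_preliminary_rf_contracts(separable_cohort, schema):
    stats = fit_normalization(separable_cohort, schema)
    enc = encode_cohort(separable_cohort, schema, stats)
    X = enc.matrix()
    rf = fit_preliminary_rf(X, enc.labels, seed=0)
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(enc.labels, rf.predict_proba(X)[:, 1]) > 0.95
    rf2 = fit_preliminary_rf(X, enc.labels, seed=0)
    np.testing.assert_array_equal(rf.predict_proba(X), rf2.predict_proba(X))
    with pytest.raises(ValueError):
        fit_preliminary_rf(np.empty((0, 3)), np.empty(0))
    with pytest.raises(ValueError):
        fit_preliminary_rf(X, np.zeros_like(enc.labels))


def test_mean_abs_shap_nonnegative_and_schema_checked(separable_cohort, schema, rng):
    stats = fit_normalization(separable_cohort, schema)
    enc = encode_cohort(separable_cohort, schema, stats)
    X = enc.matrix()
    rf = fit_preliminary_rf(X, enc.labels, n_trees=30, seed=0)
    raw = compute_mean_abs_shap(rf, X[:100])
    assert raw.shape == (X.shape[1],)
    assert np.all(raw >= 0)
    with pytest.raises(ValueError):
        compute_mean_abs_shap(rf, X[:10, :5])


def test_noise_feature_ranks_low_informative_ranks_first():
    """On a two-informative + noise design the planted feature tops the
    mean-|SHAP| ranking and pure noise stays near the bottom."""
    top_hits = 0
    noise_ranks = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 400
        strong = rng.normal(size=n)
        weak = rng.normal(size=n)
        noise = rng.normal(size=(n, 4))
        logits = 2.5 * strong + 0.6 * weak
        y = (logits + rng.normal(scale=0.8, size=n) > 0).astype(int)
        X = np.column_stack([strong, weak, noise])
        rf = fit_preliminary_rf(X, y, n_trees=60, max_depth=4, seed=seed)
        raw = compute_mean_abs_shap(rf, X)
        order = np.argsort(raw)[::-1]
        top_hits += order[0] == 0
        noise_ranks.append(min(int(np.where(order == j)[0][0]) for j in range(2, 6)))
    assert top_hits >= 9
    assert np.mean(noise_ranks) >= 1.5  # noise never crowds the top of the ranking
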