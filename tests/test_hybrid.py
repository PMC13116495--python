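"""Forest head, threshold optimization, classification and the end-to-end
prediction contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import f1_score, roc_auc_score

from ppcsurv import LABEL_COLUMN, classify, fit_rf_head, optimize_threshold
from ppcsurv.schema import SchemaError


def _bruteforce_best_f1(probs, labels):
    """Exhaustive threshold search: every achievable confusion matrix is
    realized by cutting at some observed probability (predict prob > t)."""
    best = 0.0
    for t in np.concatenate([np.unique(probs), [0.0, 0.5]]):
        pred = (probs > t).astype(int)
        best = max(best, f1_score(labels, pred, zero_division=0))
    return best


def test_rf_head_fits_separable_latents(rng):
    lat = rng.normal(size=(300, 16))
    y = (lat[:, 0] > 0).astype(int)
    rf = fit_rf_head(lat, y, n_trees=200, max_depth=10, seed=0)
    assert roc_auc_score(y, rf.predict_proba(lat)[:, 1]) > 0.99
    rf2 = fit_rf_head(lat, y, n_trees=200, max_depth=10, seed=0)
    np.testing.assert_array_equal(rf.predict_proba(lat), rf2.predict_proba(lat))
    with pytest.raises(ValueError):
        fit_rf_head(lat, np.zeros(300))


def test_threshold_optimizer_example():
    t = optimize_threshold(np.array([0.1, 0.4, 0.6, 0.9]), np.array([0, 0, 1, 1]))
    assert 0.4 < t <= 0.6
    preds = classify(np.array([0.1, 0.4, 0.6, 0.9]), t)
    assert f1_score([0, 0, 1, 1], preds) == 1.0


def test_threshold_optimizer_matches_bruteforce(rng):
    for _ in range(100):
        n = 200
        y = (rng.random(n) < 0.3).astype(int)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        probs = np.clip(rng.normal(0.35 + 0.3 * y, 0.25), 0.001, 0.999)
        t = optimize_threshold(probs, y)
        achieved = f1_score(y, classify(probs, t))
        assert achieved == pytest.approx(_bruteforce_best_f1(probs, y), abs=1e-12)


def test_threshold_ties_break_upward():
    # candidates 0.45 and 0.5 both achieve F1 = 1; the larger must win
    probs = np.array([0.3, 0.6, 0.7])
    labels = np.array([0, 1, 1])
    t = optimize_threshold(probs, labels)
    assert t == pytest.approx(0.5)


def test_threshold_degenerate_probs_warns():
    with pytest.warns(UserWarning):
        t = optimize_threshold(np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1]))
    assert t == 0.5


def test_classification_strict_inequality():
    assert classify(np.array([0.60]), 0.517)[0] == 1
    assert classify(np.array([0.517]), 0.517)[0] == 0
    assert classify(np.array([0.5]), 0.5)[0] == 0
    with pytest.raises(ValueError):
        classify(np.array([0.5]), 1.5)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    probs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
    t1=st.floats(0.01, 0.98),
    dt=st.floats(0.001, 0.5),
)
def test_raising_threshold_never_adds_positives(probs, t1, dt):
    probs = np.asarray(probs)
    t2 = min(t1 + dt, 0.99)
    assert classify(probs, t2).sum() <= classify(probs, t1).sum()


# -- end-to-end prediction contract ----------------------------------------

def test_predict_proba_contracts(trained_model, small_cohort):
    features = small_cohort.drop(columns=[LABEL_COLUMN])
    probs = trained_model.predict_proba(features)
    assert probs.shape == (len(features),)
    assert np.all((probs >= 0) & (probs <= 1))
    # permuting rows permutes outputs identically
    perm = np.random.default_rng(0).permutation(len(features))
    probs_perm = trained_model.predict_proba(features.iloc[perm])
    np.testing.assert_allclose(probs_perm, probs[perm])
    # duplicated patient gets an identical probability
    dup = features.iloc[[5, 5]]
    p = trained_model.predict_proba(dup)
    assert p[0] == p[1]


def test_predict_rejects_schema_violations(trained_model, small_cohort):
    broken = small_cohort.drop(columns=[LABEL_COLUMN]).copy()
    broken.loc[broken.index[0], "Min_SpO2"] = np.nan
    with pytest.raises(SchemaError):
        trained_model.predict_proba(broken)


def test_trained_threshold_in_range(trained_model):
    assert 0.0 < trained_model.threshold < 1.0
    assert trained_model.weights.w.min() >= 1.0
    assert trained_model.weights.w.max() <= 1.0 + trained_model.config.lambda_ + 1e-12


def test_model_round_trip_persistence(tmp_path, trained_model, small_cohort):
    from ppcsurv.persist import load_model, save_model

    features = small_cohort.drop(columns=[LABEL_COLUMN])
    save_model(trained_model, tmp_path / "bundle")
    back = load_model(tmp_path / "bundle")
    np.testing.assert_allclose(
        back.predict_proba(features), trained_model.predict_proba(features)
    )
    assert back.threshold == trained_model.threshold
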