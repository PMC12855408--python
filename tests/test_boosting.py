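"""The three boosters: hand oracles, monotonic losses, symmetries."""

import numpy as np
import pytest

from triboostcardio import AdaBoostModel, CatStyleBooster, LogitBoostModel
from triboostcardio._stumps import Stump, best_classification_stump, best_regression_stump


# ---------------------------------------------------------------------------
# stump search against brute force
# ---------------------------------------------------------------------------

def _brute_force_class_stump(X, y_sign, w):
    """Enumerate every (feature, threshold, polarity); min weighted error."""
    best = (np.inf, None)
    n, d = X.shape
    for j in range(d):
        cand = np.unique(X[:, j])
        thrs = np.concatenate([(cand[:-1] + cand[1:]) / 2, [np.inf]])
        for t in thrs:
            for left, right in ((-1, 1), (1, -1)):
                pred = np.where(X[:, j] <= t, left, right)
                err = float(w[pred != y_sign].sum())
                if err < best[0] - 1e-12:
                    best = (err, (j, t, left, right))
    return best


def test_classification_stump_matches_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(20):
        X = rng.normal(size=(25, 3))
        y = rng.choice([-1.0, 1.0], 25)
        w = rng.random(25)
        w /= w.sum()
        stump, err = best_classification_stump(X, y, w)
        brute_err, _ = _brute_force_class_stump(X, y, w)
        assert err == pytest.approx(brute_err, abs=1e-12)
        pred = stump.predict(X)
        assert float(w[pred != y].sum()) == pytest.approx(err, abs=1e-12)


def test_regression_stump_matches_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(20):
        X = rng.normal(size=(20, 2))
        z = rng.normal(size=20)
        w = rng.random(20) + 0.01
        stump, sse = best_regression_stump(X, z, w)
        best = np.inf
        for j in range(2):
            cand = np.unique(X[:, j])
            thrs = np.concatenate([(cand[:-1] + cand[1:]) / 2, [np.inf]])
            for t in thrs:
                left = X[:, j] <= t
                s = 0.0
                for m in (left, ~left):
                    if m.any():
                        mu = np.average(z[m], weights=w[m])
                        s += float((w[m] * (z[m] - mu) ** 2).sum())
                best = min(best, s)
        assert sse == pytest.approx(best, abs=1e-10)


# ---------------------------------------------------------------------------
# AdaBoost
# ---------------------------------------------------------------------------

def _adaboost_oracle(X, y01, rounds):
    """Textbook discrete boosting loop, independent of the implementation."""
    y = np.where(np.asarray(y01) == 1, 1.0, -1.0)
    n = len(y)
    w = np.full(n, 1.0 / n)
    alphas, preds = [], []
    for _ in range(rounds):
        err, (j, t, left, right) = _brute_force_class_stump(X, y, w)
        if err >= 0.5:
            break
        err = max(err, 1e-12)
        alpha = 0.5 * np.log((1 - err) / err)
        h = np.where(X[:, j] <= t, left, right)
        alphas.append(alpha)
        preds.append(h)
        if err <= 1e-12:
            break
        w = w * np.exp(-alpha * y * h)
        w /= w.sum()
    return alphas, preds


def test_adaboost_three_round_stage_weights_match_oracle():
    # small noisy layout where no single stump is perfect
    rng = np.random.default_rng(12)
    X = rng.normal(size=(12, 2)).round(2)
    y = ((X[:, 0] + X[:, 1] + 0.6 * rng.normal(size=12)) > 0).astype(int)
    model = AdaBoostModel(n_estimators=3).fit(X, y)
    oracle_alphas, _ = _adaboost_oracle(X, y, 3)
    assert len(model.alphas) == len(oracle_alphas) == 3
    assert np.allclose(model.alphas, oracle_alphas, atol=1e-10)


def test_adaboost_perfect_stump_single_stage(separable_data):
    X, y = separable_data
    model = AdaBoostModel(n_estimators=50).fit(X, y)
    assert len(model.stumps) == 1
    assert np.array_equal(model.predict(X), y)


def test_adaboost_halts_when_error_reaches_half():
    # labels independent of the single constant feature: best error = 0.5
    X = np.zeros((10, 1))
    y = np.array([0, 1] * 5)
    with pytest.raises(ValueError):
        AdaBoostModel(n_estimators=5).fit(X, y)


def test_adaboost_improves_on_noisy_cohort(medium_cohort):
    X = medium_cohort.drop(columns="target").to_numpy(float)
    y = medium_cohort["target"].to_numpy()
    model = AdaBoostModel(n_estimators=100).fit(X, y)
    assert (model.predict(X) == y).mean() > 0.8


def test_adaboost_rejects_single_class():
    with pytest.raises(ValueError):
        AdaBoostModel().fit(np.zeros((5, 1)), np.ones(5))


# ---------------------------------------------------------------------------
# LogitBoost
# ---------------------------------------------------------------------------

def test_logitboost_single_stage_matches_hand_wls_stump():
    """From the uniform p=0.5 start, z = +-2 with equal weights, so stage 1
    is the least-squares stump splitting the classes, added at half step."""
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 1, 1])
    model = LogitBoostModel(n_stages=1).fit(X, y)
    stage = model.stages[0]
    assert stage.threshold == pytest.approx(1.5)
    assert stage.left == pytest.approx(-2.0)
    assert stage.right == pytest.approx(2.0)
    assert model.stage_scales[0] == 0.5
    assert np.allclose(model.decision_function(X), [-1, -1, 1, 1])


def test_logitboost_nll_non_increasing(medium_cohort):
    X = medium_cohort.drop(columns="target").to_numpy(float)
    y = medium_cohort["target"].to_numpy()
    model = LogitBoostModel(n_stages=60).fit(X, y)
    assert all(a >= b - 1e-9 for a, b in zip(model.nll_trace, model.nll_trace[1:]))


def test_logitboost_label_flip_antisymmetry():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 4))
    y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
    f_pos = LogitBoostModel(n_stages=10).fit(X, y).decision_function(X)
    f_neg = LogitBoostModel(n_stages=10).fit(X, 1 - y).decision_function(X)
    assert np.allclose(f_pos, -f_neg, atol=1e-9)


def test_logitboost_separable_reaches_zero_training_error(separable_data):
    X, y = separable_data
    model = LogitBoostModel(n_stages=10).fit(X[:, :1], y)
    assert np.array_equal(model.predict(X[:, :1]), y)


# ---------------------------------------------------------------------------
# CatBoost-style booster
# ---------------------------------------------------------------------------

def test_catstyle_zero_trees_predicts_prior_log_odds():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 3))
    y = (rng.random(50) < 0.7).astype(int)
    model = CatStyleBooster(n_trees=0).fit(X, y)
    prior = y.mean()
    assert np.allclose(model.predict_proba(X), prior)
    assert model.base_score == pytest.approx(np.log(prior / (1 - prior)))


def test_catstyle_perfect_categorical_saturates():
    rng = np.random.default_rng(1)
    cat = rng.integers(0, 4, 400)
    y = (cat >= 2).astype(int)
    X = np.column_stack([cat.astype(float), rng.normal(size=400)])
    model = CatStyleBooster(n_trees=50, depth=3,
                            categorical_features=(0,)).fit(X, y)
    assert (model.predict(X) == y).mean() == 1.0


def test_ordered_statistics_first_occurrence_gets_prior():
    """The first row of a category in the permutation has no history, so
    its encoding equals the smoothed prior exactly."""
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0, 1, 1, 0])
    model = CatStyleBooster(n_trees=1, depth=1, categorical_features=(0,),
                            random_state=5)
    rng = np.random.default_rng(model.random_state)
    enc = model._encode_train(X, y, rng)
    perm = np.random.default_rng(model.random_state).permutation(4)
    prior = y.mean()
    first_of_each = {}
    for i in perm:
        v = X[i, 0]
        if v not in first_of_each:
            first_of_each[v] = i
    for i in first_of_each.values():
        assert enc[i, 0] == pytest.approx(prior)


def test_catstyle_no_own_label_leak_in_encoding():
    """Flipping one row's label must not change that row's own encoding."""
    rng_x = np.random.default_rng(2)
    X = np.column_stack([rng_x.integers(0, 3, 30).astype(float)])
    y = rng_x.integers(0, 2, 30)
    m = CatStyleBooster(categorical_features=(0,), random_state=3)
    enc_a = m._encode_train(X, y.astype(float), np.random.default_rng(3))
    row = 7
    y2 = y.copy()
    y2[row] = 1 - y2[row]
    # same permutation (same rng seed): only *later* rows may change
    m2 = CatStyleBooster(categorical_features=(0,), random_state=3)
    enc_b = m2._encode_train(X, y2.astype(float), np.random.default_rng(3))
    prior_shift = abs(y.mean() - y2.mean())
    perm = np.random.default_rng(3).permutation(30)
    pos = {i: k for k, i in enumerate(perm)}
    same_cat_later = [i for i in range(30)
                      if X[i, 0] == X[row, 0] and pos[i] <= pos[row]]
    for i in same_cat_later:
        if i == row:
            continue
        # rows at or before `row` in the permutation see no flipped label,
        # only the prior shift
        assert abs(enc_a[i, 0] - enc_b[i, 0]) <= prior_shift + 1e-12


def test_catstyle_training_loss_non_increasing(medium_cohort):
    X = medium_cohort.drop(columns="target").to_numpy(float)
    y = medium_cohort["target"].to_numpy()
    model = CatStyleBooster(n_trees=80).fit(X, y)
    assert all(a >= b - 1e-9 for a, b in zip(model.loss_trace, model.loss_trace[1:]))


def test_catstyle_rejects_bad_categorical_index():
    with pytest.raises(ValueError):
        CatStyleBooster(n_trees=1, categorical_features=(9,)).fit(
            np.zeros((20, 2)), np.array([0, 1] * 10))


def test_catstyle_symmetric_tree_contract():
    """Every tree carries exactly `depth` shared level predicates."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(200, 5))
    y = (X[:, 0] > 0).astype(int)
    model = CatStyleBooster(n_trees=5, depth=4).fit(X, y)
    for tree in model.trees:
        assert len(tree.features) == 4
        assert len(tree.leaf_values) == 16


# ---------------------------------------------------------------------------
# serialization round trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("factory", [
    lambda: AdaBoostModel(n_estimators=20),
    lambda: LogitBoostModel(n_stages=15),
    lambda: CatStyleBooster(n_trees=10, depth=3, categorical_features=(1,)),
])
def test_model_json_round_trip(factory, small_cohort):
    import json
    X = small_cohort.drop(columns="target").to_numpy(float)
    y = small_cohort["target"].to_numpy()
    model = factory().fit(X, y)
    blob = json.dumps(model.to_dict())
    clone = type(model).from_dict(json.loads(blob))
    assert np.array_equal(model.predict(X), clone.predict(X))
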