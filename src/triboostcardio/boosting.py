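"""The three boosting base learners of the TriBoostCardio ensemble.

* :class:`AdaBoostModel` — discrete two-class boosting of decision stumps
  with exponential stage weights alpha_m = 0.5*ln((1-err)/err).
* :class:`LogitBoostModel` — stagewise additive logistic regression: each
  stage fits a weighted-least-squares regression stump to the Newton-step
  working response z = (y* - p)/(p(1-p)) with weights w = p(1-p), and adds
  a half step to the score F(x); P(y=1|x) = 1/(1+exp(-2F)).
* :class:`CatStyleBooster` — gradient boosting on log-loss with
  depth-limited symmetric (oblivious) regression trees and leakage-free
  ordered target statistics for categorical columns: each row's category
  is encoded from the labels of *earlier* rows in a random permutation,
  with prior smoothing, so a row's own label never enters its encoding.

All models consume a numeric feature matrix and binary {0,1} labels, and
serialize to plain JSON-able dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stumps import Stump, best_classification_stump, best_regression_stump, presort

__all__ = ["AdaBoostModel", "LogitBoostModel", "CatStyleBooster"]

_EPS_ERR = 1e-12


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all() or classes.size < 2:
        raise ValueError("labels must be binary {0,1} with both classes present")
    return y


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(t, -500, 500)))


# ---------------------------------------------------------------------------
# AdaBoost
# ---------------------------------------------------------------------------

@dataclass
class AdaBoostModel:
    """Discrete AdaBoost over decision stumps.

    Fitting reweights samples each round toward those the current stage
    misclassified; a round with weighted error >= 0.5 is rejected and
    fitting halts, and a perfect round (error 0) ends fitting after being
    kept with a capped stage weight.
    """

    n_estimators: int = 200
    stumps: list[Stump] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)

    def fit(self, X, y, orders: np.ndarray | None = None, cols=None) -> "AdaBoostModel":
        X = np.asarray(X, dtype=float)
        y = _check_binary(y)
        y_sign = np.where(y == 1, 1.0, -1.0)
        n = X.shape[0]
        if orders is None:
            orders = presort(X)
        w = np.full(n, 1.0 / n)
        self.stumps, self.alphas = [], []
        for _ in range(self.n_estimators):
            stump, err = best_classification_stump(X, y_sign, w, orders, cols)
            err = err / w.sum()
            if err >= 0.5 - 1e-10:  # tolerance guards cumsum rounding
                break
            err_c = max(err, _EPS_ERR)
            alpha = 0.5 * np.log((1.0 - err_c) / err_c)
            self.stumps.append(stump)
            self.alphas.append(float(alpha))
            if err <= 0.0:
                break
            h = stump.predict(X)
            w = w * np.exp(-alpha * y_sign * h)
            w /= w.sum()
        if not self.stumps:
            raise ValueError("no stage with weighted error < 0.5; cannot boost")
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        score = np.zeros(X.shape[0])
        for alpha, stump in zip(self.alphas, self.stumps):
            score += alpha * stump.predict(X)
        return score

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def to_dict(self) -> dict:
        return {"kind": "adaboost", "n_estimators": self.n_estimators,
                "alphas": list(self.alphas),
                "stumps": [s.to_dict() for s in self.stumps]}

    @classmethod
    def from_dict(cls, d: dict) -> "AdaBoostModel":
        m = cls(n_estimators=d["n_estimators"])
        m.alphas = [float(a) for a in d["alphas"]]
        m.stumps = [Stump.from_dict(s) for s in d["stumps"]]
        return m


# ---------------------------------------------------------------------------
# LogitBoost
# ---------------------------------------------------------------------------

@dataclass
class LogitBoostModel:
    """Additive logistic regression by stagewise Newton steps on stumps.

    Working responses are clipped to ``+-z_max`` and per-sample Newton
    weights floored at ``w_floor`` for numerical stability.  If a raw half
    step would increase the training negative log-likelihood, the step is
    halved (up to 10 times) and fitting stops once no improving step
    exists, so the training NLL is non-increasing across stages.
    """

    n_stages: int = 100
    z_max: float = 4.0
    w_floor: float = 1e-10
    p_floor: float = 1e-10
    stages: list[Stump] = field(default_factory=list)
    stage_scales: list[float] = field(default_factory=list)
    nll_trace: list[float] = field(default_factory=list)

    def _nll(self, F: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(_sigmoid(2.0 * F), self.p_floor, 1.0 - self.p_floor)
        return float(-np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(self, X, y, orders: np.ndarray | None = None, cols=None) -> "LogitBoostModel":
        X = np.asarray(X, dtype=float)
        y = _check_binary(y).astype(float)
        n = X.shape[0]
        if orders is None:
            orders = presort(X)
        F = np.zeros(n)
        self.stages, self.stage_scales = [], []
        self.nll_trace = [self._nll(F, y)]
        for _ in range(self.n_stages):
            p = np.clip(_sigmoid(2.0 * F), self.p_floor, 1.0 - self.p_floor)
            w = np.maximum(p * (1.0 - p), self.w_floor)
            z = np.clip((y - p) / (p * (1.0 - p)), -self.z_max, self.z_max)
            stump, _ = best_regression_stump(X, z, w, orders, cols)
            f = stump.predict(X)
            scale = 0.5
            nll_before = self.nll_trace[-1]
            for _ in range(10):
                if self._nll(F + scale * f, y) <= nll_before:
                    break
                scale *= 0.5
            else:
                break  # no improving fraction of the Newton step
            F = F + scale * f
            self.stages.append(stump)
            self.stage_scales.append(scale)
            self.nll_trace.append(self._nll(F, y))
        return self

    def decision_function(self, X) -> np.ndarray:
        """The additive score F(x) (half log-odds)."""
        X = np.asarray(X, dtype=float)
        F = np.zeros(X.shape[0])
        for scale, stump in zip(self.stage_scales, self.stages):
            F += scale * stump.predict(X)
        return F

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(2.0 * self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)

    def to_dict(self) -> dict:
        return {"kind": "logitboost", "n_stages": self.n_stages,
                "z_max": self.z_max,
                "stage_scales": list(self.stage_scales),
                "stages": [s.to_dict() for s in self.stages]}

    @classmethod
    def from_dict(cls, d: dict) -> "LogitBoostModel":
        m = cls(n_stages=d["n_stages"], z_max=d["z_max"])
        m.stage_scales = [float(s) for s in d["stage_scales"]]
        m.stages = [Stump.from_dict(s) for s in d["stages"]]
        return m


# ---------------------------------------------------------------------------
# CatBoost-style gradient booster
# ---------------------------------------------------------------------------

@dataclass
class _SymmetricTree:
    """Oblivious tree: one (feature, threshold) predicate per level,
    shared by every node of that level."""

    features: list[int]            # -1 marks a level with no split
    thresholds: list[float]
    leaf_values: np.ndarray        # length 2**depth

    def leaf_index(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=int)
        for f, t in zip(self.features, self.thresholds):
            if f < 0:
                idx = idx * 2
            else:
                idx = idx * 2 + (X[:, f] > t)
        return idx

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_values[self.leaf_index(X)]

    def to_dict(self) -> dict:
        return {"features": list(map(int, self.features)),
                "thresholds": [float(t) for t in self.thresholds],
                "leaf_values": [float(v) for v in self.leaf_values]}

    @classmethod
    def from_dict(cls, d: dict) -> "_SymmetricTree":
        return cls(d["features"], d["thresholds"], np.asarray(d["leaf_values"], dtype=float))


class CatStyleBooster:
    """Gradient boosting on log-loss with symmetric trees and ordered
    target-statistic encoding of categorical columns.

    Parameters
    ----------
    n_trees, depth, learning_rate : ensemble size and shrinkage.
    categorical_features : column indices encoded by ordered target
        statistics during training (full-data smoothed statistics at
        prediction time).
    l2 : leaf regularization added to the Hessian sum.
    n_bins : quantile histogram bins for split search.
    prior_weight : smoothing pseudo-count ``a`` in
        (prefix_sum + a*prior) / (prefix_count + a).
    """

    def __init__(self, n_trees: int = 500, depth: int = 6, learning_rate: float = 0.1,
                 categorical_features=(), l2: float = 3.0, n_bins: int = 32,
                 prior_weight: float = 1.0, random_state: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if n_trees < 0:
            raise ValueError("n_trees must be non-negative")
        self.n_trees = n_trees
        self.depth = depth
        self.learning_rate = learning_rate
        self.categorical_features = tuple(int(c) for c in categorical_features)
        self.l2 = l2
        self.n_bins = n_bins
        self.prior_weight = prior_weight
        self.random_state = random_state
        self.trees: list[_SymmetricTree] = []
        self.base_score: float = 0.0
        self.cat_stats: dict[int, dict] = {}
        self.loss_trace: list[float] = []

    # -- categorical encoding -------------------------------------------

    def _encode_train(self, X: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
        Xe = X.astype(float).copy()
        n = X.shape[0]
        prior = float(y.mean())
        a = self.prior_weight
        for c in self.categorical_features:
            if c < 0 or c >= X.shape[1]:
                raise ValueError(f"categorical column index {c} out of range")
            perm = rng.permutation(n)
            col = X[perm, c]
            sums: dict = {}
            counts: dict = {}
            enc = np.empty(n)
            for i, v in enumerate(col):
                s = sums.get(v, 0.0)
                k = counts.get(v, 0)
                enc[i] = (s + a * prior) / (k + a)
                sums[v] = s + y[perm[i]]
                counts[v] = k + 1
            Xe[perm, c] = enc
            full = {}
            for v in np.unique(X[:, c]):
                m = X[:, c] == v
                full[float(v)] = (float(y[m].sum()) + a * prior) / (int(m.sum()) + a)
            self.cat_stats[c] = {"prior": prior, "levels": full}
        return Xe

    def _encode_predict(self, X: np.ndarray) -> np.ndarray:
        Xe = np.asarray(X, dtype=float).copy()
        for c, st in self.cat_stats.items():
            levels = st["levels"]
            prior = st["prior"]
            Xe[:, c] = np.array([levels.get(float(v), prior) for v in X[:, c]])
        return Xe

    # -- tree growing ----------------------------------------------------

    def _bin_data(self, Xe: np.ndarray):
        n, d = Xe.shape
        edges = []
        binned = np.empty((n, d), dtype=np.int64)
        qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
        for j in range(d):
            e = np.unique(np.quantile(Xe[:, j], qs))
            edges.append(e)
            # bin > b  <=>  value > e[b], matching the predict-time predicate
            binned[:, j] = np.searchsorted(e, Xe[:, j], side="left")
        return binned, edges

    def _grow_tree(self, Xe, binned, edges, g, h) -> _SymmetricTree:
        n, d = Xe.shape
        leaf = np.zeros(n, dtype=np.int64)
        feats: list[int] = []
        thrs: list[float] = []
        n_leaves = 1
        for _ in range(self.depth):
            best_gain, best = 0.0, None
            base = None
            for j in range(d):
                nb = len(edges[j]) + 1
                if nb < 2:
                    continue
                key = leaf * nb + binned[:, j]
                gs = np.bincount(key, weights=g, minlength=n_leaves * nb).reshape(n_leaves, nb)
                hs = np.bincount(key, weights=h, minlength=n_leaves * nb).reshape(n_leaves, nb)
                gl = np.cumsum(gs, axis=1)[:, :-1]
                hl = np.cumsum(hs, axis=1)[:, :-1]
                gt = gs.sum(axis=1, keepdims=True)
                ht = hs.sum(axis=1, keepdims=True)
                if base is None:
                    base = float((gt[:, 0] ** 2 / (ht[:, 0] + self.l2)).sum())
                gr = gt - gl
                hr = ht - hl
                gain = (gl ** 2 / (hl + self.l2) + gr ** 2 / (hr + self.l2)).sum(axis=0) - base
                b = int(np.argmax(gain))
                if gain[b] > best_gain + 1e-12:
                    best_gain = float(gain[b])
                    best = (j, b)
            if best is None:
                feats.append(-1)
                thrs.append(0.0)
                leaf = leaf * 2
            else:
                j, b = best
                feats.append(j)
                thrs.append(float(edges[j][b]))
                leaf = leaf * 2 + (binned[:, j] > b)
            n_leaves *= 2
        values = np.zeros(2 ** self.depth)
        gsum = np.bincount(leaf, weights=g, minlength=2 ** self.depth)
        hsum = np.bincount(leaf, weights=h, minlength=2 ** self.depth)
        nz = hsum + self.l2 > 0
        values[nz] = gsum[nz] / (hsum[nz] + self.l2)
        return _SymmetricTree(feats, thrs, values * self.learning_rate)

    def fit(self, X, y) -> "CatStyleBooster":
        X = np.asarray(X)
        y = _check_binary(y).astype(float)
        rng = np.random.default_rng(self.random_state)
        self.cat_stats = {}
        Xe = self._encode_train(X, y, rng)
        prior = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
        self.base_score = float(np.log(prior / (1.0 - prior)))
        self.trees = []
        F = np.full(X.shape[0], self.base_score)
        self.loss_trace = [self._logloss(F, y)]
        if self.n_trees == 0:
            return self
        binned, edges = self._bin_data(Xe)
        for _ in range(self.n_trees):
            p = _sigmoid(F)
            g = y - p
            h = np.maximum(p * (1.0 - p), 1e-10)
            tree = self._grow_tree(Xe, binned, edges, g, h)
            F = F + tree.predict(Xe)
            self.trees.append(tree)
            self.loss_trace.append(self._logloss(F, y))
        return self

    @staticmethod
    def _logloss(F: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(_sigmoid(F), 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def decision_function(self, X) -> np.ndarray:
        Xe = self._encode_predict(np.asarray(X))
        F = np.full(Xe.shape[0], self.base_score)
        for t in self.trees:
            F += t.predict(Xe)
        return F

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)

    def to_dict(self) -> dict:
        return {
            "kind": "catstyle", "n_trees": self.n_trees, "depth": self.depth,
            "learning_rate": self.learning_rate,
            "categorical_features": list(self.categorical_features),
            "l2": self.l2, "n_bins": self.n_bins,
            "prior_weight": self.prior_weight, "random_state": self.random_state,
            "base_score": self.base_score,
            "cat_stats": {str(c): {"prior": st["prior"],
                                   "levels": {str(k): v for k, v in st["levels"].items()}}
                          for c, st in self.cat_stats.items()},
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CatStyleBooster":
        m = cls(n_trees=d["n_trees"], depth=d["depth"], learning_rate=d["learning_rate"],
                categorical_features=d["categorical_features"], l2=d["l2"],
                n_bins=d["n_bins"], prior_weight=d["prior_weight"],
                random_state=d["random_state"])
        m.base_score = d["base_score"]
        m.cat_stats = {int(c): {"prior": st["prior"],
                                "levels": {float(k): v for k, v in st["levels"].items()}}
                       for c, st in d["cat_stats"].items()}
        m.trees = [_SymmetricTree.from_dict(t) for t in d["trees"]]
        return m
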