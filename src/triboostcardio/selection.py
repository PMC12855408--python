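"""Binary wrapper feature selection on top of the RL-SCSO optimizer.

Subsets are scored by the weighted fitness

    Fit = lambda * delta + (1 - lambda) * |S| / |Tf|

where delta is a classifier's cross-validated misclassification rate on
the masked columns, |S| the subset size and |Tf| the total feature count.
The optimizer searches a continuous space (default bounds [-4, 4] per
feature, where the sigmoid transfer saturates) and positions are mapped to
masks by a sigmoid threshold: bit j is set iff position_j > 0, with an
argmax repair when every bit would be 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._stumps import presort
from .boosting import AdaBoostModel
from .scso import SwarmConfig, run_rl_scso

__all__ = [
    "FitnessConfig",
    "SelectionResult",
    "CVErrorEvaluator",
    "binarize",
    "subset_fitness",
    "select_features",
    "selection_frequencies",
]

TARGET_COLUMN = "target"


@dataclass(frozen=True)
class FitnessConfig:
    """Weights and evaluator for the subset fitness.

    lam weighs the error-rate term (default 0.99, accuracy-dominant); the
    size penalty gets eta = 1 - lam.  The default evaluator is the
    ensemble's cheapest member — AdaBoost with 50 stumps — under
    stratified 5-fold cross-validation with a fixed fold seed.
    """

    lam: float = 0.99
    n_folds: int = 5
    fold_seed: int = 0
    n_estimators: int = 50

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")

    @property
    def eta(self) -> float:
        return 1.0 - self.lam


def binarize(position, threshold: float = 0.5) -> np.ndarray:
    """Sigmoid transfer: bit j = 1 iff sigmoid(pos_j) > threshold
    (equivalently pos_j > 0 at threshold 0.5).  An all-zero mask is
    repaired by setting the bit of the largest position value."""
    pos = np.asarray(position, dtype=float)
    if not np.isfinite(pos).all():
        raise ValueError("position must be finite")
    logit = np.log(threshold / (1.0 - threshold))
    bits = (pos > logit).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(pos))] = 1
    return bits


class CVErrorEvaluator:
    """Cross-validated AdaBoost error rate of a feature subset.

    Folds and per-fold column sort orders are computed once and reused
    across every mask (sort order per column does not depend on the mask);
    mask -> error results are memoized.
    """

    def __init__(self, X, y, fc: FitnessConfig = FitnessConfig()):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        if np.unique(self.y).size < 2:
            raise ValueError("need at least two classes present")
        self.fc = fc
        skf = StratifiedKFold(n_splits=fc.n_folds, shuffle=True,
                              random_state=fc.fold_seed)
        self._folds = []
        for tr, te in skf.split(self.X, self.y):
            Xtr = self.X[tr]
            self._folds.append((Xtr, self.y[tr], presort(Xtr), self.X[te], self.y[te]))
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def error(self, mask) -> float:
        """Mean held-out misclassification rate over the folds."""
        bits = np.asarray(mask, dtype=int)
        if bits.sum() < 1:
            raise ValueError("empty feature mask")
        key = bits.tobytes()
        if key in self._cache:
            return self._cache[key]
        cols = np.flatnonzero(bits)
        wrong = 0
        total = 0
        for Xtr, ytr, orders, Xte, yte in self._folds:
            model = AdaBoostModel(n_estimators=self.fc.n_estimators)
            model.fit(Xtr, ytr, orders=orders, cols=cols)
            wrong += int(np.sum(model.predict(Xte) != yte))
            total += yte.size
        err = wrong / total
        self._cache[key] = err
        self.n_evaluations += 1
        return err

    def fitness(self, mask) -> float:
        bits = np.asarray(mask, dtype=int)
        delta = self.error(bits)
        return self.fc.lam * delta + self.fc.eta * bits.sum() / bits.size


def subset_fitness(mask, X, y, fc: FitnessConfig = FitnessConfig()) -> float:
    """Fit = lam*delta + (1-lam)*|S|/|Tf| for one mask (fresh evaluator)."""
    return CVErrorEvaluator(X, y, fc).fitness(mask)


@dataclass
class SelectionResult:
    mask: np.ndarray
    fitness: float
    trace: list[float]
    selected: tuple[str, ...] = ()
    n_evaluations: int = 0
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        return json.dumps({
            "mask": [int(b) for b in self.mask],
            "fitness": self.fitness,
            "trace": list(self.trace),
            "selected": list(self.selected),
        })


def _split_table(table, y=None):
    if isinstance(table, pd.DataFrame):
        if y is None:
            if TARGET_COLUMN not in table.columns:
                raise ValueError(f"table lacks a {TARGET_COLUMN!r} column")
            y = table[TARGET_COLUMN].to_numpy()
            X = table.drop(columns=[TARGET_COLUMN])
        else:
            X = table
        names = tuple(X.columns)
        return X.to_numpy(dtype=float), np.asarray(y), names
    X = np.asarray(table, dtype=float)
    if y is None:
        raise ValueError("labels required when table is an array")
    return X, np.asarray(y), tuple(f"f{i}" for i in range(X.shape[1]))


def select_features(
    table,
    y=None,
    fc: FitnessConfig = FitnessConfig(),
    config: SwarmConfig = SwarmConfig(),
    evaluator: CVErrorEvaluator | None = None,
) -> SelectionResult:
    """Run RL-SCSO over sigmoid-binarized positions to minimize the
    subset fitness; returns the best mask, its fitness, the per-iteration
    best-fitness trace and the per-feature selection indicator.

    A one-feature table short-circuits to the only feasible subset.  An
    existing evaluator may be passed to reuse its fold layout and
    mask-fitness cache across repeated runs on the same data.
    """
    X, y, names = _split_table(table, y)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes present")
    d = X.shape[1]
    if evaluator is None:
        evaluator = CVErrorEvaluator(X, y, fc)
    if d == 1:
        mask = np.array([1])
        return SelectionResult(mask, evaluator.fitness(mask), [],
                               selected=names, feature_names=names)

    def objective(position):
        return evaluator.fitness(binarize(position))

    result = run_rl_scso(objective, d, config)
    mask = binarize(result.best.position)
    selected = tuple(n for n, b in zip(names, mask) if b)
    return SelectionResult(mask, result.best.fitness, result.trace,
                           selected=selected,
                           n_evaluations=result.n_evaluations,
                           feature_names=names)


def selection_frequencies(
    table,
    y=None,
    fc: FitnessConfig = FitnessConfig(),
    config: SwarmConfig = SwarmConfig(),
    n_seeds: int = 20,
) -> pd.DataFrame:
    """Per-feature selection frequency across repeated seeded runs."""
    X, yv, names = _split_table(table, y)
    evaluator = CVErrorEvaluator(X, yv, fc)
    counts = np.zeros(X.shape[1])
    for s in range(n_seeds):
        cfg = replace(config, seed=config.seed + s)
        res = select_features(table, y, fc=fc, config=cfg, evaluator=evaluator)
        counts += res.mask
    return pd.DataFrame({"feature": list(names), "frequency": counts / n_seeds})
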