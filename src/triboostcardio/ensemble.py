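"""The TriBoostCardio ensemble: three boosters combined by majority vote.

A CatBoost-style symmetric-tree gradient booster, AdaBoost and LogitBoost
are trained on identical training data (stratified 80:20 split under a
seed, with the documented defaults of 500 trees / 200 estimators / 100
iterations) and combined by unweighted hard majority voting on the
held-out partition.  Stratified 5-fold cross-validation metrics on the
training partition are reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .boosting import AdaBoostModel, CatStyleBooster, LogitBoostModel
from .metrics import MetricsReport, compute_metrics, confusion, majority_vote

__all__ = ["TriBoostConfig", "TriBoostModel", "TriBoostResult", "train_triboost"]

TARGET_COLUMN = "target"


@dataclass(frozen=True)
class TriBoostConfig:
    cat_trees: int = 500
    cat_depth: int = 6
    cat_learning_rate: float = 0.1
    ada_estimators: int = 200
    logit_stages: int = 100
    categorical_features: tuple[int, ...] = ()
    test_size: float = 0.2
    cv_folds: int = 5          # 0 disables the training-partition CV report
    seed: int = 0


@dataclass
class TriBoostModel:
    """Three fitted members exposing a common predict contract."""

    catstyle: CatStyleBooster
    adaboost: AdaBoostModel
    logitboost: LogitBoostModel

    def member_predictions(self, X) -> dict[str, np.ndarray]:
        return {
            "catstyle": self.catstyle.predict(X),
            "adaboost": self.adaboost.predict(X),
            "logitboost": self.logitboost.predict(X),
        }

    def predict(self, X) -> np.ndarray:
        p = self.member_predictions(X)
        return majority_vote(p["catstyle"], p["adaboost"], p["logitboost"])

    def to_json(self) -> str:
        return json.dumps({
            "catstyle": self.catstyle.to_dict(),
            "adaboost": self.adaboost.to_dict(),
            "logitboost": self.logitboost.to_dict(),
        })

    @classmethod
    def from_json(cls, text: str) -> "TriBoostModel":
        d = json.loads(text)
        return cls(
            catstyle=CatStyleBooster.from_dict(d["catstyle"]),
            adaboost=AdaBoostModel.from_dict(d["adaboost"]),
            logitboost=LogitBoostModel.from_dict(d["logitboost"]),
        )


@dataclass
class TriBoostResult:
    model: TriBoostModel
    test_metrics: MetricsReport
    member_test_metrics: dict[str, MetricsReport]
    cv_metrics: MetricsReport | None
    train_index: np.ndarray
    test_index: np.ndarray
    config: TriBoostConfig = field(default_factory=TriBoostConfig)


def _as_xy(table, y=None):
    if isinstance(table, pd.DataFrame):
        if y is None:
            y = table[TARGET_COLUMN].to_numpy()
            table = table.drop(columns=[TARGET_COLUMN])
        return table.to_numpy(dtype=float), np.asarray(y).astype(int)
    if y is None:
        raise ValueError("labels required when table is an array")
    return np.asarray(table, dtype=float), np.asarray(y).astype(int)


def _fit_members(X, y, config: TriBoostConfig) -> TriBoostModel:
    cat = CatStyleBooster(
        n_trees=config.cat_trees, depth=config.cat_depth,
        learning_rate=config.cat_learning_rate,
        categorical_features=config.categorical_features,
        random_state=config.seed,
    ).fit(X, y)
    ada = AdaBoostModel(n_estimators=config.ada_estimators).fit(X, y)
    logit = LogitBoostModel(n_stages=config.logit_stages).fit(X, y)
    return TriBoostModel(cat, ada, logit)


def train_triboost(table, y=None, config: TriBoostConfig = TriBoostConfig()) -> TriBoostResult:
    """Stratified 80:20 split, three members trained on the training
    partition, majority-vote evaluation on the held-out 20%, and
    (optionally) 5-fold CV metrics on the training partition.

    Deterministic under the config seed.  Requires >= 10 samples per class.
    """
    X, yv = _as_xy(table, y)
    classes, counts = np.unique(yv, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary labels with both classes required")
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class")

    idx = np.arange(X.shape[0])
    tr_idx, te_idx = train_test_split(
        idx, test_size=config.test_size, stratify=yv, random_state=config.seed
    )
    model = _fit_members(X[tr_idx], yv[tr_idx], config)

    member_preds = model.member_predictions(X[te_idx])
    vote = majority_vote(member_preds["catstyle"], member_preds["adaboost"],
                         member_preds["logitboost"])
    test_metrics = compute_metrics(confusion(yv[te_idx], vote))
    member_metrics = {
        name: compute_metrics(confusion(yv[te_idx], pred))
        for name, pred in member_preds.items()
    }

    cv_metrics = None
    if config.cv_folds >= 2:
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=config.seed)
        tp = tn = fp = fn = 0
        for tr, va in skf.split(X[tr_idx], yv[tr_idx]):
            fold_model = _fit_members(X[tr_idx][tr], yv[tr_idx][tr], config)
            c = confusion(yv[tr_idx][va], fold_model.predict(X[tr_idx][va]))
            tp += c.tp; tn += c.tn; fp += c.fp; fn += c.fn
        from .metrics import ConfusionCounts
        cv_metrics = compute_metrics(ConfusionCounts(tp, tn, fp, fn))

    return TriBoostResult(model=model, test_metrics=test_metrics,
                          member_test_metrics=member_metrics,
                          cv_metrics=cv_metrics,
                          train_index=tr_idx, test_index=te_idx,
                          config=config)
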