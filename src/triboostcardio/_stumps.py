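"""Vectorized decision-stump search shared by the boosting learners.

Stumps split one feature at one threshold (``x <= threshold`` goes left).
Search is exact over all distinct split points, using per-column sort
orders that callers may precompute once and reuse across boosting stages
and cross-validation reruns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Stump", "presort", "best_classification_stump", "best_regression_stump"]


@dataclass(frozen=True)
class Stump:
    """One split: samples with feature <= threshold get ``left``."""

    feature: int
    threshold: float
    left: float
    right: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        go_left = X[:, self.feature] <= self.threshold
        return np.where(go_left, self.left, self.right)

    def to_dict(self) -> dict:
        return {"feature": int(self.feature), "threshold": float(self.threshold),
                "left": float(self.left), "right": float(self.right)}

    @classmethod
    def from_dict(cls, d: dict) -> "Stump":
        return cls(d["feature"], d["threshold"], d["left"], d["right"])


def presort(X: np.ndarray) -> np.ndarray:
    """Per-column argsort of the feature matrix (n x d int array)."""
    return np.argsort(X, axis=0, kind="stable")


def _split_candidates(xs: np.ndarray) -> np.ndarray:
    """Boolean mask of valid split positions in a sorted column.

    Position i means the left block is xs[:i+1]; valid when the value
    changes at the boundary.  The last position (constant stump) is
    always valid.
    """
    n = xs.size
    ok = np.empty(n, dtype=bool)
    ok[:-1] = xs[:-1] < xs[1:]
    ok[-1] = True
    return ok


def _thresholds(xs: np.ndarray) -> np.ndarray:
    n = xs.size
    thr = np.empty(n)
    thr[:-1] = 0.5 * (xs[:-1] + xs[1:])
    thr[-1] = np.inf
    return thr


def best_classification_stump(
    X: np.ndarray,
    y_sign: np.ndarray,
    w: np.ndarray,
    orders: np.ndarray | None = None,
    cols=None,
) -> tuple[Stump, float]:
    """Minimum weighted 0-1 error stump voting in {-1, +1}.

    Parameters
    ----------
    y_sign : labels in {-1, +1}.
    w : non-negative sample weights.
    orders : optional precomputed :func:`presort` output.
    cols : optional iterable of column indices to restrict the search to.
    """
    n, d = X.shape
    if orders is None:
        orders = presort(X)
    if cols is None:
        cols = range(d)
    is_pos = y_sign > 0
    total_pos = float(w[is_pos].sum())
    total_neg = float(w[~is_pos].sum())

    best = (np.inf, 0, np.inf, -1.0, 1.0)  # err, col, thr, left, right
    for j in cols:
        idx = orders[:, j]
        xs = X[idx, j]
        ws = w[idx]
        cpos = np.cumsum(ws * is_pos[idx])
        cneg = np.cumsum(ws) - cpos
        ok = _split_candidates(xs)
        # left votes -1, right votes +1: misclassify left positives, right negatives
        err_lneg = cpos + (total_neg - cneg)
        err_lpos = (total_pos + total_neg) - err_lneg
        thr = _thresholds(xs)
        for errs, left, right in ((err_lneg, -1.0, 1.0), (err_lpos, 1.0, -1.0)):
            masked = np.where(ok, errs, np.inf)
            i = int(np.argmin(masked))
            if masked[i] < best[0]:
                best = (float(masked[i]), j, float(thr[i]), left, right)
    err, j, thr, left, right = best
    return Stump(j, thr, left, right), err


def best_regression_stump(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    orders: np.ndarray | None = None,
    cols=None,
) -> tuple[Stump, float]:
    """Weighted-least-squares stump: piecewise-constant fit minimizing
    sum w*(z - f(x))^2 over all single-feature splits."""
    n, d = X.shape
    if orders is None:
        orders = presort(X)
    if cols is None:
        cols = range(d)
    best_sse = np.inf
    best_stump = None
    for j in cols:
        idx = orders[:, j]
        xs = X[idx, j]
        ws = w[idx]
        zs = z[idx]
        sw = np.cumsum(ws)
        swz = np.cumsum(ws * zs)
        swz2 = np.cumsum(ws * zs * zs)
        tot_w, tot_wz, tot_wz2 = sw[-1], swz[-1], swz2[-1]
        rw = tot_w - sw
        rwz = tot_wz - swz
        with np.errstate(divide="ignore", invalid="ignore"):
            left_term = np.where(sw > 0, swz * swz / sw, 0.0)
            right_term = np.where(rw > 0, rwz * rwz / rw, 0.0)
        sse = tot_wz2 - left_term - right_term
        ok = _split_candidates(xs)
        masked = np.where(ok, sse, np.inf)
        i = int(np.argmin(masked))
        if masked[i] < best_sse:
            left_val = swz[i] / sw[i] if sw[i] > 0 else 0.0
            right_val = rwz[i] / rw[i] if rw[i] > 0 else left_val
            thr = _thresholds(xs)[i]
            best_sse = float(masked[i])
            best_stump = Stump(j, float(thr), float(left_val), float(right_val))
    return best_stump, best_sse
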