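"""Record cleaning and signal conditioning ahead of modelling.

Wearable vital-sign streams are smoothed with a scalar Kalman filter
(random-walk state model: identity transition with process noise ``q`` and
measurement noise ``r``); tabular records get duplicate removal,
mean/median imputation, an age-aware heart-rate anomaly flag, and min-max
normalization fit on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KalmanState",
    "HeartRateRule",
    "NormalizationParams",
    "kalman_filter_series",
    "kalman_steady_state_gain",
    "drop_duplicates",
    "impute_missing",
    "flag_heart_rate",
    "drop_zero_variance",
    "fit_minmax",
    "apply_minmax",
    "invert_minmax",
    "preprocess_table",
]

TARGET_COLUMN = "target"


@dataclass
class KalmanState:
    """Scalar filter state: estimate, error covariance and noise levels."""

    estimate: float
    error_cov: float
    process_noise_q: float = 0.01
    measurement_noise_r: float = 1.0

    def predict(self) -> None:
        self.error_cov += self.process_noise_q

    def update(self, z: float) -> float:
        gain = self.error_cov / (self.error_cov + self.measurement_noise_r)
        self.estimate += gain * (z - self.estimate)
        self.error_cov *= 1.0 - gain
        return gain


def kalman_filter_series(
    series,
    q: float = 0.01,
    r: float = 1.0,
    init_estimate: float | None = None,
    init_cov: float = 1.0,
    return_gains: bool = False,
):
    """Scalar predict/correct smoothing of a 1-D series with missing entries.

    Missing entries (NaN) receive the prediction only — no correction step
    — so corrupted samples are replaced by the filter's statistically
    optimal estimate.  Output length equals input length.

    Parameters
    ----------
    q, r : process / measurement noise variances; ``r`` must be positive.
    init_estimate : initial state; defaults to the first observed value.
    init_cov : initial error covariance (> 0).
    return_gains : also return the per-step Kalman gain (NaN on missing
        steps, where no correction happens).
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if r <= 0:
        raise ValueError("measurement noise r must be positive")
    if q < 0:
        raise ValueError("process noise q must be non-negative")
    observed = ~np.isnan(x)
    if init_estimate is None:
        if not observed.any():
            raise ValueError("all-missing series requires init_estimate")
        init_estimate = float(x[observed][0])

    state = KalmanState(float(init_estimate), float(init_cov), q, r)
    out = np.empty_like(x)
    gains = np.full_like(x, np.nan)
    for i, z in enumerate(x):
        state.predict()
        if observed[i]:
            gains[i] = state.update(z)
        out[i] = state.estimate
    if return_gains:
        return out, gains
    return out


def kalman_steady_state_gain(q: float, r: float) -> float:
    """Closed-form steady-state gain of the scalar random-walk filter.

    The prior covariance fixed point solves P^2 = q*P + q*r, giving
    P = (q + sqrt(q^2 + 4*q*r)) / 2 and gain K = P / (P + r).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    p = (q + np.sqrt(q * q + 4.0 * q * r)) / 2.0
    return p / (p + r)


def drop_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce exact feature-row duplicates to their first occurrence.

    Duplication is judged on all non-target columns; row order is
    otherwise preserved.
    """
    subset = [c for c in table.columns if c != TARGET_COLUMN]
    if not subset:
        subset = list(table.columns)
    return table.drop_duplicates(subset=subset, keep="first").reset_index(drop=True)


def impute_missing(
    table: pd.DataFrame,
    strategy: str = "mean",
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Fill missing entries with the column mean/median (mode for
    categoricals), computed over observed entries only.

    Non-numeric columns and columns named in ``categorical`` use the mode.
    Raises on a fully missing column.
    """
    if strategy not in ("mean", "median"):
        raise ValueError("strategy must be 'mean' or 'median'")
    out = table.copy()
    for col in out.columns:
        s = out[col]
        if not s.isna().any():
            continue
        if s.notna().sum() == 0:
            raise ValueError(f"column {col!r} is fully missing")
        if col in categorical or not pd.api.types.is_numeric_dtype(s):
            fill = s.mode(dropna=True).iloc[0]
        elif strategy == "mean":
            fill = s.mean()
        else:
            fill = s.median()
        out[col] = s.fillna(fill)
    return out


def _age_predicted_max(age_years: float) -> float:
    return 220.0 - age_years


@dataclass(frozen=True)
class HeartRateRule:
    """Age-aware heart-rate band: below ``lower_bpm`` (bradycardia bound)
    or above ``upper_rule(age)`` (default age-predicted maximum 220 - age)
    flags a potential deviation."""

    lower_bpm: float = 60.0
    upper_rule: Callable[[float], float] = _age_predicted_max


def flag_heart_rate(hr_bpm: float, age_years: float,
                    rule: HeartRateRule = HeartRateRule()) -> bool:
    """True iff the rate falls outside the age-specific acceptable band."""
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    if not 0.0 <= age_years <= 120.0:
        raise ValueError("age must lie in [0, 120] years")
    return bool(hr_bpm < rule.lower_bpm or hr_bpm > rule.upper_rule(age_years))


def drop_zero_variance(table: pd.DataFrame) -> pd.DataFrame:
    """Remove constant (zero-variance) feature columns; target is kept."""
    keep = [
        c for c in table.columns
        if c == TARGET_COLUMN or table[c].nunique(dropna=True) > 1
    ]
    return table[keep]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training (min, max) pairs; training min -> 0, max -> 1."""

    columns: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray


def fit_minmax(table: pd.DataFrame, columns: Sequence[str] | None = None) -> NormalizationParams:
    """Learn per-column min/max on the training partition only."""
    if len(table) == 0:
        raise ValueError("cannot fit normalization on an empty table")
    if columns is None:
        columns = [c for c in table.columns if c != TARGET_COLUMN
                   and pd.api.types.is_numeric_dtype(table[c])]
    sub = table[list(columns)].to_numpy(dtype=float)
    return NormalizationParams(tuple(columns), sub.min(axis=0), sub.max(axis=0))


def apply_minmax(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Map each fitted column through (x - min) / (max - min).

    Constant training columns map to 0; values outside the training range
    extrapolate linearly (no clipping).
    """
    out = table.copy()
    span = params.maxs - params.mins
    for j, col in enumerate(params.columns):
        if span[j] == 0:
            out[col] = 0.0
        else:
            out[col] = (table[col].to_numpy(dtype=float) - params.mins[j]) / span[j]
    return out


def invert_minmax(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Inverse of :func:`apply_minmax` (constant columns recover min)."""
    out = table.copy()
    span = params.maxs - params.mins
    for j, col in enumerate(params.columns):
        out[col] = table[col].to_numpy(dtype=float) * span[j] + params.mins[j]
    return out


def preprocess_table(
    table: pd.DataFrame,
    strategy: str = "mean",
    hr_column: str = "max_heart_rate",
    age_column: str = "age",
    rule: HeartRateRule = HeartRateRule(),
) -> pd.DataFrame:
    """Duplicate removal -> imputation -> zero-variance drop -> HR flag.

    Flagged (out-of-threshold) records are retained, with the flag recorded
    in an ``hr_flag`` column when both heart-rate and age columns exist.
    Normalization is deliberately left to the modelling stage, where it is
    fit on the training partition only.
    """
    out = drop_duplicates(table)
    out = impute_missing(out, strategy=strategy)
    out = drop_zero_variance(out)
    if hr_column in out.columns and age_column in out.columns:
        flags = [
            flag_heart_rate(max(float(h), 1e-9), float(np.clip(a, 0, 120)), rule)
            for h, a in zip(out[hr_column], out[age_column])
        ]
        out = out.copy()
        out["hr_flag"] = np.asarray(flags, dtype=int)
    return out
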