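"""Synthetic cardiovascular cohorts and vital-sign streams.

The generator emulates the schema of the public CVD tabular data the
pipeline targets — demographics (age, sex), symptom variables (chest-pain
type), physiological variables (resting blood pressure 94-200 mmHg, serum
cholesterol 126-564 mg/dL, maximum heart rate 71-202 bpm, ST depression
0-6.2) and diagnostic codes — with a binary target (0 = absence, 1 =
presence of cardiovascular disease).

Ground truth is controllable: a known subset of columns is truly
informative.  Each feature has a standard-normal latent; the target is
drawn from a logistic model on the informative latents only, with
user-supplied log-odds effect sizes, and the intercept is solved so the
expected positive rate matches ``class_balance``.  Numeric attributes are
min-max mapped from their latent onto the declared bounds (so declared
ranges are respected exactly); categorical attributes are quantile-coded
into equally probable integer levels.

Vital-sign streams are a constant baseline plus Gaussian sensor noise,
sparse additive artifact spikes and missing entries, mirroring the failure
modes of wearable monitors (motion artifacts, signal dropouts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "AttributeRange",
    "CohortSpec",
    "VitalSeriesSpec",
    "default_attribute_ranges",
    "generate_cohort",
    "generate_vital_series",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_vitals_csv",
    "read_vitals_csv",
]

TARGET_COLUMN = "target"


@dataclass(frozen=True)
class AttributeRange:
    """Declared bounds / level count for one generated attribute.

    kind is "numeric" (values min-max mapped into [low, high]) or
    "categorical" (integer codes 0..n_levels-1 with uniform marginals).
    """

    low: float = 0.0
    high: float = 1.0
    kind: str = "numeric"
    n_levels: int = 2

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "numeric" and not self.high >= self.low:
            raise ValueError("high must be >= low")
        if self.kind == "categorical" and self.n_levels < 2:
            raise ValueError("categorical attributes need >= 2 levels")


def default_attribute_ranges() -> dict[str, AttributeRange]:
    """The printed clinical attribute schema with its documented ranges."""
    return {
        "age": AttributeRange(29, 77),
        "sex": AttributeRange(kind="categorical", n_levels=2),
        "chest_pain_type": AttributeRange(kind="categorical", n_levels=4),
        "resting_bp": AttributeRange(94, 200),          # mmHg
        "serum_cholesterol": AttributeRange(126, 564),  # mg/dL
        "fasting_blood_sugar": AttributeRange(kind="categorical", n_levels=2),
        "resting_ecg": AttributeRange(kind="categorical", n_levels=3),
        "max_heart_rate": AttributeRange(71, 202),      # bpm
        "exercise_angina": AttributeRange(kind="categorical", n_levels=2),
        "oldpeak": AttributeRange(0.0, 6.2),            # ST depression
        "st_slope": AttributeRange(kind="categorical", n_levels=3),
        "num_vessels": AttributeRange(kind="categorical", n_levels=4),
    }


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int = 2000
    n_informative: int = 4
    n_noise: int = 16
    effect_sizes: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0)
    class_balance: float = 0.5
    seed: int = 0
    attribute_ranges: dict[str, AttributeRange] = field(
        default_factory=default_attribute_ranges
    )

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("at least one feature is required")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if len(self.effect_sizes) != self.n_informative:
            raise ValueError(
                f"effect_sizes length {len(self.effect_sizes)} != "
                f"n_informative {self.n_informative}"
            )

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_noise

    def feature_names(self) -> list[str]:
        names = list(self.attribute_ranges)
        extra = [f"feat_{i}" for i in range(len(names), self.n_features)]
        return (names + extra)[: self.n_features]

    def informative_names(self) -> list[str]:
        return self.feature_names()[: self.n_informative]


def _solve_intercept(eta: np.ndarray, balance: float) -> float:
    """Intercept b such that mean(expit(b + eta)) == balance."""
    f = lambda b: float(np.mean(expit(b + eta))) - balance
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:  # pathological effect sizes; fall back
        return float(np.log(balance / (1.0 - balance)))
    return float(brentq(f, lo, hi, xtol=1e-10))


def _latent_to_numeric(z: np.ndarray, low: float, high: float) -> np.ndarray:
    span = z.max() - z.min()
    if span == 0:
        return np.full_like(z, (low + high) / 2.0)
    # clip guards float rounding at the upper edge of the mapped range
    return np.clip(low + (high - low) * (z - z.min()) / span, low, high)


def _latent_to_categorical(z: np.ndarray, n_levels: int) -> np.ndarray:
    # equal-probability quantile bins -> uniform marginal level codes
    edges = np.quantile(z, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(edges, z, side="left").astype(int)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a labelled cohort table (features + binary ``target``).

    The first ``n_informative`` columns carry signal; the remaining
    ``n_noise`` columns are independent of the target.  The returned frame
    records the informative column names in ``df.attrs["informative"]``.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_samples, spec.n_features))
    beta = np.asarray(spec.effect_sizes, dtype=float)
    eta = z[:, : spec.n_informative] @ beta if spec.n_informative else np.zeros(spec.n_samples)
    intercept = _solve_intercept(eta, spec.class_balance)
    p = expit(intercept + eta)
    y = (rng.random(spec.n_samples) < p).astype(int)

    names = spec.feature_names()
    ranges = spec.attribute_ranges
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        attr = ranges.get(name, AttributeRange(0.0, 1.0))
        if attr.kind == "categorical":
            cols[name] = _latent_to_categorical(z[:, j], attr.n_levels)
        else:
            cols[name] = _latent_to_numeric(z[:, j], attr.low, attr.high)
    cols[TARGET_COLUMN] = y
    df = pd.DataFrame(cols)
    df.attrs["informative"] = spec.informative_names()
    return df


@dataclass(frozen=True)
class VitalSeriesSpec:
    length: int = 1000
    baseline: float = 75.0       # bpm (or mmHg for pressure channels)
    noise_sd: float = 3.0
    artifact_rate: float = 0.01
    artifact_magnitude: float = 40.0
    missing_rate: float = 0.02
    seed: int = 0
    start: str = "2024-07-01T00:00:00"
    period_s: float = 1.0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("artifact_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def generate_vital_series(spec: VitalSeriesSpec) -> pd.DataFrame:
    """Time-stamped vital-sign stream with sensor noise, spikes and gaps.

    Columns: ``timestamp`` (ISO-8601), ``value`` (NaN where missing),
    ``missing`` (0/1).
    """
    rng = np.random.default_rng(spec.seed)
    values = spec.baseline + rng.normal(0.0, spec.noise_sd, spec.length)
    artifacts = rng.random(spec.length) < spec.artifact_rate
    values = values + artifacts * spec.artifact_magnitude
    missing = rng.random(spec.length) < spec.missing_rate
    values = np.where(missing, np.nan, values)
    stamps = pd.date_range(spec.start, periods=spec.length,
                           freq=pd.Timedelta(seconds=spec.period_s))
    return pd.DataFrame({
        "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "value": values,
        "missing": missing.astype(int),
    })


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_vitals_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_vitals_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
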