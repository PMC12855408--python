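"""Shallow clinical feature construction and shallow/deep feature fusion.

Shallow features are interpretable clinical quantities (pulse pressure,
BMI, lipid panel values); deep features are externally computed embeddings
(e.g. ECG encoder outputs) supplied as precomputed vectors.  Fusion is a
plain concatenation — normalized shallow features first, then the deep
embedding — yielding one named high-dimensional vector per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FusedVector", "pulse_pressure", "bmi", "fuse", "fuse_tables",
           "load_deep_features"]


def pulse_pressure(systolic_mmHg: float, diastolic_mmHg: float) -> float:
    """Systolic minus diastolic pressure (mmHg), a marker of arterial
    stiffness.  Requires systolic >= diastolic > 0."""
    if diastolic_mmHg <= 0:
        raise ValueError("diastolic pressure must be positive")
    if diastolic_mmHg > systolic_mmHg:
        raise ValueError("diastolic pressure exceeds systolic")
    return systolic_mmHg - diastolic_mmHg


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight / height^2 (kg/m^2)."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / (height_m * height_m)


@dataclass(frozen=True)
class FusedVector:
    """Concatenated feature vector with provenance-preserving names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("fused feature names must be unique")


def fuse(
    shallow,
    deep,
    shallow_names: Sequence[str] | None = None,
    deep_names: Sequence[str] | None = None,
) -> FusedVector:
    """Concatenate a (normalized) shallow vector with a deep embedding.

    Order is preserved (shallow first); an empty deep vector yields
    shallow-only mode.  Raises on non-finite entries.
    """
    s = np.asarray(shallow, dtype=float).ravel()
    d = np.asarray(deep, dtype=float).ravel()
    if not np.isfinite(s).all() or not np.isfinite(d).all():
        raise ValueError("fused vectors must be finite")
    if shallow_names is None:
        shallow_names = [f"shallow_{i}" for i in range(s.size)]
    if deep_names is None:
        deep_names = [f"deep_{i}" for i in range(d.size)]
    if len(shallow_names) != s.size or len(deep_names) != d.size:
        raise ValueError("name vectors must match value lengths")
    return FusedVector(np.concatenate([s, d]),
                       tuple(shallow_names) + tuple(deep_names))


def load_deep_features(path, id_column: str = "sample_id") -> pd.DataFrame:
    """Read a deep-embedding CSV keyed by sample id."""
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ValueError(f"deep-feature table lacks id column {id_column!r}")
    return df


def fuse_tables(
    shallow: pd.DataFrame,
    deep: pd.DataFrame | None,
    id_column: str = "sample_id",
) -> pd.DataFrame:
    """Join a deep-embedding table onto the shallow table by sample id and
    concatenate columns (shallow first).  ``deep=None`` is shallow-only."""
    if deep is None:
        return shallow.copy()
    if id_column not in shallow.columns:
        raise ValueError(f"shallow table lacks id column {id_column!r}")
    clash = (set(shallow.columns) & set(deep.columns)) - {id_column}
    if clash:
        raise ValueError(f"duplicate feature names across tables: {sorted(clash)}")
    merged = shallow.merge(deep, on=id_column, how="inner", validate="one_to_one")
    return merged
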