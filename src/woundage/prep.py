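"""Preprocessing: total-area normalization, Z-score standardization, PLS-DR.

The classifier pipeline is strictly leakage-safe: normalization (an optional,
whole-cohort rescaling applied before any split) → train/validation split →
Z-score fitted on training rows only → supervised two-dimensional reduction
(PLS-DR: the first two NIPALS PLS latent variables of the standardized matrix
against the one-hot class encoding) fitted on training rows only.  Held-out and
external rows are only ever transformed with training-set parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import one_hot, pls_nipals
from .peaktable import PeakTable

__all__ = [
    "normalize_total_area",
    "ScalerParams",
    "zscore_fit",
    "zscore_apply",
    "zscore_invert",
    "ReducerParams",
    "plsdr_fit",
    "plsdr_apply",
]


def normalize_total_area(table: PeakTable) -> PeakTable:
    """Rescale every sample so its total area equals the cohort median total.

    The standard metabolomics convention for correcting per-injection loading
    differences.  Idempotent; raises on a zero-sum row (naming the sample).
    """
    totals = table.areas.sum(axis=1)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with non-positive total area: {zero}")
    target = float(totals.median())
    scaled = table.areas.mul(target / totals, axis=0)
    return PeakTable(scaled, table.meta.copy())


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature training mean and SD (population convention), in feature order."""

    mean: np.ndarray
    sd: np.ndarray
    feature_ids: tuple[str, ...]
    dropped: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd}, index=list(self.feature_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dropped=()) -> "ScalerParams":
        return cls(
            mean=frame["mean"].to_numpy(float),
            sd=frame["sd"].to_numpy(float),
            feature_ids=tuple(frame.index),
            dropped=tuple(dropped),
        )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, PeakTable):
        return X.log_areas()
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def zscore_fit(train: pd.DataFrame | np.ndarray, drop_constant: bool = False) -> ScalerParams:
    """Fit per-feature standardization parameters on training rows only.

    Uses the population (1/n) SD.  A constant training column is an error
    unless ``drop_constant`` is set, in which case it is removed and recorded
    in ``ScalerParams.dropped``.
    """
    frame = _as_frame(train)
    if len(frame) < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant and not drop_constant:
        raise ValueError(
            f"constant training column(s) {constant[:5]}{'...' if len(constant) > 5 else ''}; "
            "pass drop_constant=True to remove them"
        )
    keep = sd.index[sd > 0]
    return ScalerParams(
        mean=mean[keep].to_numpy(),
        sd=sd[keep].to_numpy(),
        feature_ids=tuple(keep),
        dropped=tuple(constant),
    )


def zscore_apply(params: ScalerParams, X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Standardize ``X`` with previously fitted training parameters."""
    frame = _as_frame(X)
    missing = [f for f in params.feature_ids if f not in frame.columns]
    if missing:
        raise KeyError(f"features missing from input: {missing[:5]}")
    sub = frame[list(params.feature_ids)]
    return (sub - params.mean) / params.sd


def zscore_invert(params: ScalerParams, Z: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Undo :func:`zscore_apply` (round-trips to ~1e-10)."""
    frame = _as_frame(Z) if not isinstance(Z, pd.DataFrame) else Z
    return frame * params.sd + params.mean


@dataclass(frozen=True)
class ReducerParams:
    """PLS-DR projection: standardized feature space → 2 latent coordinates."""

    x_mean: np.ndarray
    rotation: np.ndarray  # p×2
    feature_ids: tuple[str, ...]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rotation.shape[1] != 2:
            raise ValueError("PLS-DR reduces to exactly 2 dimensions")
        if not np.all(np.isfinite(self.rotation)):
            raise ValueError("reducer weights must be finite")


def plsdr_fit(X: pd.DataFrame | np.ndarray, labels) -> ReducerParams:
    """Fit the supervised 2-D reduction on standardized training data.

    The two coordinates are the first two PLS latent variables of X against the
    one-hot class encoding; training score vectors are mutually orthogonal.
    """
    frame = _as_frame(X)
    labels = [str(l) for l in labels]
    if len(set(labels)) < 2:
        raise ValueError("PLS-DR requires at least two classes at fit time")
    if frame.shape[1] < 2:
        raise ValueError("PLS-DR requires at least two feature columns")
    Y, classes = one_hot(labels)
    model = pls_nipals(frame.to_numpy(float), Y, A=2)
    return ReducerParams(
        x_mean=model.x_mean,
        rotation=model.x_rotation(),
        feature_ids=tuple(frame.columns),
        classes=tuple(classes),
    )


def plsdr_apply(params: ReducerParams, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project standardized data onto the fitted 2-D latent space."""
    frame = _as_frame(X)
    missing = [f for f in params.feature_ids if f not in frame.columns]
    if missing:
        raise KeyError(f"features missing from input: {missing[:5]}")
    arr = frame[list(params.feature_ids)].to_numpy(float)
    return (arr - params.x_mean) @ params.rotation
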