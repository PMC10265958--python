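"""Samples × features peak-area container with per-sample metadata.

A :class:`PeakTable` holds non-negative peak areas (one row per injected sample,
one column per chromatographic feature) together with two metadata fields per
sample: the time label (``control``, ``4`` … ``48`` hours post-contusion, or
``unknown``) and the sample role (``study``, ``qc`` or ``external``).

CSV layout: columns ``sample_id,label,role`` followed by one column per feature.
The round trip through CSV is lossless to 12 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PeakTable", "CONTROL_LABEL"]

CONTROL_LABEL = "control"
_META_COLUMNS = ["label", "role"]
_ROLES = {"study", "qc", "external"}


@dataclass
class PeakTable:
    """Peak areas plus sample metadata, indexed by sample id."""

    areas: pd.DataFrame  # index: sample_id, columns: feature ids, values: areas ≥ 0
    meta: pd.DataFrame  # index: sample_id, columns: label, role

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.areas.index.equals(self.meta.index):
            raise ValueError("areas and meta must share the same sample index")
        if self.areas.index.has_duplicates:
            dupes = self.areas.index[self.areas.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = self.areas.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("peak areas must be finite")
        if values.size and (values < 0).any():
            raise ValueError("peak areas must be non-negative")
        missing = [c for c in _META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns {missing}")
        bad_roles = set(self.meta["role"]) - _ROLES
        if bad_roles:
            raise ValueError(f"unknown sample roles {sorted(bad_roles)}")

    # -- selection ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def n_samples(self) -> int:
        return len(self.areas)

    def subset_role(self, role: str) -> "PeakTable":
        mask = self.meta["role"] == role
        return PeakTable(self.areas.loc[mask].copy(), self.meta.loc[mask].copy())

    def subset_labels(self, labels) -> "PeakTable":
        labels = set(labels)
        mask = self.meta["label"].isin(labels)
        return PeakTable(self.areas.loc[mask].copy(), self.meta.loc[mask].copy())

    def subset_samples(self, sample_ids) -> "PeakTable":
        ids = list(sample_ids)
        return PeakTable(self.areas.loc[ids].copy(), self.meta.loc[ids].copy())

    def subset_features(self, feature_ids) -> "PeakTable":
        cols = list(feature_ids)
        missing = [c for c in cols if c not in self.areas.columns]
        if missing:
            raise KeyError(f"features not present in table: {missing}")
        return PeakTable(self.areas[cols].copy(), self.meta.copy())

    def concat(self, other: "PeakTable") -> "PeakTable":
        if list(other.areas.columns) != list(self.areas.columns):
            raise ValueError("cannot concatenate tables with different feature ids")
        return PeakTable(
            pd.concat([self.areas, other.areas]), pd.concat([self.meta, other.meta])
        )

    def log_areas(self, pseudo: float = 0.0) -> pd.DataFrame:
        """Natural-log areas; ``pseudo`` is added first when zeros may occur."""
        values = self.areas + pseudo
        if (values.to_numpy() <= 0).any():
            raise ValueError("log transform requires strictly positive areas")
        return np.log(values)

    # -- persistence -------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta[_META_COLUMNS], self.areas], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakTable":
        frame = pd.read_csv(path, index_col="sample_id")
        meta = frame[_META_COLUMNS].astype(str)
        areas = frame.drop(columns=_META_COLUMNS).astype(float)
        return cls(areas, meta)
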