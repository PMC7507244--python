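"""Assembly, normalization and serialization of the 49-feature table.

One row per eye: 21 Scheimpflug-camera features, 27 OCT sublayer
features and gender (female = 0, male = 1), plus the group label.
Normalization is a z-score fitted on training rows only; validation rows
are always transformed with the training statistics, so information
cannot leak through the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cornea import GENDER_CODE, EyeRecord, NormativePattern
from .indices import extract_oct_features
from .registry import ALL_FEATURES, GENDER_FEATURE, GROUPS, PENTACAM_FEATURES

ID_COLUMNS = ("eye_id", "group")


@dataclass(frozen=True)
class FeatureTable:
    """Eyes x 49 features + group label, backed by a pandas DataFrame."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = list(ID_COLUMNS) + list(ALL_FEATURES)
        if list(self.df.columns) != expected:
            raise ValueError("feature table columns do not match the 49-feature registry")
        if self.df[list(ALL_FEATURES)].isna().any().any():
            raise ValueError("feature table contains missing values")
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"invalid group labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def features(self) -> pd.DataFrame:
        return self.df[list(ALL_FEATURES)]

    @property
    def labels(self) -> pd.Series:
        return self.df["group"]

    def subset_classes(self, classes: Sequence[str]) -> "FeatureTable":
        """Rows belonging to the given groups, in original order."""
        mask = self.df["group"].isin(list(classes))
        return FeatureTable(self.df.loc[mask].reset_index(drop=True), self.provenance)

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips float64 exactly
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "FeatureTable":
        return cls(pd.read_csv(path, float_precision="round_trip"), provenance if provenance is not None else str(path))


def assemble_table(cohort: Iterable[EyeRecord], pattern: NormativePattern,
                   provenance: str = "") -> FeatureTable:
    """Build the 49-column feature table for a cohort.

    Column order is the registry order; OCT features are computed from
    the zonal profiles against the supplied normative pattern.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for eye in cohort:
        row: dict[str, object] = {"eye_id": eye.eye_id, "group": eye.group}
        row.update({f: eye.scheimpflug[f] for f in PENTACAM_FEATURES})
        row.update(extract_oct_features(eye, pattern))
        row[GENDER_FEATURE] = GENDER_CODE[eye.gender]
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(ID_COLUMNS) + list(ALL_FEATURES))
    return FeatureTable(df=df, provenance=provenance)


@dataclass(frozen=True)
class Normalizer:
    """Per-feature z-score parameters learned from a training subset."""

    location: pd.Series
    scale: pd.Series

    @classmethod
    def fit(cls, rows: pd.DataFrame) -> "Normalizer":
        """Fit mean/SD (ddof=1) per column on training rows only.

        Raises on fewer than 2 rows or any zero-variance feature (the
        offending feature is named).
        """
        if len(rows) < 2:
            raise ValueError("need at least 2 training rows to fit a normalizer")
        location = rows.mean()
        scale = rows.std(ddof=1)
        degenerate = scale.index[(scale == 0) | ~np.isfinite(scale)].tolist()
        if degenerate:
            raise ValueError(f"zero-variance feature(s) in training rows: {degenerate}")
        return cls(location=location, scale=scale)

    def _check(self, rows: pd.DataFrame) -> None:
        if list(rows.columns) != list(self.location.index):
            raise ValueError("column mismatch between normalizer and data")

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        self._check(rows)
        return (rows - self.location) / self.scale

    def inverse_transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        self._check(rows)
        return rows * self.scale + self.location


def fit_normalizer(table: FeatureTable, rows: Sequence[int] | None = None,
                   features: Sequence[str] = ALL_FEATURES) -> Normalizer:
    """Fit a z-score normalizer on a training subset of a feature table
    (``rows`` are positional indices; None = all rows)."""
    df = table.features[list(features)]
    if rows is not None:
        df = df.iloc[list(rows)]
    return Normalizer.fit(df)


def apply_normalizer(state: Normalizer, rows: pd.DataFrame) -> pd.DataFrame:
    """Transform rows with training statistics (no re-fitting)."""
    return state.transform(rows)
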