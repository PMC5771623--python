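"""Samples-by-features matrix with explicit missing-value sentinels."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel carried by undefined feature values (division by zero, negative
#: radicand, missing band coverage).  Serialized as an empty cell.
UNDEFINED = float("nan")


@dataclass
class FeatureTable:
    """An ordered samples x named-features matrix.

    Missing entries carry NaN; nothing is ever silently imputed.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: list[str]) -> "FeatureTable":
        """Sub-table restricted to the named feature columns, in order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(list(self.sample_ids), list(names),
                            self.values[:, idx].copy())

    def hstack(self, other: "FeatureTable") -> "FeatureTable":
        """Column-wise concatenation; sample ids must match exactly."""
        if self.sample_ids != other.sample_ids:
            raise ValueError("cannot stack tables with different sample ids")
        return FeatureTable(
            list(self.sample_ids),
            list(self.feature_names) + list(other.feature_names),
            np.hstack([self.values, other.values]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids,
                                                        name="sample_id"),
                            columns=self.feature_names)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, na_rep="")

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        return cls(list(df.index.astype(str)), list(df.columns),
                   df.to_numpy(dtype=float))
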