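"""In-memory containers shared across modules.

The central object is :class:`OmicsMatrix`: a samples-by-features real
matrix with a binary outcome per sample and a block tag (``chemistry`` /
``metabolite`` / ``protein``) per feature.  Cohorts studied here have no
missing values; the container enforces this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

VALID_BLOCKS = ("chemistry", "metabolite", "protein")


@dataclass
class OmicsMatrix:
    """Samples x features matrix with per-sample labels and per-feature blocks.

    Parameters
    ----------
    values : pandas.DataFrame
        Real-valued matrix, index = sample ids, columns = feature ids.
    labels : pandas.Series
        Binary outcome per sample (1 = converter, 0 = non-converter),
        aligned with ``values.index``.
    block : pandas.Series
        Block tag per feature, aligned with ``values.columns``.
    informative_features : list of str
        Feature ids carrying a planted class effect (synthetic cohorts
        record ground truth here; empty for real data).
    """

    values: pd.DataFrame
    labels: pd.Series
    block: pd.Series
    informative_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.isna().stack()
            row, col = bad[bad].index[0]
            raise DataError(f"missing value at sample {row!r}, feature {col!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise SchemaError(f"duplicate feature id {dup!r}")
        if len(self.labels) != len(self.values):
            raise SchemaError("labels length does not match sample count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise SchemaError("labels must be binary 0/1")
        if len(self.block) != self.values.shape[1]:
            raise SchemaError("block annotation length does not match feature count")
        unknown = set(self.block) - set(VALID_BLOCKS)
        if unknown:
            raise SchemaError(f"unknown block tags: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        feature_ids = list(feature_ids)
        missing = set(feature_ids) - set(self.values.columns)
        if missing:
            raise SchemaError(f"unknown features requested: {sorted(missing)}")
        return OmicsMatrix(
            values=self.values[feature_ids].copy(),
            labels=self.labels.copy(),
            block=self.block.loc[feature_ids].copy(),
            informative_features=[f for f in self.informative_features if f in feature_ids],
        )

    def block_view(self, name: str) -> "OmicsMatrix":
        if name not in VALID_BLOCKS:
            raise SchemaError(f"unknown block {name!r}")
        cols = [f for f, b in self.block.items() if b == name]
        return self.subset_features(cols)
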