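"""Feature x sample expression matrices.

A thin, unit-aware wrapper around a :class:`pandas.DataFrame` with features
as rows and samples as columns.  Three units are supported:

``count``
    Non-negative integer read counts.
``rpm``
    Reads per million (non-negative floats).
``log_intensity``
    Real-valued log-scale intensities (e.g. log2 LFQ values) where missing
    values (NaN) are permitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("count", "rpm", "log_intensity")


@dataclass
class ExpressionMatrix:
    """Features x samples numeric table with an explicit unit."""

    data: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        values = self.data.to_numpy(dtype=float)
        if self.unit == "count":
            if np.isnan(values).any():
                raise ValueError("count matrices may not contain missing values")
            if (values < 0).any() or not np.allclose(values, np.round(values)):
                raise ValueError("counts must be non-negative integers")
            self.data = self.data.astype(np.int64)
        elif self.unit == "rpm":
            if np.isnan(values).any():
                raise ValueError("rpm matrices may not contain missing values")
            if (values < 0).any():
                raise ValueError("rpm values must be non-negative")
            self.data = self.data.astype(float)
        else:
            self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, unit: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, unit=unit)
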