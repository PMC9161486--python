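"""Ordered (feature, score) lists feeding enrichment analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RankedList:
    """Features sorted by descending score, ties broken lexicographically.

    The deterministic tie-break makes rankings reproducible across
    platforms regardless of the stability of the upstream sort.
    """

    features: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.scores):
            raise ValueError("features and scores differ in length")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in ranked list")
        s = np.asarray(self.scores, dtype=float)
        if np.isnan(s).any():
            raise ValueError("NaN scores are not allowed in a ranked list")
        for i in range(len(s) - 1):
            if s[i] < s[i + 1]:
                raise ValueError("scores are not sorted in descending order")
            if s[i] == s[i + 1] and self.features[i] > self.features[i + 1]:
                raise ValueError("tied scores are not in lexicographic feature order")

    def __len__(self) -> int:
        return len(self.features)

    @classmethod
    def from_scores(cls, scores: Mapping[str, float] | pd.Series) -> "RankedList":
        s = pd.Series(dict(scores), dtype=float)
        order = sorted(s.index, key=lambda f: (-s[f], f))
        return cls(tuple(order), tuple(float(s[f]) for f in order))

    def to_series(self) -> pd.Series:
        return pd.Series(list(self.scores), index=list(self.features), name="score")

    def to_rnk(self, path) -> None:
        self.to_series().to_csv(path, sep="\t", header=False)

    @classmethod
    def from_rnk(cls, path) -> "RankedList":
        df = pd.read_csv(path, sep="\t", header=None, names=["feature", "score"])
        return cls.from_scores(pd.Series(df["score"].values, index=df["feature"].astype(str)))
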