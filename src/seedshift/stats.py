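"""Two-group cohort statistics.

Covers the differential-expression path for tumor/normal isomiR matrices
(group fold changes, unpaired t-tests, Benjamini-Hochberg adjustment,
volcano classification) and the proteome path (regulation classes,
Fisher's exact gene-set enrichment, downshifted-Gaussian imputation of
left-censored intensities, ranked-list construction for preranked GSEA).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .ranking import RankedList

logger = logging.getLogger(__name__)

#: smallest positive double; stands in for p -> 0 in degenerate-variance cases
_MIN_P = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class Thresholds:
    """Significance cutoffs; strict inequalities throughout."""

    log2fc_cut: float = 2.0
    padj_cut: float = 0.05
    protein_p_cut: float = 0.05
    rpm_cut: float = 15.0

    def __post_init__(self) -> None:
        for name in ("log2fc_cut", "padj_cut", "protein_p_cut", "rpm_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group labelling with optional tumor->normal pairing."""

    group_of: Mapping[str, str]
    pairing: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.pairing is not None:
            values = list(self.pairing.values())
            if len(set(values)) != len(values):
                raise ValueError("pairing must be injective")
            unknown = set(self.pairing) | set(values)
            if not unknown <= set(self.group_of):
                raise ValueError("pairing refers to unlabelled samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_of)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.group_of), "group": list(self.group_of.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["sample_id"], df["group"])))


def log2_group_fc(
    values_g1: Sequence[float],
    values_g2: Sequence[float],
    pseudocount: float = 0.5,
) -> float:
    """log2 of the ratio of group means, stabilised by a pseudocount.

    The pseudocount (default 0.5 RPM) keeps zero-expression groups finite;
    set it to 0 for data that cannot be zero.
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    num = x.mean() + pseudocount
    den = y.mean() + pseudocount
    if den <= 0:
        raise ValueError("denominator mean plus pseudocount must be > 0")
    return float(np.log2(num / den))


def unpaired_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided unpaired t-test; ``variant`` selects Welch or Student df.

    Degenerate variances are handled explicitly: identical constant groups
    give (0, 1); constant groups with different means give an infinite t
    and the smallest representable p.
    """
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), _MIN_P
    t, p = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(t), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_classify(log2fc: float, p_adj: float, th: Thresholds = Thresholds()) -> str:
    """'sig_up' / 'sig_down' / 'ns' with strict threshold inequalities."""
    if not (np.isfinite(p_adj) and not np.isnan(log2fc)):
        raise ValueError("non-finite inputs")
    if p_adj < th.padj_cut:
        if log2fc > th.log2fc_cut:
            return "sig_up"
        if log2fc < -th.log2fc_cut:
            return "sig_down"
    return "ns"


def differential_expression(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    group1: str = "tumor",
    group2: str = "normal",
    thresholds: Thresholds = Thresholds(),
    pseudocount: float = 0.5,
    variant: str = "welch",
) -> pd.DataFrame:
    """Per-feature fold change, t-test, BH adjustment and volcano class.

    ``group1`` is the numerator of the fold change (tumor over normal).
    Returns a DataFrame indexed by feature with columns
    ``log2fc, t, p, p_adj, klass``.
    """
    g1 = design.samples_in(group1)
    g2 = design.samples_in(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 samples per group")
    a = matrix.data[g1].to_numpy(dtype=float)
    b = matrix.data[g2].to_numpy(dtype=float)
    lfc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    t = np.asarray(res.statistic, dtype=float).copy()
    p = np.asarray(res.pvalue, dtype=float).copy()
    # degenerate-variance rows, handled as in unpaired_t
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    same = degenerate & (a.mean(axis=1) == b.mean(axis=1))
    diff = degenerate & ~same
    t[same], p[same] = 0.0, 1.0
    t[diff] = np.copysign(np.inf, (a.mean(axis=1) - b.mean(axis=1))[diff])
    p[diff] = _MIN_P
    padj = bh_adjust(p)
    klass = [
        volcano_classify(float(l), float(q), thresholds) for l, q in zip(lfc, padj)
    ]
    return pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "p_adj": padj, "klass": klass},
        index=matrix.data.index,
    )


def protein_regulation(log2fc_vs_control: float, p: float, p_cut: float = 0.05) -> str:
    """'up' / 'down' / 'unchanged' with strict sign and p cutoffs."""
    if not (np.isfinite(log2fc_vs_control) and np.isfinite(p)):
        raise ValueError("non-finite inputs")
    if p < p_cut:
        if log2fc_vs_control > 0:
            return "up"
        if log2fc_vs_control < 0:
            return "down"
    return "unchanged"


def fisher_enrichment(
    regulated: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test of a set among regulated.

    The universe is the detected background; returns ``(odds_ratio, p)``
    where the odds ratio is ``(a*d)/(b*c)`` with ``inf`` allowed.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    regulated = set(regulated)
    gene_set = set(gene_set)
    if not regulated <= universe or not gene_set <= universe:
        raise ValueError("regulated and gene_set must be subsets of the universe")
    a = len(regulated & gene_set)
    b = len(regulated - gene_set)
    c = len(gene_set - regulated)
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return odds, float(p)


def impute_downshift(
    matrix: ExpressionMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Replace missing log-intensities by downshifted-Gaussian draws.

    Models detection-limit censoring: for each sample, missing cells are
    drawn from Normal(mean_s - shift*sd_s, (width*sd_s)^2) computed from
    that sample's observed values.  Width 0.3 / shift 1.8 are the common
    proteomics defaults.  Observed cells are returned untouched.
    """
    if matrix.unit != "log_intensity":
        raise ValueError("impute_downshift expects a log_intensity matrix")
    if rng is None:
        rng = np.random.default_rng(seed)
    df = matrix.data.copy()
    for col in df.columns:
        vals = df[col]
        missing = vals.isna()
        if not missing.any():
            continue
        observed = vals[~missing]
        if observed.empty:
            raise ValueError(f"sample {col!r} is entirely missing")
        sd = observed.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"sample {col!r} has zero observed sd")
        draws = rng.normal(observed.mean() - shift * sd, width * sd, missing.sum())
        df.loc[missing, col] = draws
    return ExpressionMatrix(df, unit="log_intensity")


def ranked_list_from_groups(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    treatment_group: str,
    reference_group: str,
    method: str | None = None,
    pseudocount: float = 0.0,
) -> RankedList:
    """Per-feature fold change of treatment vs reference, as a ranked list.

    ``method`` is ``'difference'`` (difference of group means; the log2
    fold change when the matrix already holds log2 intensities) or
    ``'ratio'`` (log2 ratio of group means on a linear scale).  By default
    it is inferred from the matrix unit.
    """
    if method is None:
        method = "difference" if matrix.unit == "log_intensity" else "ratio"
    if method not in ("difference", "ratio"):
        raise ValueError("method must be 'difference' or 'ratio'")
    treat = design.samples_in(treatment_group)
    ref = design.samples_in(reference_group)
    if not treat or not ref:
        raise ValueError("both groups must contain at least one sample")
    tm = matrix.data[treat].mean(axis=1)
    rm = matrix.data[ref].mean(axis=1)
    if method == "difference":
        scores = tm - rm
    else:
        scores = np.log2((tm + pseudocount) / (rm + pseudocount))
    scores = scores.dropna()
    return RankedList.from_scores(scores)
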