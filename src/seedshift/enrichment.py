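"""Gene-set activity scores and a self-contained GSEA engine.

Two complementary tools for relating gene sets to a phenotype:

* a *single-sample activity score* — the per-patient median of z-scaled
  expression over the genes of a set (used for, e.g., an E2F-target
  activity readout per tumor);
* *gene set enrichment analysis* with the weighted Kolmogorov-Smirnov
  running-sum statistic, normalised enrichment scores, permutation
  p-values and a permutation FDR, in two modes: preranked with gene-set
  permutation, and phenotype permutation over a Spearman-correlation
  ranking metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ExpressionMatrix
from .ranking import RankedList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. a Hallmark collection); source is metadata."""

    sets: Mapping[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, members in dict(self.sets).items():
            members = frozenset(str(g) for g in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in members):
                raise ValueError(f"gene set {name!r} contains empty gene ids")
            clean[str(name)] = members
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def zscale_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-scale each gene over all patients (sample sd, ddof=1).

    Zero-variance genes cannot be scaled; they are emitted as all-missing
    rows and logged.  Missing input values stay missing.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scaling needs at least 2 patients")
    df = matrix.data.astype(float)
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    degenerate = ~(sd > 0)
    if degenerate.any():
        logger.warning(
            "zscale_genes: %d zero-variance genes set to missing", int(degenerate.sum())
        )
    z = df.sub(mean, axis=0).div(sd, axis=0)
    z.loc[degenerate] = np.nan
    return ExpressionMatrix(z, unit="log_intensity")


def activity_score(zmatrix: ExpressionMatrix, gene_set: Iterable[str]) -> pd.Series:
    """Per-patient median of z-scaled expression over a gene set.

    Genes of the set absent from the matrix (or missing for a patient)
    are skipped for that patient.
    """
    genes = [g for g in set(gene_set) if g in zmatrix.data.index]
    if not genes:
        raise ValueError("no gene of the set is present in the matrix")
    scores = zmatrix.data.loc[genes].median(axis=0, skipna=True)
    scores.name = "activity_score"
    return scores


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks for ties); NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = sps.spearmanr(x, y).statistic
    return float(r)


def correlation_rank_metric(
    expression: ExpressionMatrix,
    phenotype: Sequence[float],
) -> RankedList:
    """Per-gene Spearman correlation with a phenotype, as a ranked list.

    Genes with undefined correlation (zero rank variance) are excluded
    and logged.
    """
    pheno = np.asarray(phenotype, dtype=float)
    if pheno.size != expression.shape[1]:
        raise ValueError("phenotype length must equal the number of patients")
    values = expression.data.to_numpy(dtype=float)
    r = _rank_corr_matrix(values, pheno)
    scores = pd.Series(r, index=expression.data.index)
    bad = scores.isna()
    if bad.any():
        logger.warning(
            "correlation_rank_metric: dropped %d genes with undefined correlation",
            int(bad.sum()),
        )
    return RankedList.from_scores(scores[~bad])


def _rank_corr_matrix(values: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Row-wise Spearman r between a matrix and a vector (vectorised)."""
    ranks = sps.rankdata(values, axis=1)
    pr = sps.rankdata(phenotype)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    pc = pr - pr.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (pc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ pc) / denom
    r[denom == 0] = np.nan
    return r


def gsea_es(
    ranked: RankedList,
    gene_set: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running sum.

    Walking down the ranked list, hits increment the running sum by
    ``|score|^p / sum_hits |score|^p`` and misses decrement it by
    ``1/(N - N_hits)``; the ES is the running-sum value of maximal
    absolute deviation (signed).  With ``weight_p = 0`` this reduces to
    the classic unweighted KS statistic.
    """
    members = set(gene_set)
    hit = np.fromiter((f in members for f in ranked.features), bool, len(ranked))
    nh = int(hit.sum())
    if nh == 0 or nh == len(ranked):
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    scores = np.asarray(ranked.scores, dtype=float)
    running = _running_sum(scores, hit, weight_p)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight_p: float) -> np.ndarray:
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    nh = int(hit.sum())
    if total == 0:  # all hit scores exactly zero: fall back to uniform increments
        hit_w = hit.astype(float)
        total = float(nh)
    steps = hit_w / total - (~hit) / (len(scores) - nh)
    return np.cumsum(steps)


def _es_batch(scores: np.ndarray, hit_matrix: np.ndarray, weight_p: float) -> np.ndarray:
    """ES for many hit indicator rows over one fixed ranking (vectorised)."""
    w = np.abs(scores) ** weight_p
    hit_w = hit_matrix * w
    totals = hit_w.sum(axis=1, keepdims=True)
    nh = hit_matrix.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] == 0
    if degenerate.any():
        hit_w[degenerate] = hit_matrix[degenerate].astype(float)
        totals = hit_w.sum(axis=1, keepdims=True)
    steps = hit_w / totals - (~hit_matrix) / (len(scores) - nh)
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(len(running)), idx]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    n_perm: int
    weight_p: float


def gsea_significance(
    sets: GeneSetCollection,
    ranked: RankedList | None = None,
    expression: ExpressionMatrix | None = None,
    phenotype: Sequence[float] | None = None,
    mode: str = "preranked_setperm",
    n_perm: int = 1000,
    weight_p: float = 1.0,
    min_set_size: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """NES, permutation p and FDR q for every (sufficiently large) set.

    ``preranked_setperm`` draws random gene sets of matching size from the
    ranked universe as the null; ``phenotype_perm`` permutes the phenotype
    vector and recomputes the Spearman-correlation ranking for each
    permutation.  NES divides ES by the mean |null ES| of matching sign;
    p uses the +1-corrected same-sign tail; q follows the standard
    sign-stratified pooled-NES FDR procedure.  Deterministic under a
    fixed seed.
    """
    if mode not in ("preranked_setperm", "phenotype_perm"):
        raise ValueError("mode must be 'preranked_setperm' or 'phenotype_perm'")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)

    if mode == "phenotype_perm":
        if expression is None or phenotype is None:
            raise ValueError("phenotype mode needs expression and phenotype")
        ranked = correlation_rank_metric(expression, phenotype)
    if ranked is None:
        raise ValueError("preranked mode needs a ranked list")

    universe = list(ranked.features)
    feat_index = {f: i for i, f in enumerate(universe)}
    scores = np.asarray(ranked.scores, dtype=float)
    n = len(universe)

    usable: dict[str, np.ndarray] = {}
    for name in sorted(sets.sets):
        idx = np.array(sorted(feat_index[g] for g in sets[name] if g in feat_index), dtype=int)
        if len(idx) < min_set_size:
            logger.warning(
                "gsea: skipping set %r (%d members in universe < %d)",
                name, len(idx), min_set_size,
            )
            continue
        if len(idx) == n:
            logger.warning("gsea: skipping set %r (covers the whole universe)", name)
            continue
        usable[name] = idx
    if not usable:
        return []

    obs_es = {}
    for name, idx in usable.items():
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        obs_es[name] = _es_batch(scores, hit[None, :], weight_p)[0]

    null_es: dict[str, np.ndarray] = {}
    if mode == "preranked_setperm":
        # random same-size subsets; one draw batch is shared per set size
        by_size: dict[int, np.ndarray] = {}
        for name, idx in usable.items():
            k = len(idx)
            if k not in by_size:
                draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
                hits = np.zeros((n_perm, n), dtype=bool)
                np.put_along_axis(hits, draws, True, axis=1)
                by_size[k] = _es_batch(scores, hits, weight_p)
            null_es[name] = by_size[k]
    else:
        values = expression.data.to_numpy(dtype=float)
        pheno = np.asarray(phenotype, dtype=float)
        kept = [i for i, f in enumerate(expression.data.index) if f in feat_index]
        values = values[kept]
        row_names = [expression.data.index[i] for i in kept]
        member_masks = {
            name: np.fromiter((f in sets[name] for f in row_names), bool, len(row_names))
            for name in usable
        }
        nulls = {name: np.empty(n_perm) for name in usable}
        for b in range(n_perm):
            perm = rng.permutation(pheno)
            r = _rank_corr_matrix(values, perm)
            r = np.nan_to_num(r, nan=0.0)
            order = np.argsort(-r, kind="stable")
            s_sorted = r[order]
            for name, mask in member_masks.items():
                nulls[name][b] = _es_batch(s_sorted, mask[order][None, :], weight_p)[0]
        null_es = nulls

    # sign-stratified normalisation
    def _norm(es_value: float, nulls: np.ndarray) -> float:
        same = nulls[nulls > 0] if es_value >= 0 else -nulls[nulls < 0]
        if same.size == 0:
            return np.nan
        return es_value / same.mean()

    nes_obs = {name: _norm(obs_es[name], null_es[name]) for name in usable}
    null_nes_pool: list[np.ndarray] = []
    for name in usable:
        nulls = null_es[name]
        pos = nulls[nulls > 0]
        neg = nulls[nulls < 0]
        normed = np.concatenate(
            [
                pos / pos.mean() if pos.size else pos,
                neg / (-neg).mean() if neg.size else neg,
            ]
        )
        null_nes_pool.append(normed)
    pooled = np.concatenate(null_nes_pool)

    results = []
    obs_nes_values = np.array([nes_obs[name] for name in usable])
    for name, idx in usable.items():
        es = obs_es[name]
        nulls = null_es[name]
        same = nulls[nulls > 0] if es >= 0 else nulls[nulls < 0]
        extreme = (same >= es).sum() if es >= 0 else (same <= es).sum()
        p = (1 + int(extreme)) / (1 + same.size)
        nes = nes_obs[name]
        if np.isnan(nes):
            logger.warning("gsea: no same-sign null ES for set %r; q undefined", name)
            q = np.nan
        else:
            if nes >= 0:
                null_frac_all = (pooled >= 0).mean()
                null_tail = (pooled >= nes).mean() / null_frac_all if null_frac_all else np.nan
                obs_side = obs_nes_values[obs_nes_values >= 0]
                obs_tail = (obs_side >= nes).mean()
            else:
                null_frac_all = (pooled < 0).mean()
                null_tail = (pooled <= nes).mean() / null_frac_all if null_frac_all else np.nan
                obs_side = obs_nes_values[obs_nes_values < 0]
                obs_tail = (obs_side <= nes).mean()
            if not np.isfinite(null_tail) or obs_tail == 0:
                q = np.nan
            else:
                q = min(1.0, null_tail / obs_tail)
        results.append(
            EnrichmentResult(name, len(idx), float(es), float(nes), float(p), float(q),
                             n_perm, weight_p)
        )
    return results


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.set_name, r.size, r.es, r.nes, r.p_perm, r.fdr_q) for r in results
    ]
    return pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "q"])


def bubble_summary(
    results_by_condition: Mapping[str, Iterable[EnrichmentResult]],
) -> pd.DataFrame:
    """Long-format (condition, set, NES, q) table over the full grid.

    Combinations missing from a condition's results are emitted with NaN
    so downstream bubble-heatmap rendering sees a complete grid.
    """
    if not results_by_condition:
        raise ValueError("need at least one condition")
    per_cond = {
        cond: {r.set_name: r for r in results}
        for cond, results in results_by_condition.items()
    }
    all_sets = sorted({s for d in per_cond.values() for s in d})
    rows = []
    for cond, d in per_cond.items():
        for set_name in all_sets:
            r = d.get(set_name)
            rows.append(
                (cond, set_name,
                 r.nes if r else np.nan,
                 r.fdr_q if r else np.nan)
            )
    return pd.DataFrame(rows, columns=["condition", "set", "nes", "q"])
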