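"""Activity scores, Spearman ranking and the GSEA engine."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from seedshift.enrichment import (
    GeneSetCollection,
    activity_score,
    bubble_summary,
    correlation_rank_metric,
    gsea_es,
    gsea_significance,
    spearman,
    zscale_genes,
)
from seedshift.matrix import ExpressionMatrix
from seedshift.ranking import RankedList


def _em(data, **kw):
    return ExpressionMatrix(pd.DataFrame(data, **kw), unit="log_intensity")


class TestZscale:
    def test_hand_example(self):
        z = zscale_genes(_em({"p1": [1.0], "p2": [2.0], "p3": [3.0]}, index=["g"]))
        assert list(z.data.loc["g"]) == pytest.approx([-1, 0, 1])

    def test_constant_gene_becomes_missing(self):
        z = zscale_genes(_em({"p1": [5.0, 1.0], "p2": [5.0, 2.0], "p3": [5.0, 3.0]},
                             index=["flat", "g"]))
        assert z.data.loc["flat"].isna().all()
        assert not z.data.loc["g"].isna().any()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = _em(rng.normal(10, 3, (20, 8)))
        once = zscale_genes(m)
        twice = zscale_genes(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            zscale_genes(_em({"p1": [1.0, 2.0]}))


class TestActivityScore:
    def test_median_over_set_genes(self):
        z = _em({"p1": [-1.0, 0.0, 2.0]}, index=["g1", "g2", "g3"])
        assert activity_score(z, {"g1", "g2", "g3"})["p1"] == pytest.approx(0.0)

    def test_non_set_genes_irrelevant(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(0, 1, (10, 5)),
                            index=[f"g{i}" for i in range(10)])
        z = ExpressionMatrix(data, unit="log_intensity")
        before = activity_score(z, {"g0", "g1", "g2"})
        data2 = data.copy()
        data2.loc["g9"] *= 100
        after = activity_score(ExpressionMatrix(data2, unit="log_intensity"),
                               {"g0", "g1", "g2"})
        assert before.equals(after)

    def test_missing_set_rejected(self):
        z = _em({"p1": [1.0], "p2": [2.0]}, index=["g1"])
        with pytest.raises(ValueError):
            activity_score(z, {"absent"})

    def test_affine_invariance(self):
        # per-gene affine transforms (positive scale) cancel in z-scaling
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(rng.normal(8, 2, (30, 40)),
                           index=[f"g{i}" for i in range(30)])
        a = rng.uniform(0.5, 3.0, 30)
        b = rng.normal(0, 5, 30)
        transformed = raw.mul(a, axis=0).add(b, axis=0)
        gene_set = {f"g{i}" for i in range(10)}
        s1 = activity_score(zscale_genes(ExpressionMatrix(raw, unit="log_intensity")), gene_set)
        s2 = activity_score(zscale_genes(ExpressionMatrix(transformed, unit="log_intensity")), gene_set)
        assert np.max(np.abs(s1 - s2)) < 1e-12


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3, 5], [10, 20, 21, 100]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 5], [9, 3, 2, -4]) == pytest.approx(-1.0)

    def test_midrank_example(self):
        # ranks x = [1, 2.5, 2.5, 4], y = [1, 3, 2, 4]; Pearson = 3/sqrt(10)
        assert spearman([1, 2, 2, 3], [1, 3, 2, 4]) == pytest.approx(3 / math.sqrt(10))

    def test_degenerate_is_nan(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))


class TestCorrelationRankMetric:
    def test_self_and_anti_phenotype(self):
        pheno = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(0, 1, (5, 5)), index=[f"g{i}" for i in range(5)])
        data.loc["gpos"] = pheno
        data.loc["gneg"] = -pheno
        rl = correlation_rank_metric(ExpressionMatrix(data, unit="log_intensity"), pheno)
        assert rl.features[0] == "gpos" and rl.scores[0] == pytest.approx(1.0)
        assert rl.features[-1] == "gneg" and rl.scores[-1] == pytest.approx(-1.0)

    def test_matches_per_gene_oracle(self):
        rng = np.random.default_rng(5)
        pheno = rng.normal(0, 1, 30)
        data = pd.DataFrame(rng.normal(0, 1, (20, 30)),
                            index=[f"g{i:02d}" for i in range(20)])
        rl = correlation_rank_metric(ExpressionMatrix(data, unit="log_intensity"), pheno)
        expected = {g: spearman(data.loc[g], pheno) for g in data.index}
        order = sorted(expected, key=lambda g: (-expected[g], g))
        assert list(rl.features) == order
        for f, s in zip(rl.features, rl.scores):
            assert s == pytest.approx(expected[f], abs=1e-12)


def _es_oracle(scores, hit_flags, p=1.0):
    """Running-sum walk written from the definition."""
    n = len(scores)
    nh = sum(hit_flags)
    denom = sum(abs(s) ** p for s, h in zip(scores, hit_flags) if h)
    running, cur, best = [], 0.0, 0.0
    for s, h in zip(scores, hit_flags):
        if h:
            cur += (abs(s) ** p) / denom if denom else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
    return max(running, key=abs)


class TestGseaEs:
    def test_single_top_hit_is_one(self):
        rl = RankedList.from_scores({f"g{i}": 10.0 - i for i in range(10)})
        es, _ = gsea_es(rl, {"g0"})
        assert es == pytest.approx(1.0)

    def test_bottom_hit_is_negative(self):
        rl = RankedList.from_scores({f"g{i}": 10.0 - i for i in range(10)})
        es, _ = gsea_es(rl, {"g9"})
        assert es < 0

    def test_hand_walk_example(self):
        rl = RankedList.from_scores({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})
        es, running = gsea_es(rl, {"g1", "g3"})
        assert es == pytest.approx(2 / 3)
        assert running == pytest.approx([5 / 8, 5 / 8 - 1 / 3, 2 / 3, 1 / 3, 0.0])

    def test_matches_oracle_on_all_small_subsets(self):
        rng = np.random.default_rng(6)
        for n in range(2, 11):
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            features = [f"g{i}" for i in range(n)]
            rl = RankedList(tuple(features), tuple(float(s) for s in scores))
            for mask in range(1, 2**n - 1):
                members = {features[i] for i in range(n) if mask >> i & 1}
                es, _ = gsea_es(rl, members)
                flags = [f in members for f in features]
                ref = _es_oracle(scores, flags)
                # an exact +/- tie in |running sum| leaves the ES sign
                # float-order dependent; the magnitude is always unique
                assert abs(es) == pytest.approx(abs(ref), abs=1e-12)
                assert min(abs(es - ref), abs(es + ref)) < 1e-12

    def test_weight_zero_reduces_to_unweighted_ks(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(0, 1, 50))[::-1]
        features = [f"g{i:02d}" for i in range(50)]
        rl = RankedList(tuple(features), tuple(float(s) for s in scores))
        members = set(rng.choice(features, 10, replace=False))
        es, _ = gsea_es(rl, members, weight_p=0.0)
        flags = [f in members for f in features]
        # classic KS: hits step 1/Nh regardless of score
        cur, best = 0.0, 0.0
        for h in flags:
            cur += 1 / 10 if h else -1 / 40
            if abs(cur) > abs(best):
                best = cur
        assert es == pytest.approx(best, abs=1e-12)

    def test_agrees_with_gseapy_reference(self):
        rl = RankedList.from_scores({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})
        es, _ = gsea_es(rl, {"g1", "g3"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import gseapy

            res = gseapy.prerank(
                rnk=rl.to_series().reset_index(),
                gene_sets={"s": ["g1", "g3"]},
                permutation_num=10, min_size=1, max_size=10,
                seed=1, outdir=None, no_plot=True,
            )
        assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-6)

    def test_degenerate_sets_rejected(self):
        rl = RankedList.from_scores({"g1": 2.0, "g2": 1.0})
        with pytest.raises(ValueError):
            gsea_es(rl, {"absent"})
        with pytest.raises(ValueError):
            gsea_es(rl, {"g1", "g2"})


class TestGseaSignificance:
    def _planted_ranking(self, n=200, seed=8):
        rng = np.random.default_rng(seed)
        scores = {f"g{i:03d}": float(rng.normal(0, 1)) for i in range(n)}
        for i in range(20):
            scores[f"g{i:03d}"] += 3.0  # planted top block
        return RankedList.from_scores(pd.Series(scores))

    def test_planted_set_significant(self):
        rl = self._planted_ranking()
        sets = GeneSetCollection({"planted": frozenset(f"g{i:03d}" for i in range(20))})
        res = gsea_significance(sets, ranked=rl, n_perm=1000, seed=9)[0]
        assert res.nes > 1 and res.p_perm <= 0.01

    def test_deterministic_under_seed(self):
        rl = self._planted_ranking(seed=10)
        sets = GeneSetCollection({
            "planted": frozenset(f"g{i:03d}" for i in range(20)),
            "random": frozenset(f"g{i:03d}" for i in range(50, 80)),
        })
        a = gsea_significance(sets, ranked=rl, n_perm=200, seed=11)
        b = gsea_significance(sets, ranked=rl, n_perm=200, seed=11)
        assert a == b

    def test_null_pvalues_calibrated(self):
        # random sets on random rankings: rejection rate at alpha=.05 stays
        # within a Monte-Carlo band around nominal
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 100
        for rep in range(reps):
            scores = pd.Series(rng.normal(0, 1, 100),
                               index=[f"g{i:03d}" for i in range(100)])
            rl = RankedList.from_scores(scores)
            members = frozenset(rng.choice(scores.index, 15, replace=False))
            res = gsea_significance(GeneSetCollection({"s": members}),
                                    ranked=rl, n_perm=200,
                                    rng=np.random.default_rng(1000 + rep))[0]
            rejections += res.p_perm <= 0.05
        assert 0.02 * reps <= rejections <= 0.10 * reps

    def test_small_sets_skipped(self):
        rl = self._planted_ranking(seed=13)
        sets = GeneSetCollection({"tiny": frozenset({"g000", "g001"})})
        assert gsea_significance(sets, ranked=rl, n_perm=100, seed=1) == []

    def test_phenotype_permutation_mode(self):
        rng = np.random.default_rng(14)
        pheno = rng.normal(0, 1, 40)
        data = pd.DataFrame(rng.normal(0, 1, (60, 40)),
                            index=[f"g{i:02d}" for i in range(60)])
        for i in range(10):  # genes tracking the phenotype
            data.iloc[i] = pheno + rng.normal(0, 0.4, 40)
        em = ExpressionMatrix(data, unit="log_intensity")
        sets = GeneSetCollection({"tracking": frozenset(f"g{i:02d}" for i in range(10))})
        res = gsea_significance(sets, expression=em, phenotype=pheno,
                                mode="phenotype_perm", n_perm=200, seed=15)[0]
        assert res.es > 0 and res.p_perm <= 0.05


class TestBubbleSummary:
    def _result(self, name, nes, q):
        from seedshift.enrichment import EnrichmentResult

        return EnrichmentResult(name, 10, nes / 2, nes, 0.01, q, 100, 1.0)

    def test_single_row_passthrough(self):
        table = bubble_summary({"c1": [self._result("s1", 1.5, 0.02)]})
        assert len(table) == 1
        assert table.loc[0, "nes"] == 1.5 and table.loc[0, "q"] == 0.02

    def test_grid_complete_with_missing(self):
        table = bubble_summary({
            "c1": [self._result("s1", 1.0, 0.1)],
            "c2": [self._result("s2", -1.0, 0.2)],
        })
        assert len(table) == 4
        missing = table[(table.condition == "c1") & (table.set == "s2")]
        assert missing["nes"].isna().all()
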