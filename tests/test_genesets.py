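"""Exact-test oracles (full enumeration) and gene-set statistics."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbpscape.annotation import FeatureRecord, build_annotation
from rbpscape.genesets import (
    compare_intron_lengths,
    filter_splicing_events,
    fisher_binding_regulation,
    geneset_enrichment,
    hypergeom_overlap,
    regress_log2_changes,
    significant_genes,
)
from rbpscape.simulate import DeConfig, simulate_de_tables


def enumerate_hypergeom_tail(n_bg: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """Oracle: fraction of all C(n_bg, n_b) draws of B with >= n_overlap
    elements inside a fixed A, by exhaustive enumeration."""
    a = set(range(n_a))
    hits = total = 0
    for draw in itertools.combinations(range(n_bg), n_b):
        total += 1
        if len(a & set(draw)) >= n_overlap:
            hits += 1
    return hits / total


def enumerate_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Oracle: sum of probabilities of all margin-fixed tables with
    probability <= the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(r1, c1) + 1) if prob(x) <= p_obs + 1e-12)


class TestSignificantGenes:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "log2_fold_change", "padj"]
        ).set_index("gene")

    def test_threshold_rules(self):
        de = self.make_table(
            [
                ("down", -1.0, 0.01),
                ("weak", 0.5, 0.001),  # 0.5 < log2(1.5) ~ 0.585
                ("unadjusted", 1.0, 0.2),
                ("up", 0.9, 0.04),
            ]
        )
        up, down = significant_genes(de)
        assert down == {"down"}
        assert up == {"up"}

    def test_boundary_is_inclusive_on_fold_change(self):
        de = self.make_table([("edge", math.log2(1.5), 0.049)])
        up, down = significant_genes(de)
        assert up == {"edge"}

    def test_missing_padj_warns_and_excludes(self):
        de = self.make_table([("a", 2.0, np.nan), ("b", 2.0, 0.01)])
        with pytest.warns(UserWarning, match="adjusted P"):
            up, _ = significant_genes(de)
        assert up == {"b"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        de = self.make_table(
            [(f"g{i}", float(rng.normal(0, 1)), float(rng.uniform(0, 0.1)))
             for i in range(200)]
        )
        loose = set.union(*significant_genes(de, lfc_threshold=0.3))
        tight = set.union(*significant_genes(de, lfc_threshold=1.0))
        assert tight <= loose


class TestHypergeomOverlap:
    def test_full_overlap_5_5_10(self):
        bg = [f"g{i}" for i in range(10)]
        res = hypergeom_overlap(bg[:5], bg[:5], bg)
        assert res.p_value == pytest.approx(1 / 252, rel=1e-9)

    @pytest.mark.parametrize(
        "n_bg, n_a, n_b, n_ov",
        [(10, 5, 5, 5), (10, 4, 6, 3), (12, 5, 4, 2), (15, 7, 6, 4), (8, 3, 3, 0)],
    )
    def test_matches_exhaustive_enumeration(self, n_bg, n_a, n_b, n_ov):
        bg = [f"g{i}" for i in range(n_bg)]
        a = set(bg[:n_a])
        # construct a B with exactly n_ov overlap
        b = set(bg[:n_ov]) | set(bg[n_a : n_a + n_b - n_ov])
        res = hypergeom_overlap(a, b, bg)
        assert res.n_overlap == n_ov
        assert res.p_value == pytest.approx(
            enumerate_hypergeom_tail(n_bg, n_a, n_b, n_ov), abs=1e-12
        )

    def test_degenerate_all_equal(self):
        bg = [f"g{i}" for i in range(6)]
        res = hypergeom_overlap(bg, bg, bg)
        assert res.p_value == pytest.approx(1.0)

    def test_rejects_sets_outside_background(self):
        with pytest.raises(ValueError, match="stranger"):
            hypergeom_overlap({"stranger"}, set(), {"a", "b"})


class TestFisher:
    def test_diagonal_2x2_is_one_third(self):
        expressed = {"a", "b", "c", "d"}
        res = fisher_binding_regulation({"a", "b"}, {"a", "b"}, expressed)
        assert res.table == ((2, 0), (0, 2))
        assert res.p_value == pytest.approx(1 / 3, rel=1e-9)

    @pytest.mark.parametrize(
        "a, b, c, d",
        [(2, 0, 0, 2), (5, 3, 2, 8), (1, 9, 10, 10), (0, 7, 6, 4), (12, 3, 4, 15)],
    )
    def test_matches_margin_fixed_enumeration(self, a, b, c, d):
        genes = [f"g{i}" for i in range(a + b + c + d)]
        targets = set(genes[: a + b])
        regulated = set(genes[:a]) | set(genes[a + b : a + b + c])
        res = fisher_binding_regulation(targets, regulated, genes)
        assert res.table == ((a, b), (c, d))
        assert res.p_value == pytest.approx(
            enumerate_fisher_two_sided(a, b, c, d), abs=1e-12
        )

    def test_perfect_association_is_extreme(self):
        genes = [f"g{i}" for i in range(1000)]
        targets = set(genes[:50])
        res = fisher_binding_regulation(targets, targets, genes)
        assert res.p_value < 1e-10

    def test_null_pvalues_roughly_uniform(self):
        """Independent marginals: Fisher P approximately uniform."""
        rng = np.random.default_rng(42)
        genes = np.array([f"g{i}" for i in range(10_000)])
        pvals = []
        for _ in range(40):
            t = set(rng.choice(genes, 1000, replace=False))
            r = set(rng.choice(genes, 800, replace=False))
            pvals.append(fisher_binding_regulation(t, r, genes).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRegression:
    def de(self, lfc: dict[str, float], padj=0.001) -> pd.DataFrame:
        return pd.DataFrame(
            {"log2_fold_change": list(lfc.values()), "padj": padj},
            index=list(lfc.keys()),
        )

    def test_identity_and_anticorrelation(self):
        a = self.de({"g1": 1.0, "g2": -2.0, "g3": 3.0, "g4": -1.5})
        assert regress_log2_changes(a, a).slope == pytest.approx(1.0)
        neg = self.de({k: -v for k, v in
                       zip(a.index, a["log2_fold_change"])})
        res = regress_log2_changes(a, neg)
        assert res.slope == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_requires_three_shared_significant_genes(self):
        a = self.de({"g1": 1.0, "g2": -2.0})
        with pytest.raises(ValueError, match=">= 3"):
            regress_log2_changes(a, a)

    def test_independent_tables_give_null_slope(self):
        rejections = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(200)]
            a = self.de(dict(zip(genes, rng.normal(0, 2, 200))))
            b = self.de(dict(zip(genes, rng.normal(0, 2, 200))))
            if regress_log2_changes(a, b, restrict="all").p_value < 0.05:
                rejections += 1
        assert rejections <= 2  # <= 10% of seeds


class TestIntronLengths:
    def annotation(self, intron_scale: dict[str, int]):
        records = []
        pos = 0
        for gid, intron_len in intron_scale.items():
            records += [
                FeatureRecord("chr1", pos, pos + intron_len + 200, "+", "gene", gid),
                FeatureRecord("chr1", pos, pos + 100, "+", "exon", gid),
                FeatureRecord(
                    "chr1", pos + 100 + intron_len, pos + intron_len + 200, "+", "exon", gid
                ),
            ]
            pos += intron_len + 300
        return build_annotation(records)

    def test_long_intron_set_detected(self):
        rng = np.random.default_rng(1)
        lengths = {}
        down, other = [], []
        for i in range(100):
            gid = f"down{i}"
            lengths[gid] = int(rng.integers(8_000, 12_000))
            down.append(gid)
        for i in range(100):
            gid = f"other{i}"
            lengths[gid] = int(rng.integers(800, 1_200))
            other.append(gid)
        ann = self.annotation(lengths)
        cmp = compare_intron_lengths({"down": down, "other": other}, ann)
        row = cmp.iloc[0]
        assert row["p_value"] < 1e-6
        assert row["median_a"] > row["median_b"]

    def test_identical_sets_not_significant(self):
        ann = self.annotation({f"g{i}": 1000 for i in range(10)})
        genes = list(ann.genes)
        cmp = compare_intron_lengths({"a": genes, "b": genes}, ann)
        # all lengths equal -> degenerate, reported non-applicable
        assert math.isnan(cmp.iloc[0]["p_value"])

    def test_intronless_genes_count_as_zero(self):
        records = [
            FeatureRecord("chr1", 0, 100, "+", "gene", "single"),
            FeatureRecord("chr1", 0, 100, "+", "exon", "single"),
        ]
        ann = build_annotation(records)
        from rbpscape.genesets import intron_length_table

        table = intron_length_table({"s": ["single"]}, ann)
        assert table.iloc[0]["total_intron_length"] == 0


class TestSplicingFilter:
    def events(self, rows):
        return pd.DataFrame(
            rows, columns=["event_id", "event_type", "sep_score", "q_value"]
        )

    def test_rules_and_direction(self):
        ev = self.events(
            [
                ("inc", "cassette", 0.6, 0.01),
                ("exc", "cassette", -0.7, 0.04),
                ("boundary", "cassette", 0.5, 0.01),  # strict: dropped
                ("weak_q", "cassette", 0.9, 0.05),  # strict: dropped
            ]
        )
        kept = filter_splicing_events(ev)
        assert list(kept["event_id"]) == ["inc", "exc"]
        assert list(kept["direction"]) == ["inclusion", "exclusion"]


class TestGenesetEnrichment:
    def test_exact_term_ranks_first(self):
        bg = [f"g{i}" for i in range(100)]
        terms = {f"t{j}": set(bg[10 * j : 10 * j + 10]) for j in range(10)}
        res = geneset_enrichment(terms["t3"], terms, bg)
        assert res.iloc[0]["term"] == "t3"
        assert res.iloc[0]["q_value"] < 0.05

    def test_null_false_positive_rate_controlled(self):
        bg = [f"g{i}" for i in range(500)]
        rng = np.random.default_rng(5)
        false_hits = 0
        n_rep = 25
        for _ in range(n_rep):
            terms = {
                f"t{j}": set(rng.choice(bg, 25, replace=False)) for j in range(20)
            }
            query = set(rng.choice(bg, 40, replace=False))
            res = geneset_enrichment(query, terms, bg)
            false_hits += int((res["q_value"] < 0.05).sum() > 0)
        assert false_hits / n_rep <= 0.15

    def test_zero_overlap_term_not_ahead_of_hits(self):
        bg = [f"g{i}" for i in range(60)]
        terms = {"hit": set(bg[:10]), "miss": set(bg[50:60])}
        res = geneset_enrichment(set(bg[:10]), terms, bg).set_index("term")
        assert res.loc["miss", "p_value"] >= res.loc["hit", "p_value"]


class TestSimulatedDeTables:
    def test_constructed_overlap_recovered(self):
        cfg = DeConfig(n_background=800, n_sig_a=60, n_sig_b=60, overlap_fraction=0.5)
        de_a, de_b, truth = simulate_de_tables(cfg, seed=3)
        up_a, down_a = significant_genes(de_a)
        assert (up_a | down_a) == truth["sig_a"]
        res = hypergeom_overlap(truth["sig_a"], truth["sig_b"], truth["background"])
        assert res.n_overlap == len(truth["overlap"]) == 30

    def test_anticorrelated_shared_effects(self):
        cfg = DeConfig(effect_sign=-1, overlap_fraction=0.5)
        de_a, de_b, _ = simulate_de_tables(cfg, seed=6)
        res = regress_log2_changes(de_a, de_b)
        assert res.slope < 0
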