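"""Methylation contexts, weighted gene levels, category profiles."""

import numpy as np
import pandas as pd
import pytest

import t2tdup as T
from t2tdup.methylation import (call_context, category_profiles, gene_levels,
                                levels_frame,
                                methylation_expression_correlation)
from t2tdup.models import GeneModel

from conftest import random_dna


class TestCallContext:
    @pytest.mark.parametrize("seq,pos,expected", [
        ("ACGT", 1, "CG"),
        ("ACAGT", 1, "CHG"),
        ("ACATT", 1, "CHH"),
        ("ACCGT", 1, "CHG"),
    ])
    def test_plus_strand(self, seq, pos, expected):
        assert call_context(seq, pos, "+") == expected

    def test_minus_strand(self):
        # G on plus at pos 2 -> C on minus; downstream (leftward) CG
        assert call_context("ACGT", 2, "-") == "CG"

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError):
            call_context("AAGT", 1, "+")

    def test_context_partition_exhaustive(self):
        """Every reference C on either strand gets exactly one context."""
        seq = random_dna(10_000, 42)
        for i, base in enumerate(seq[:-2]):
            if base == "C":
                assert call_context(seq, i, "+") in ("CG", "CHG", "CHH")
        for i, base in enumerate(seq):
            if base == "G" and i >= 2:
                assert call_context(seq, i, "-") in ("CG", "CHG", "CHH")

    def test_cg_strand_symmetry(self):
        seq = random_dna(5_000, 43)
        for i in range(len(seq) - 2):
            if seq[i] == "C" and call_context(seq, i, "+") == "CG":
                assert call_context(seq, i + 1, "-") == "CG"


def _records(rows):
    return pd.DataFrame(rows, columns=["chrom", "position", "strand",
                                       "count_methylated",
                                       "count_unmethylated", "context",
                                       "trinucleotide"])


class TestGeneLevels:
    def test_weighted_pooling(self):
        recs = _records([("c", 10, "+", 3, 7, "CG", "CGA"),
                         ("c", 20, "+", 1, 9, "CG", "CGT")])
        gene = GeneModel("g1", "c", 0, 100)
        lv = {x.context: x.level for x in gene_levels(recs, [gene])}
        assert lv["CG"] == pytest.approx(4 / 20)

    def test_fully_methylated(self):
        recs = _records([("c", 10, "+", 5, 0, "CHH", "CTA")])
        (lv,) = [x for x in gene_levels(recs, [GeneModel("g1", "c", 0, 100)])
                 if x.context == "CHH"]
        assert lv.level == 1.0

    def test_no_coverage_is_nan(self):
        recs = _records([("c", 500, "+", 1, 1, "CG", "CGA")])
        (lv,) = [x for x in gene_levels(recs, [GeneModel("g1", "c", 0, 100)])
                 if x.context == "CG"]
        assert np.isnan(lv.level)

    def test_min_coverage_filter(self):
        recs = _records([("c", 10, "+", 1, 0, "CG", "CGA"),
                         ("c", 20, "+", 0, 10, "CG", "CGT")])
        (lv,) = [x for x in gene_levels(recs, [GeneModel("g1", "c", 0, 100)],
                                        min_coverage=5)
                 if x.context == "CG"]
        assert lv.level == 0.0  # only the deep site counts

    def test_pooled_identity_vs_per_read_tally(self, tiny):
        """Gene level equals the read-level tally, not a mean of fractions."""
        genome, _, genes, _ = tiny
        cx = T.simulate_methylation(genome, genes[:5],
                                    {"CG": 0.6, "CHG": 0.3, "CHH": 0.1},
                                    depth=9, seed=3,
                                    regions={"chr01": [(0, 60_000)]})
        g = genes[0]
        levels = {x.context: x.level for x in gene_levels(cx, [g])}
        sub = cx[(cx["position"] > g.start)
                 & (cx["position"] <= g.end)]
        for ctx in ("CG", "CHG", "CHH"):
            rows = sub[sub["context"] == ctx]
            # brute-force per-read tally
            reads = []
            for r in rows.itertuples():
                reads.extend([1] * r.count_methylated)
                reads.extend([0] * r.count_unmethylated)
            assert levels[ctx] == pytest.approx(np.mean(reads))

    def test_binomial_concentration_in_gene(self, tiny):
        genome, _, genes, _ = tiny
        g = max(genes, key=lambda x: x.length)
        cx = T.simulate_methylation(genome, [g], {"CG": 0.6, "CHG": 0.3,
                                                  "CHH": 0.1},
                                    depth=50, seed=4,
                                    regions={g.chrom: [(g.start, g.end)]})
        (lv,) = [x for x in gene_levels(cx, [g]) if x.context == "CG"]
        assert lv.n_cytosines >= 50
        assert 0.5 <= lv.level <= 0.7


class TestCategoryProfiles:
    def test_planted_category_ordering(self, tiny):
        genome, _, genes, _ = tiny
        picked = genes[:6]
        cats = {g.gene_id: ("AED" if i < 3 else "NoDiff")
                for i, g in enumerate(picked)}
        gene_means = {g.gene_id: {"CG": 0.3 if cats[g.gene_id] == "AED"
                                  else 0.6} for g in picked}
        merged = {}
        for g in picked:
            merged.setdefault(g.chrom, []).append(
                (max(0, g.start - 2500), g.end + 2500))
        from t2tdup.models import merge_intervals
        merged = {c: merge_intervals(v) for c, v in merged.items()}
        cx = T.simulate_methylation(genome, picked,
                                    {"CG": 0.45, "CHG": 0.3, "CHH": 0.1},
                                    depth=20, seed=5, gene_means=gene_means,
                                    regions=merged)
        summary, track = category_profiles(cx, picked, cats)
        cg = summary[summary["context"] == "CG"].set_index("category")
        assert cg.loc["AED", "mean"] < cg.loc["NoDiff", "mean"]
        # gene-body bins reflect the planted contrast too
        body = track[(track["context"] == "CG") & (track["bin"] >= 20)
                     & (track["bin"] < 80)]
        m = body.groupby("category")["mean_level"].mean()
        assert m["AED"] < m["NoDiff"]

    def test_uniform_methylation_flat_track(self, tiny):
        genome, _, genes, _ = tiny
        picked = genes[:3]
        cx = T.simulate_methylation(genome, picked,
                                    {"CG": 0.5, "CHG": 0.5, "CHH": 0.5},
                                    depth=40, seed=6,
                                    regions={g.chrom: [(g.start - 2500,
                                                        g.end + 2500)]
                                             for g in picked})
        _, track = category_profiles(cx, picked,
                                     {g.gene_id: "all" for g in picked})
        cg = track[track["context"] == "CG"]["mean_level"].dropna()
        assert cg.max() - cg.min() < 0.25

    def test_single_gene_category_equals_gene_level(self, tiny):
        genome, _, genes, _ = tiny
        g = genes[0]
        cx = T.simulate_methylation(genome, [g], {"CG": 0.6, "CHG": 0.3,
                                                  "CHH": 0.1},
                                    depth=20, seed=7,
                                    regions={g.chrom: [(g.start, g.end)]})
        summary, _ = category_profiles(cx, [g], {g.gene_id: "solo"})
        lv = levels_frame(gene_levels(cx, [g]))
        for ctx in ("CG", "CHG", "CHH"):
            want = lv[lv["context"] == ctx]["level"].iloc[0]
            got = summary[(summary["context"] == ctx)]["mean"].iloc[0]
            assert got == pytest.approx(want)


class TestMethylationExpressionCorrelation:
    def _pairs(self, n):
        return pd.DataFrame([{"pair_id": f"P{i}", "gene_a": f"a{i}",
                              "gene_b": f"b{i}"} for i in range(n)])

    def test_perfect_linear_relation(self):
        samples = [f"S{i}" for i in range(6)]
        lv = pd.DataFrame([np.linspace(0.1, 0.6, 6)], index=["a0"],
                          columns=samples)
        # level linear in log2(TPM+1), the correlated quantity
        expr = pd.DataFrame([2 ** np.linspace(1, 8, 6) - 1], index=["a0"],
                            columns=samples)
        gene_table, _ = methylation_expression_correlation(
            {"CG": lv}, expr, self._pairs(0))
        assert abs(gene_table["r"].iloc[0]) > 0.99

    def test_planted_anticorrelation_flagged(self):
        flagged = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            samples = [f"S{i}" for i in range(6)]
            expr_rows, lv_rows, genes = {}, {}, []
            for i in range(20):
                g = f"a{i}"
                genes.append(g)
                e = rng.lognormal(4, 1, 6)
                noise = rng.normal(0, 0.03, 6)
                lv_rows[g] = np.clip(
                    0.8 - 0.15 * (np.log2(e + 1) - np.log2(e + 1).mean())
                    + noise, 0, 1)
                expr_rows[g] = e
            lv = pd.DataFrame(lv_rows, index=samples).T
            expr = pd.DataFrame(expr_rows, index=samples).T
            pairs = pd.DataFrame([{"pair_id": f"P{i}", "gene_a": f"a{i}",
                                   "gene_b": f"a{(i + 1) % 20}"}
                                  for i in range(20)])
            _, pair_table = methylation_expression_correlation(
                {"CG": lv}, expr, pairs)
            flagged += pair_table["significant"].mean()
        assert flagged / n_seeds >= 0.9

    def test_null_flag_rate_controlled(self):
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            samples = [f"S{i}" for i in range(8)]
            genes = [f"a{i}" for i in range(100)]
            lv = pd.DataFrame(rng.uniform(0.2, 0.8, (100, 8)), index=genes,
                              columns=samples)
            expr = pd.DataFrame(rng.lognormal(4, 1, (100, 8)), index=genes,
                                columns=samples)
            gene_table, _ = methylation_expression_correlation(
                {"CG": lv}, expr, self._pairs(0))
            rates.append(gene_table["significant"].mean())
        assert np.mean(rates) <= 0.1

    def test_constant_level_excluded(self):
        samples = [f"S{i}" for i in range(6)]
        lv = pd.DataFrame([[0.5] * 6], index=["a0"], columns=samples)
        expr = pd.DataFrame([np.linspace(1, 100, 6)], index=["a0"],
                            columns=samples)
        gene_table, _ = methylation_expression_correlation(
            {"CG": lv}, expr, self._pairs(0))
        assert len(gene_table) == 0

    def test_too_few_samples_rejected(self):
        samples = [f"S{i}" for i in range(3)]
        lv = pd.DataFrame([[0.1, 0.2, 0.3]], index=["a0"], columns=samples)
        with pytest.raises(ValueError):
            methylation_expression_correlation({"CG": lv}, lv,
                                               self._pairs(0))
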