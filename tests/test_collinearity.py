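"""Collinear blocks: anchors, DP chaining vs brute force, WGD extraction."""

import itertools
import math

import numpy as np
import pytest

import t2tdup as T
from t2tdup.collinearity import (WGD_KS_WINDOW, _best_chain_dp, _chain_score,
                                 brute_force_best_chain, chain_blocks,
                                 extract_wgd_pairs, homolog_pairs,
                                 random_pairs)
from t2tdup.models import GeneModel, GenomeSet, KaKsResult

from conftest import random_dna


def _mk_genes(n_per_chrom, chroms=("c1", "c2"), pitch=2000, width=900):
    genes = []
    for c in chroms:
        for i in range(n_per_chrom):
            genes.append(GeneModel(f"{c}_g{i}", c, i * pitch,
                                   i * pitch + width))
    return genes


class TestHomologPairs:
    def test_identical_cds_anchor(self):
        from t2tdup.synth import random_cds
        cds = random_cds(100, np.random.default_rng(0))
        seq1 = random_dna(1000, 1) + cds + random_dna(1000, 2)
        seq2 = random_dna(500, 3) + cds + random_dna(1500, 4)
        genome = GenomeSet({"c1": seq1, "c2": seq2})
        genes = [GeneModel("gA", "c1", 1000, 1000 + len(cds)),
                 GeneModel("gB", "c2", 500, 500 + len(cds))]
        anchors = homolog_pairs(genes, genome)
        assert len(anchors) == 1
        assert anchors[0][2] == pytest.approx(1.0)

    def test_planted_duplicates_anchored(self, demo):
        from t2tdup.collinearity import gene_ranks
        anchors = homolog_pairs(demo["genes"], demo["genome"])
        got = {frozenset((a, b)) for a, b, _ in anchors}
        ranks = gene_ranks(demo["genes"])
        planted = set()
        for p in demo["ledger"].gene_pairs:
            (ca, ra), (cb, rb) = ranks[p["gene_a"]], ranks[p["gene_b"]]
            if ca == cb and abs(ra - rb) <= 5:
                continue  # tandem-like pairs are excluded by design
            planted.add(frozenset((p["gene_a"], p["gene_b"])))
        assert len(planted & got) >= 0.95 * len(planted)

    def test_unrelated_cds_no_anchor(self):
        from t2tdup.synth import random_cds
        rng = np.random.default_rng(5)
        a, b = random_cds(100, rng), random_cds(100, rng)
        genome = GenomeSet({"c1": a, "c2": b})
        genes = [GeneModel("gA", "c1", 0, len(a)),
                 GeneModel("gB", "c2", 0, len(b))]
        assert homolog_pairs(genes, genome) == []


class TestChaining:
    def _anchors(self, positions, chroms=("c1", "c2")):
        genes = _mk_genes(30, chroms)
        return [(f"{chroms[0]}_g{i}", f"{chroms[1]}_g{j}", 1.0)
                for i, j in positions], genes

    def test_six_consecutive_one_block(self):
        anchors, genes = self._anchors([(i, i) for i in range(6)])
        blocks = chain_blocks(anchors, genes)
        assert len(blocks) == 1
        assert len(blocks[0].pairs) == 6

    def test_below_threshold_no_block(self):
        anchors, genes = self._anchors([(i, i) for i in range(4)])
        assert chain_blocks(anchors, genes, min_block_pairs=5) == []

    def test_planted_wgd_layout_tiled(self, demo):
        anchors = homolog_pairs(demo["genes"], demo["genome"])
        blocks = chain_blocks(anchors, demo["genes"])
        in_blocks = {frozenset(p) for b in blocks for p in b.pairs}
        planted = {frozenset((p["gene_a"], p["gene_b"]))
                   for p in demo["ledger"].gene_pairs
                   if p["origin"] == "WGD"}
        assert len(planted & in_blocks) >= 0.9 * len(planted)

    def test_block_monotonicity_invariant(self, demo):
        from t2tdup.collinearity import gene_ranks
        anchors = homolog_pairs(demo["genes"], demo["genome"])
        blocks = chain_blocks(anchors, demo["genes"])
        ranks = gene_ranks(demo["genes"])
        for b in blocks:
            ra = [ranks[a][1] for a, _ in b.pairs]
            rb = [ranks[x][1] for _, x in b.pairs]
            assert ra == sorted(ra)
            assert rb == sorted(rb) or rb == sorted(rb, reverse=True)

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_equals_bruteforce(self, seed):
        """Sparse DP matches exhaustive chain enumeration on <= 12 anchors."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        points = list({(int(rng.integers(0, 15)), int(rng.integers(0, 15)))
                       for _ in range(n)})
        best_dp = None
        for orientation in "+-":
            chain, score = _best_chain_dp(points, orientation, max_gap=25)
            if chain and (best_dp is None or score > best_dp[1]):
                best_dp = (chain, score)
        _, bf_score = brute_force_best_chain(points, max_gap=25)
        assert best_dp[1] == pytest.approx(bf_score)


class TestWgdExtraction:
    def _block(self, ks_values):
        pairs = [(f"a{i}", f"b{i}") for i in range(len(ks_values))]
        table = {frozenset(p): KaKsResult(0, 0, 0, 0, 0, 0, k / 4, k,
                                          0.25, "ok")
                 for p, k in zip(pairs, ks_values)}
        return T.CollinearBlock(pairs, "c1", "c2"), table

    def test_inclusive_lower_bound(self):
        block, table = self._block([0.15] * 5)
        assert len(extract_wgd_pairs([block], table)) == 5
        assert block.median_ks == pytest.approx(0.15)

    def test_outside_window_excluded(self):
        block, table = self._block([0.40] * 5)
        assert extract_wgd_pairs([block], table) == []

    def test_undefined_ks_block_excluded(self):
        block, table = self._block([0.2] * 5)
        nan_table = {k: KaKsResult(0, 0, 0, 0, 0, 0, math.nan, math.nan,
                                   math.nan, "saturated") for k in table}
        assert extract_wgd_pairs([block], nan_table) == []

    def test_idempotent(self):
        block, table = self._block([0.18, 0.2, 0.22, 0.25, 0.16])
        first = extract_wgd_pairs([block], table)
        second = extract_wgd_pairs([block], table)
        assert [(w.gene_a, w.gene_b) for w in first] \
            == [(w.gene_a, w.gene_b) for w in second]

    def test_planted_wgd_pairs_extracted(self, demo):
        gidx = {g.gene_id: g for g in demo["genes"]}
        anchors = homolog_pairs(demo["genes"], demo["genome"])
        blocks = chain_blocks(anchors, demo["genes"])
        table = {}
        for b in blocks:
            for a, x in b.pairs:
                key = frozenset((a, x))
                try:
                    table[key] = T.kaks_pair(
                        gidx[a].cds_sequence(demo["genome"]),
                        gidx[x].cds_sequence(demo["genome"]))
                except ValueError:
                    pass
        wgd = extract_wgd_pairs(blocks, table)
        got = {frozenset((w.gene_a, w.gene_b)) for w in wgd}
        planted = {frozenset((p["gene_a"], p["gene_b"]))
                   for p in demo["ledger"].gene_pairs
                   if p["origin"] == "WGD"}
        assert len(planted & got) >= 0.9 * len(planted)


class TestRandomPairs:
    def test_exhaustion(self):
        ids = list("ABCDE")
        pairs = random_pairs(ids, n=10_000, seed=0)
        assert len(pairs) == 10
        assert set(pairs) == set(
            tuple(sorted(p)) for p in itertools.combinations(ids, 2))

    def test_seed_reproducible(self):
        ids = [f"g{i}" for i in range(100)]
        assert random_pairs(ids, 50, seed=7) == random_pairs(ids, 50, seed=7)

    def test_full_scale_sample_distinct(self):
        ids = [f"g{i}" for i in range(20_000)]
        pairs = random_pairs(ids, n=10_000, seed=1)
        assert len(pairs) == 10_000
        assert len(set(pairs)) == 10_000
        assert all(a != b for a, b in pairs)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            random_pairs(["only"], 10, seed=0)
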