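"""Segmental duplications: self-alignment, filters, gene pairs, stats."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import t2tdup as T
from t2tdup import seqio
from t2tdup.models import GenomeSet, GeneModel, SDRecord, reciprocal_overlap
from t2tdup.pipeline import satellite_mask
from t2tdup.sd import (assign_sd_gene_pairs, compare_sd_ks, filter_sds,
                       self_align, summarize_sds)

from conftest import random_dna


def planted_recovery(sds, truth_sds):
    """Best reciprocal overlap of each planted SD among detected ones."""
    out = []
    for t in truth_sds:
        best = 0.0
        ta = (t["chrom_a"], t["start_a"], t["end_a"])
        tb = (t["chrom_b"], t["start_b"], t["end_b"])
        for s in sds:
            sa = (s.chrom_a, s.start_a, s.end_a)
            sb = (s.chrom_b, s.start_b, s.end_b)

            def ro(x, y):
                if x[0] != y[0]:
                    return 0.0
                return reciprocal_overlap((x[1], x[2]), (y[1], y[2]))

            best = max(best, min(ro(sa, ta), ro(sb, tb)),
                       min(ro(sa, tb), ro(sb, ta)))
        out.append(best)
    return out


@pytest.fixture(scope="module")
def detected(demo, demo_arrays):
    calls = T.scan_telomeres(demo["genome"])
    mask = satellite_mask(demo_arrays, calls)
    cands = self_align(demo["genome"], mask=mask)
    return cands, filter_sds(cands)


class TestSelfAlign:
    def test_planted_sds_recovered(self, demo, detected):
        _, sds = detected
        recov = planted_recovery(sds, demo["ledger"].sds)
        assert all(r >= 0.8 for r in recov)

    def test_exact_duplicate_identity_one(self):
        block = random_dna(2000, 21)
        genome = GenomeSet({"c1": random_dna(5000, 22) + block
                            + random_dna(5000, 23),
                            "c2": random_dna(4000, 24) + block
                            + random_dna(6000, 25)})
        cands = self_align(genome)
        hits = [c for c in cands if c.length >= 1500]
        assert hits
        assert max(c.identity for c in hits) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_empirical_null_no_candidates(self, seed):
        """No planted SDs + masked tandem arrays: nothing >= 1 kb."""
        plan = T.GenomePlan(n_chromosomes=2, chrom_length=150_000,
                            cen_array_span=20_000, sd_specs=[],
                            n_gene_pairs=0, n_collinear_blocks=0,
                            seed=200 + seed)
        genome, ledger, genes, tes = T.generate_genome(plan)
        from t2tdup.centromeres import genome_tandem_arrays
        arrays = genome_tandem_arrays(genome, min_period=50, max_period=500)
        mask = satellite_mask(arrays, T.scan_telomeres(genome))
        cands = self_align(genome, mask=mask)
        assert [c for c in cands if c.length >= 1000] == []

    def test_k_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            self_align(GenomeSet({"c": "ACGTACGT"}), k=31)

    def test_invariants_on_emitted_records(self, detected):
        _, sds = detected
        for s in sds:
            assert s.identity >= 0.90
            assert s.length >= 1000
            assert (s.chrom_a, s.start_a, s.end_a) \
                != (s.chrom_b, s.start_b, s.end_b)
            assert s.kind == ("intra" if s.chrom_a == s.chrom_b else "inter")


class TestFilters:
    def _rec(self, ident, length, chrom_b="c2"):
        return SDRecord("c1", 0, length, chrom_b, 50_000, 50_000 + length,
                        ident, length)

    def test_identity_boundary(self):
        assert filter_sds([self._rec(0.89, 2000)]) == []
        kept = filter_sds([self._rec(0.90, 1000)])
        assert len(kept) == 1  # both thresholds inclusive

    def test_length_boundary(self):
        assert filter_sds([self._rec(0.95, 999)]) == []

    def test_collinear_block_exclusion(self):
        sd = self._rec(0.95, 2000)
        region = (("c1", [(0, 2500)]), ("c2", [(49_000, 53_000)]))
        assert filter_sds([sd], [region]) == []
        # partial containment is kept
        region2 = (("c1", [(0, 1000)]), ("c2", [(49_000, 53_000)]))
        assert len(filter_sds([sd], [region2])) == 1

    def test_palindrome_discarded(self):
        sd = SDRecord("c1", 0, 2000, "c1", 500, 2500, 0.95, 2000)
        assert filter_sds([sd]) == []


class TestGenePairs:
    def test_planted_pairs_recovered(self, demo, detected):
        _, sds = detected
        pairs = assign_sd_gene_pairs(sds, demo["genes"])
        got = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
        want = {frozenset((p["gene_a"], p["gene_b"]))
                for p in demo["ledger"].gene_pairs if p["origin"] == "SD"}
        assert want <= got

    def test_fifty_percent_rule(self):
        sd = SDRecord("c1", 1000, 3000, "c2", 1000, 3000, 0.95, 2000)
        inside = GeneModel("gA", "c1", 1500, 2500)
        partner = GeneModel("gB", "c2", 1500, 2500)
        below = GeneModel("gC", "c1", 2020, 4020)  # 49% inside
        pairs = assign_sd_gene_pairs([sd], [inside, partner, below])
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("gA", "gB")]
        assert pairs[0].overlap_a >= 0.5 and pairs[0].overlap_b >= 0.5

    def test_deduplication_keeps_best_identity(self):
        ga = GeneModel("gA", "c1", 1500, 2500)
        gb = GeneModel("gB", "c2", 1500, 2500)
        sd1 = SDRecord("c1", 1000, 3000, "c2", 1000, 3000, 0.92, 2000)
        sd2 = SDRecord("c1", 1200, 3200, "c2", 1200, 3200, 0.97, 2000)
        pairs = assign_sd_gene_pairs([sd1, sd2], [ga, gb])
        assert len(pairs) == 1
        assert pairs[0].sd.identity == 0.97

    def test_sd_without_genes(self):
        sd = SDRecord("c1", 0, 2000, "c2", 0, 2000, 0.95, 2000)
        assert assign_sd_gene_pairs([sd], []) == []


class TestSummaries:
    def test_counts_and_coverage(self, demo, detected):
        _, sds = detected
        summary = summarize_sds(sds, demo["genome"])
        assert summary["n_intra"] + summary["n_inter"] == summary["n_sds"]
        assert summary["coverage_bp"] <= summary["genome_bp"]
        assert summary["intra_pct"] + summary["inter_pct"] \
            == pytest.approx(100.0, abs=0.02)

    def test_empty(self, demo):
        s = summarize_sds([], demo["genome"])
        assert s["n_sds"] == 0 and s["coverage_bp"] == 0


class TestCompareKs:
    def test_identical_samples_p_one(self):
        x = list(np.random.default_rng(0).normal(0.2, 0.05, 50))
        mi, mt, p, u = compare_sd_ks(x, list(x))
        assert mi == pytest.approx(mt)
        assert p >= 0.9

    def test_complete_separation_u_zero(self):
        _, _, _, u = compare_sd_ks([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_shifted_distributions_significant(self, seed):
        rng = np.random.default_rng(seed)
        intra = rng.normal(0.20, 0.05, 500)
        inter = rng.normal(0.26, 0.05, 500)
        mi, mt, p, _ = compare_sd_ks(intra, inter)
        assert p < 1e-3
        assert mi < mt

    def test_empty_group_nan(self):
        mi, mt, p, u = compare_sd_ks([], [1.0])
        assert np.isnan(p)

    def test_matches_scipy_directly(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        _, _, p, u = compare_sd_ks(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic")
        assert p == pytest.approx(ref.pvalue)


class TestRoundTrip:
    def test_paf_round_trip_preserves_filtering(self, tmp_path, detected):
        cands, sds = detected
        path = tmp_path / "cands.paf"
        seqio.write_paf(cands, path)
        reread = seqio.read_paf(path)
        sds2 = filter_sds(reread)
        key = lambda s: (s.chrom_a, s.start_a, s.end_a, s.chrom_b,
                         s.start_b, s.end_b, round(s.identity, 6), s.kind)
        assert sorted(map(key, sds)) == sorted(map(key, sds2))

    def test_blast_tabular_coordinates_converted(self, tmp_path):
        line = ("c1\tc2\t95.50\t2000\t80\t10\t101\t2100\t5001\t7000\t"
                "0.0\t3000\n")
        p = tmp_path / "hits.tsv"
        p.write_text(line)
        (rec,) = seqio.read_blast_tabular(p)
        assert (rec.start_a, rec.end_a) == (100, 2100)
        assert (rec.start_b, rec.end_b) == (5000, 7000)
        assert rec.identity == pytest.approx(0.955)
        assert rec.strand == "+"
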