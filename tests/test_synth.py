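"""Synthetic-genome generator: planted truth, determinism, error paths."""

import numpy as np
import pytest

import t2tdup as T
from t2tdup.align import global_identity
from t2tdup.kaks import kaks_pair
from t2tdup.synth import (PackingError, SaturationError,
                          mutate_cds_to_target_ks, random_cds)


class TestGenerateGenome:
    def test_telomere_ledger_counts(self, demo):
        plan, ledger = demo["plan"], demo["ledger"]
        assert len(ledger.telomeres) == 2 * plan.n_chromosomes
        for t in ledger.telomeres:
            assert t["copies"] == plan.telomere_copies

    def test_ledger_in_bounds_and_complete(self, demo):
        ledger = demo["ledger"]
        ledger.check_bounds()
        assert len(ledger.centromeres) == demo["plan"].n_chromosomes
        assert len(ledger.sds) == len(demo["plan"].sd_specs)
        gene_ids = {g.gene_id for g in demo["genes"]}
        for p in ledger.gene_pairs:
            assert p["gene_a"] in gene_ids and p["gene_b"] in gene_ids

    def test_zero_divergence_centromere_is_exact_tandem(self):
        plan = T.GenomePlan(n_chromosomes=1, chrom_length=300_000,
                            cen_monomer_divergence=0.0, sd_specs=[],
                            n_gene_pairs=0, n_collinear_blocks=0, seed=4)
        genome, ledger, _, _ = T.generate_genome(plan)
        cen = ledger.centromeres[0]
        start, p = cen["start"], plan.cen_monomer_length
        # the array begins with a run of exact monomer copies
        run = genome["chr01"][start: start + 20 * p]
        assert run == ledger.monomer * 20

    def test_planted_sd_identity_recovered_by_global_alignment(self):
        plan = T.GenomePlan(n_chromosomes=2, chrom_length=200_000,
                            cen_array_span=30_000,
                            sd_specs=[(2000, 0.95, "intra")],
                            n_gene_pairs=0, n_collinear_blocks=0, seed=9)
        genome, ledger, _, _ = T.generate_genome(plan)
        sd = ledger.sds[0]
        seg_a = genome[sd["chrom_a"]][sd["start_a"]: sd["end_a"]]
        seg_b = genome[sd["chrom_b"]][sd["start_b"]: sd["end_b"]]
        # independent Needleman-Wunsch oracle (Biopython, unit scores)
        from Bio import Align
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score, al.mismatch_score = 1, -1
        al.open_gap_score = al.extend_gap_score = -1
        aln = al.align(seg_a, seg_b)[0]
        matches = sum(
            sum(1 for x, y in zip(seg_a[sa:ea], seg_b[sb:eb]) if x == y)
            for (sa, ea), (sb, eb) in zip(*aln.aligned))
        ident = matches / max(len(seg_a), len(seg_b))
        assert 0.93 <= ident <= 0.97
        assert abs(ident - sd["identity_realized"]) < 0.02
        assert abs(global_identity(seg_a, seg_b) - ident) < 0.02

    def test_determinism_byte_identical(self, tmp_path):
        plan = T.GenomePlan(n_chromosomes=2, chrom_length=200_000,
                            cen_array_span=30_000, seed=17)
        p1 = T.write_bundle(plan, tmp_path / "a")
        p2 = T.write_bundle(plan, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_infeasible_packing_rejected(self):
        plan = T.GenomePlan(n_chromosomes=1, chrom_length=110_000,
                            cen_array_span=50_000, telomere_copies=100,
                            sd_specs=[(20_000, 0.95, "intra")] * 4,
                            n_gene_pairs=0, n_collinear_blocks=0, seed=0)
        with pytest.raises(PackingError):
            T.generate_genome(plan)

    def test_plan_invariants_enforced(self):
        with pytest.raises(ValueError):
            T.GenomePlan(chrom_length=1000).validate()
        with pytest.raises(ValueError):
            T.GenomePlan(sd_specs=[(1000, 1.5, "intra")]).validate()
        with pytest.raises(ValueError):
            T.GenomePlan(ks_targets=[-0.1]).validate()


class TestMutateCds:
    def test_zero_targets_identity(self):
        cds = random_cds(50, np.random.default_rng(1))
        assert mutate_cds_to_target_ks(cds, 0.0, 0.0, seed=1) == cds

    def test_no_stop_codons_introduced(self):
        for seed in range(10):
            cds = random_cds(200, np.random.default_rng(seed))
            mut = mutate_cds_to_target_ks(cds, 0.3, 0.1, seed=seed)
            codons = [mut[i: i + 3] for i in range(0, len(mut) - 3, 3)]
            from t2tdup.kaks import STOP_CODONS
            assert not any(c in STOP_CODONS for c in codons)

    def test_recovery_by_ng_estimator(self):
        ests = []
        for seed in range(10):
            cds = random_cds(1000, np.random.default_rng(seed))
            mut = mutate_cds_to_target_ks(cds, 0.2, 0.0, seed=seed + 99)
            r = kaks_pair(cds, mut)
            ests.append(r.ks)
            assert r.ka == pytest.approx(0.0, abs=1e-9)
        assert abs(np.mean(ests) - 0.2) <= 0.02

    def test_single_codon_high_target_errors(self):
        with pytest.raises(SaturationError):
            mutate_cds_to_target_ks("TTT", 0.5, 0.0, seed=0)

    def test_frame_and_stop_validation(self):
        with pytest.raises(ValueError):
            mutate_cds_to_target_ks("ATGA", 0.1)
        with pytest.raises(ValueError):
            mutate_cds_to_target_ks("ATGTAAGGGAAA", 0.1)


class TestSimulateExpression:
    def test_tpm_columns_sum_to_million(self, demo_expression):
        tpm = demo_expression["tpm"]
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_nodiff_zero_dispersion_fold_change_vanishes(self):
        import pandas as pd
        pairs = pd.DataFrame([{"pair_id": "P1", "gene_a": "a",
                               "gene_b": "b", "category": "NoDiff"}])
        design = T.ExpressionDesign(n_samples=6, dispersion=0.0,
                                    indep_log_sd=0.0, base_mean=5000)
        counts, tpm, _ = T.simulate_expression(pairs, design, seed=0)
        from t2tdup.expression import sample_means
        m = sample_means(tpm)
        lfc = np.log2(m.loc["a"] / m.loc["b"])
        assert np.abs(lfc).max() < 0.1

    def test_aed_dominance_structure(self, demo_expression):
        """Planted AED pairs: the dominant gene's replicate-mean is >= 2x its
        partner in at least ceil(M/3) samples and never the reverse."""
        import math
        from t2tdup.expression import sample_means
        truth = demo_expression["truth"]
        pairs = demo_expression["pairs"]
        m = sample_means(demo_expression["tpm"])
        M = m.shape[1]
        merged = pairs.merge(truth, on="pair_id", suffixes=("", "_t"))
        for row in merged[merged["category"] == "AED"].itertuples():
            dom = row.dominant_gene
            other = row.gene_b if dom == row.gene_a else row.gene_a
            ratio = m.loc[dom] / m.loc[other]
            assert (ratio >= 2).sum() >= math.ceil(M / 3)

    def test_too_few_samples_rejected(self):
        import pandas as pd
        pairs = pd.DataFrame([{"pair_id": "P1", "gene_a": "a",
                               "gene_b": "b", "category": "AED"}])
        with pytest.raises(ValueError):
            T.simulate_expression(pairs, T.ExpressionDesign(n_samples=2),
                                  seed=0)


class TestSimulateMethylation:

    def test_extreme_means(self, tiny):
        genome, _, genes, _ = tiny
        regions = {"chr01": [(10_000, 20_000)]}
        cx = T.simulate_methylation(
            genome, genes, {"CG": 1.0, "CHG": 0.5, "CHH": 0.0},
            depth=10, seed=0, regions=regions)
        cg = cx[cx["context"] == "CG"]
        chh = cx[cx["context"] == "CHH"]
        assert (cg["count_methylated"] == 10).all()
        assert (chh["count_methylated"] == 0).all()

    def test_binomial_concentration(self, tiny):
        genome, _, genes, _ = tiny
        regions = {"chr01": [(10_000, 40_000)]}
        cx = T.simulate_methylation(genome, genes, {"CG": 0.6, "CHG": 0.3,
                                                    "CHH": 0.1},
                                    depth=50, seed=1, regions=regions)
        cg = cx[cx["context"] == "CG"]
        assert len(cg) >= 1000
        level = cg["count_methylated"].sum() / (
            cg["count_methylated"].sum() + cg["count_unmethylated"].sum())
        assert 0.58 <= level <= 0.62

    def test_context_matches_reference(self, tiny):
        from t2tdup.methylation import call_context
        genome, _, genes, _ = tiny
        seq = genome["chr01"]
        cx = T.simulate_methylation(genome, genes, {"CG": 0.5, "CHG": 0.5,
                                                    "CHH": 0.5},
                                    depth=5, seed=2,
                                    regions={"chr01": [(30_000, 31_000)]})
        for row in cx.sample(50, random_state=0).itertuples():
            assert call_context(seq, row.position - 1, row.strand) \
                == row.context

    def test_depth_validated(self, tiny):
        genome, _, genes, _ = tiny
        with pytest.raises(ValueError):
            T.simulate_methylation(genome, genes, {"CG": 0.5}, depth=0)
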