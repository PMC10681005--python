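"""End-to-end orchestration: run every stage on one input bundle.

Stages run in dependency order — telomeres, centromeres, collinearity,
segmental duplications, Ka/Ks, expression divergence, methylation — each
logging its parameters into the results bundle, which is written as one
JSON document plus per-stage TSV/BED files. A fixed config and seed
reproduce byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import (centromeres as cen, collinearity as col, expression as expr,
               kaks as kk, methylation as meth, sd as sdmod,
               telomeres as tel)
from . import seqio
from .models import to_dict

log = logging.getLogger(__name__)


def ratio_summary(numerator: float, denominator: float, decimals: int = 2,
                  mode: str = "fold") -> float:
    """Printed-ratio arithmetic: numerator/denominator rounded
    half-away-from-zero at ``decimals``; percent mode multiplies by 100.
    Returns NaN for a zero denominator."""
    if denominator == 0:
        return math.nan
    value = numerator / denominator
    if mode == "percent":
        value *= 100.0
    elif mode != "fold":
        raise ValueError(f"mode must be fold|percent, got {mode!r}")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def satellite_mask(arrays, telomere_calls, pad: int = 2000) -> dict:
    """Mask intervals for SD seeding from detected tandem arrays and
    telomeres, padded to absorb sub-threshold partial repeat runs at array
    edges (as a soft-masked assembly would)."""
    from .models import merge_intervals

    mask: dict = {}
    for a in arrays:
        mask.setdefault(a.chrom, []).append((max(0, a.start - pad),
                                             a.end + pad))
    for t in telomere_calls:
        mask.setdefault(t.chrom, []).append((max(0, t.start - pad),
                                             t.stop + pad))
    return {c: merge_intervals(v) for c, v in mask.items()}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seed for one full run."""

    genome: str
    genes: str
    te: str = ""
    counts: str = ""
    cx_report: str = ""
    alignments: str = ""           # optional PAF; empty = internal self-align
    outdir: str = "t2tdup_out"
    seed: int = 0
    # module thresholds (documented defaults)
    telomere_window: int = 150_000
    telomere_min_copies: int = 10
    telomere_min_purity: float = 0.8
    monomer_min_period: int = 50
    monomer_max_period: int = 500
    monomer_min_copies: int = 10
    monomer_min_identity: float = 0.8
    cluster_identity: float = 0.8
    hit_identity: float = 0.7
    min_monomer_density: float = 0.3
    tpm_expressed_threshold: float = 1.0
    sd_min_len: int = 1000
    sd_min_identity: float = 0.90
    wgd_overlap: float = 0.8
    min_protein_identity: float = 0.5
    min_block_pairs: int = 5
    max_gap_genes: int = 25
    wgd_ks_window: tuple = col.WGD_KS_WINDOW
    fdr: float = 0.05
    lfc: float = 1.0
    n_random_pairs: int = 10_000
    min_coverage: int = 1

    def validate(self) -> None:
        for name in ("telomere_min_purity", "monomer_min_identity",
                     "cluster_identity", "hit_identity",
                     "min_monomer_density", "sd_min_identity",
                     "wgd_overlap", "min_protein_identity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError(f"fdr={self.fdr} outside (0, 1)")
        for name in ("telomere_window", "sd_min_len", "min_block_pairs",
                     "max_gap_genes", "n_random_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.wgd_ks_window
        if not (0 <= lo <= hi):
            raise ValueError("bad wgd_ks_window")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wgd_ks_window"] = list(self.wgd_ks_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "wgd_ks_window" in d:
            d["wgd_ks_window"] = tuple(d["wgd_ks_window"])
        return cls(**d)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the results bundle. Returns the bundle."""
    config.validate()
    for name in ("genome", "genes"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(
                f"required input {name!r} missing: {p or '(unset)'}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s", name)
                bundle["stages"][name] = fn()
            except Exception as e:  # halt with the failing stage named
                raise StageError(name, e) from e
        return deco

    genome = seqio.read_fasta(config.genome)
    genes = seqio.read_gff3(config.genes)
    tes = seqio.read_te_bed(config.te) if config.te else []
    counts = seqio.read_counts(config.counts) if config.counts else None
    cx = seqio.read_cx_report(config.cx_report) if config.cx_report else None

    state: dict = {}

    @stage("telomeres")
    def _():
        calls = tel.scan_telomeres(
            genome, window=config.telomere_window,
            min_copies=config.telomere_min_copies,
            min_purity=config.telomere_min_purity)
        census = tel.telomere_census(calls, sorted(genome))
        seqio.write_bed(tel.calls_to_bed(calls), outdir / "telomeres.bed")
        state["telomere_calls"] = calls
        return {"params": {"window": config.telomere_window,
                           "min_copies": config.telomere_min_copies,
                           "min_purity": config.telomere_min_purity},
                "total": len(calls),
                "t2t_chromosomes": int((census["status"] == "T2T").sum())}

    @stage("centromeres")
    def _():
        arrays = cen.genome_tandem_arrays(
            genome, min_period=config.monomer_min_period,
            max_period=config.monomer_max_period,
            min_copies=config.monomer_min_copies,
            min_identity=config.monomer_min_identity)
        state["arrays"] = arrays
        monomers = [m for a in arrays for m in a.monomers]
        if not monomers:
            state["cen_calls"] = []
            return {"n_arrays": 0, "calls": []}
        clusters = cen.cluster_monomers(monomers, config.cluster_identity)
        consensus = clusters[0].consensus
        track = cen.scan_consensus(genome, consensus,
                                   hit_identity=config.hit_identity)
        calls = cen.call_centromeres(
            track, genes, tes,
            min_monomer_density=config.min_monomer_density,
            chrom_lengths={c: len(genome[c]) for c in genome})
        state["cen_calls"] = calls
        with open(outdir / "centromere_consensus.fa", "w") as fh:
            fh.write(f">consensus_monomer\n{consensus}\n")
        seqio.write_bed([(c.chrom, c.start, c.end,
                          f"CEN:{c.monomer_density:.3f}") for c in calls],
                        outdir / "centromeres.bed")
        result = {"params": {"cluster_identity": config.cluster_identity,
                             "hit_identity": config.hit_identity,
                             "min_monomer_density":
                                 config.min_monomer_density},
                  "n_arrays": len(arrays),
                  "monomer_length": len(consensus),
                  "monomer_copies": clusters[0].genome_copies,
                  "calls": [to_dict(c) for c in calls]}
        if counts is not None:
            lengths = pd.Series({g.gene_id: float(g.length) for g in genes})
            tpm = expr.tpm(counts, lengths)
            state["tpm"] = tpm
            n, n_expr, pct = cen.centromeric_gene_expression(
                calls, genes, tpm, config.tpm_expressed_threshold)
            result["centromeric_genes"] = {
                "n_genes": n, "n_expressed": n_expr, "expressed_pct": pct}
        return result

    @stage("collinearity")
    def _():
        anchors = col.homolog_pairs(
            genes, genome, min_protein_identity=config.min_protein_identity)
        blocks = col.chain_blocks(anchors, genes,
                                  min_block_pairs=config.min_block_pairs,
                                  max_gap_genes=config.max_gap_genes)
        state["anchors"] = anchors
        state["blocks"] = blocks
        pd.DataFrame(anchors, columns=["gene_a", "gene_b", "identity"]) \
            .to_csv(outdir / "anchors.tsv", sep="\t", index=False)
        return {"params": {"min_protein_identity":
                           config.min_protein_identity,
                           "min_block_pairs": config.min_block_pairs,
                           "max_gap_genes": config.max_gap_genes},
                "n_anchors": len(anchors), "n_blocks": len(blocks),
                "block_sizes": [len(b.pairs) for b in blocks]}

    @stage("sd")
    def _():
        if config.alignments:
            cands = seqio.read_paf(config.alignments)
        else:
            # soft-mask detected satellite/telomere arrays before self-align
            mask = satellite_mask(state.get("arrays", []),
                                  state.get("telomere_calls", []))
            cands = sdmod.self_align(genome, mask=mask)
        regions = sdmod.block_regions(state["blocks"], genes)
        sds = sdmod.filter_sds(cands, regions, min_len=config.sd_min_len,
                               min_identity=config.sd_min_identity,
                               wgd_overlap=config.wgd_overlap)
        pairs = sdmod.assign_sd_gene_pairs(sds, genes)
        summary = sdmod.summarize_sds(sds, genome)
        state["sds"] = sds
        state["sd_pairs"] = pairs
        sdmod.sds_to_frame(sds).to_csv(outdir / "sds.tsv", sep="\t",
                                       index=False)
        return {"params": {"min_len": config.sd_min_len,
                           "min_identity": config.sd_min_identity,
                           "wgd_overlap": config.wgd_overlap},
                "n_candidates": len(cands), "summary": summary,
                "n_gene_pairs": len(pairs)}

    @stage("kaks")
    def _():
        gidx = {g.gene_id: g for g in genes}
        wanted = {frozenset((p.gene_a, p.gene_b))
                  for p in state["sd_pairs"]}
        for b in state["blocks"]:
            wanted |= {frozenset(p) for p in b.pairs}
        table = {}
        rows = []
        for key in sorted(wanted, key=sorted):
            a, b = sorted(key)
            try:
                res = kk.kaks_pair(gidx[a].cds_sequence(genome),
                                   gidx[b].cds_sequence(genome))
            except ValueError:
                continue
            table[key] = res
            rows.append({"gene_a": a, "gene_b": b,
                         "ka": round(res.ka, 4), "ks": round(res.ks, 4),
                         "ratio": round(res.ratio, 4)
                         if math.isfinite(res.ratio) else res.ratio,
                         "status": res.status})
        state["ks_table"] = table
        wgd_pairs = col.extract_wgd_pairs(state["blocks"], table,
                                          window=config.wgd_ks_window)
        state["wgd_pairs"] = wgd_pairs
        pd.DataFrame(rows).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
        sd_ks = [table[frozenset((p.gene_a, p.gene_b))].ks
                 for p in state["sd_pairs"]
                 if frozenset((p.gene_a, p.gene_b)) in table]
        intra = [table[frozenset((p.gene_a, p.gene_b))].ks
                 for p in state["sd_pairs"]
                 if p.sd.kind == "intra"
                 and frozenset((p.gene_a, p.gene_b)) in table]
        inter = [table[frozenset((p.gene_a, p.gene_b))].ks
                 for p in state["sd_pairs"]
                 if p.sd.kind == "inter"
                 and frozenset((p.gene_a, p.gene_b)) in table]
        mi, mt, p, u = sdmod.compare_sd_ks(intra, inter)
        return {"n_pairs_estimated": len(table),
                "n_wgd_pairs": len(wgd_pairs),
                "sd_ks_below_0.15_pct": ratio_summary(
                    sum(1 for k in sd_ks if np.isfinite(k) and k < 0.15),
                    len(sd_ks), mode="percent") if sd_ks else None,
                "intra_vs_inter": {"mean_intra": None if math.isnan(mi)
                                   else round(mi, 4),
                                   "mean_inter": None if math.isnan(mt)
                                   else round(mt, 4),
                                   "wilcoxon_p": None if math.isnan(p)
                                   else p}}

    @stage("divergence")
    def _():
        if counts is None:
            return {"skipped": "no counts input"}
        tpm = state["tpm"]
        rows = []
        for p in state["sd_pairs"]:
            rows.append({"pair_id": f"sd:{p.gene_a}:{p.gene_b}",
                         "gene_a": p.gene_a, "gene_b": p.gene_b,
                         "origin": "SD"})
        for w in state["wgd_pairs"]:
            rows.append({"pair_id": f"wgd:{w.gene_a}:{w.gene_b}",
                         "gene_a": w.gene_a, "gene_b": w.gene_b,
                         "origin": "WGD"})
        pairs_df = pd.DataFrame(rows).drop_duplicates("pair_id")
        pairs_df = pairs_df[pairs_df["gene_a"].isin(tpm.index)
                            & pairs_df["gene_b"].isin(tpm.index)]
        if not len(pairs_df):
            return {"skipped": "no duplicate pairs with expression"}
        cats, statuses = expr.classify_pairs(pairs_df, tpm, fdr=config.fdr,
                                             lfc=config.lfc)
        state["categories"] = {
            row["gene_a"]: c.category
            for (_, row), c in zip(pairs_df.iterrows(), cats)}
        state["categories"].update({
            row["gene_b"]: c.category
            for (_, row), c in zip(pairs_df.iterrows(), cats)})
        counts_by_origin = {}
        for (_, row), c in zip(pairs_df.iterrows(), cats):
            d = counts_by_origin.setdefault(
                row["origin"], {"AED": 0, "Sub": 0, "NoDiff": 0})
            d[c.category] += 1
        rnd = col.random_pairs(list(tpm.index), n=config.n_random_pairs,
                               seed=config.seed)
        groups = {"SD": [(p.gene_a, p.gene_b) for p in state["sd_pairs"]],
                  "WGD": [(w.gene_a, w.gene_b)
                          for w in state["wgd_pairs"]],
                  "random": rnd}
        corr, excluded = expr.pair_correlations(groups, tpm)
        corr.to_csv(outdir / "pair_correlations.tsv", sep="\t", index=False)
        pd.DataFrame([{"pair_id": c.pair_id, "category": c.category,
                       "dominant_gene": c.dominant_gene} for c in cats]) \
            .to_csv(outdir / "divergence_categories.tsv", sep="\t",
                    index=False)
        mean_r = {g: round(float(sub["r"].mean()), 4)
                  for g, sub in corr.groupby("group")}
        return {"params": {"fdr": config.fdr, "lfc": config.lfc},
                "categories": expr.category_counts(cats),
                "by_origin": counts_by_origin,
                "mean_r": mean_r, "excluded_pairs": excluded}

    @stage("methylation")
    def _():
        if cx is None:
            return {"skipped": "no cytosine report input"}
        levels = meth.gene_levels(cx, genes, config.min_coverage)
        lf = meth.levels_frame(levels)
        lf.to_csv(outdir / "gene_methylation.tsv", sep="\t", index=False)
        result = {"params": {"min_coverage": config.min_coverage},
                  "n_genes": len({g.gene_id for g in levels}),
                  "mean_level": {
                      ctx: round(float(sub["level"].mean()), 4)
                      for ctx, sub in lf.dropna(subset=["level"])
                      .groupby("context")}}
        if "categories" in state:
            summary, track = meth.category_profiles(
                cx, genes, state["categories"], config.min_coverage)
            track.to_csv(outdir / "metagene_track.tsv", sep="\t",
                         index=False)
            result["by_category"] = {
                f"{r.category}/{r.context}": round(r.mean, 4)
                for r in summary.itertuples()}
        return result

    seqio.write_json(bundle, outdir / "results.json")
    return bundle
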