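"""Synthetic genomes with planted, ledgered ground truth.

The generator emulates the statistical structure the downstream analyses
assume: chromosomes carrying terminal telomere arrays, one centromeric
satellite array per chromosome (a shared ~198-bp monomer, mutated per copy,
interspersed with labeled Gypsy/Copia retrotransposon chunks), planted
segmental duplications with controlled length and identity, duplicated gene
pairs with controlled codon divergence, replicated negative-binomial
expression with planted divergence categories, and per-cytosine methylation
counts with context-specific means. Every planted feature is recorded in a
TruthLedger keyed for recovery tests.

Background sequence is i.i.d. uniform A/C/G/T. All randomness flows from a
single integer seed through ``numpy.random.SeedSequence.spawn``; a fixed
plan and seed reproduce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import kaks as K
from .align import global_identity
from .models import GeneModel, GenomeSet, TEAnnotation, revcomp
from . import seqio

TELOMERE_MOTIF = "TTTAGGG"          # plus-strand 3' end; 5' end carries CCCTAAA

_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _IDX[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return _BASE[arr].tobytes().decode()


class PackingError(ValueError):
    """Planted features cannot be placed without overlap."""


class SaturationError(ValueError):
    """A divergence target cannot be realized on the given sequence."""


@dataclass
class ExpressionDesign:
    """Replicated multi-sample expression design for duplicate pairs."""

    n_samples: int = 11
    n_replicates: int = 3
    base_mean: float = 300.0
    dispersion: float = 0.02        # NB: var = m + dispersion * m^2
    fold: float = 6.0               # planted expression ratio in affected samples
    shared_log_sd: float = 0.7      # per-sample profile shared within a pair
    indep_log_sd: float = 0.12      # per-gene-per-sample residual

    @property
    def samples(self):
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class GenomePlan:
    n_chromosomes: int = 17
    chrom_length: int = 300_000
    telomere_copies: int = 100
    cen_monomer_length: int = 198
    cen_array_span: int = 100_000
    cen_monomer_divergence: float = 0.05
    cen_te_fraction: float = 0.28       # fraction of the centromere span in TE chunks
    cen_gypsy_fraction: float = 0.8     # Gypsy share of centromeric TE bp
    sd_specs: list = field(default_factory=lambda: [
        (5000, 0.95, "intra"), (5000, 0.95, "inter"),
        (3000, 0.93, "inter"), (8000, 0.97, "intra"),
        (4000, 0.94, "inter"), (6000, 0.96, "inter"),
    ])
    n_gene_pairs: int = 12              # dispersed duplicate pairs
    ks_targets: list = field(default_factory=lambda: [
        0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
    n_collinear_blocks: int = 2
    genes_per_block: int = 8
    wgd_ks_target: float = 0.20
    gene_codons: int = 300
    n_background_genes_per_chrom: int = 3
    n_cen_genes_per_chrom: int = 1
    n_te_per_chrom: int = 8
    te_length: int = 1500
    expression_design: ExpressionDesign = field(default_factory=ExpressionDesign)
    methylation_means: dict = field(default_factory=lambda: {
        "CG": 0.6, "CHG": 0.3, "CHH": 0.1})
    seed: int = 0

    def validate(self) -> None:
        tel_span = 7 * self.telomere_copies
        if self.chrom_length <= 2 * tel_span + self.cen_array_span:
            raise ValueError("chrom_length must exceed telomeres + centromere span")
        for L, ident, kind in self.sd_specs:
            if not (0.0 <= ident <= 1.0):
                raise ValueError(f"SD identity {ident} outside [0,1]")
            if kind not in ("intra", "inter"):
                raise ValueError(f"SD kind {kind!r} must be intra|inter")
            if kind == "inter" and self.n_chromosomes < 2:
                raise ValueError("inter-chromosomal SD needs >= 2 chromosomes")
        if any(k < 0 for k in self.ks_targets):
            raise ValueError("Ks targets must be >= 0")
        if not (0.0 <= self.cen_monomer_divergence <= 1.0):
            raise ValueError("monomer divergence outside [0,1]")
        if self.expression_design.n_samples < 3:
            raise ValueError(
                "an AED/Sub distinction needs at least 3 samples")

    def chrom_names(self):
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclass
class TruthLedger:
    """Record of every planted feature, keyed for recovery tests."""

    telomeres: list = field(default_factory=list)
    centromeres: list = field(default_factory=list)
    monomer: str = ""
    sds: list = field(default_factory=list)
    gene_pairs: list = field(default_factory=list)
    gene_methylation: dict = field(default_factory=dict)
    chrom_lengths: dict = field(default_factory=dict)

    def pair_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.gene_pairs)

    def to_json(self, path) -> None:
        seqio.write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        d = seqio.read_json(path)
        return cls(**d)

    def check_bounds(self) -> None:
        for t in self.telomeres:
            assert 0 <= t["start"] < t["stop"] <= self.chrom_lengths[t["chrom"]]
        for c in self.centromeres:
            assert 0 <= c["start"] < c["end"] <= self.chrom_lengths[c["chrom"]]
        for s in self.sds:
            for side in ("a", "b"):
                L = self.chrom_lengths[s[f"chrom_{side}"]]
                assert 0 <= s[f"start_{side}"] < s[f"end_{side}"] <= L


# ------------------------------------------------------------------ CDS


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal sense codons + TAA."""
    internal = [c for c in K.SENSE_CODONS if c != "ATG"]
    body = rng.choice(internal, size=max(n_codons - 2, 0))
    return "ATG" + "".join(body) + "TAA"


def _inv_jc(rate: float) -> float:
    """Expected per-site difference proportion for a Jukes-Cantor rate."""
    return 0.75 * (1.0 - math.exp(-4.0 * rate / 3.0))


def _syn_options(codon: str):
    aa = K.translate_codon(codon)
    opts = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if not K.is_stop(mut) and K.translate_codon(mut) == aa:
                opts.append(mut)
    return opts


def _nonsyn_options(codon: str):
    aa = K.translate_codon(codon)
    opts = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if not K.is_stop(mut) and K.translate_codon(mut) != aa:
                opts.append(mut)
    return opts


def mutate_cds_to_target_ks(cds: str, target_ks: float, target_ka: float = 0.0,
                            seed=None) -> str:
    """Plant substitutions so NG estimates recover the target Ka and Ks.

    The Jukes-Cantor inverse of each target gives the difference proportion
    to realize; that many single-base synonymous (resp. nonsynonymous)
    substitutions are placed at distinct randomly chosen codons, so the NG
    pathway count of every mutated codon is exactly one difference of the
    intended class and no stop codon is ever introduced.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i: i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if K.is_stop(c):
            raise ValueError(f"internal stop codon at codon {i}")
    has_stop = bool(codons) and K.is_stop(codons[-1])
    body = codons[:-1] if has_stop else list(codons)
    if target_ks < 0 or target_ka < 0:
        raise ValueError("targets must be >= 0")

    s_sites = sum(K.ng_count_sites(c)[0] for c in body)
    n_sites = 3.0 * len(body) - s_sites
    ps, pn = _inv_jc(target_ks), _inv_jc(target_ka)
    if ps >= K.SATURATION or pn >= K.SATURATION:
        raise SaturationError("target beyond Jukes-Cantor saturation")
    n_syn = int(round(ps * s_sites))
    n_non = int(round(pn * n_sites))
    if target_ks > 0 and n_syn == 0:
        raise SaturationError(
            f"sequence too short to realize Ks={target_ks} "
            f"({s_sites:.2f} synonymous sites)")
    if target_ka > 0 and n_non == 0:
        raise SaturationError(
            f"sequence too short to realize Ka={target_ka} "
            f"({n_sites:.2f} nonsynonymous sites)")
    if n_syn == 0 and n_non == 0:
        return cds

    rng = np.random.default_rng(seed)
    syn_idx = [i for i, c in enumerate(body) if _syn_options(c)]
    non_idx = [i for i, c in enumerate(body) if _nonsyn_options(c)]
    if len(syn_idx) < n_syn:
        raise SaturationError("not enough synonymously mutable codons")
    chosen_syn = rng.choice(syn_idx, size=n_syn, replace=False)
    out = list(body)
    for i in chosen_syn:
        opts = _syn_options(out[i])
        out[i] = opts[rng.integers(len(opts))]
    remaining = [i for i in non_idx if i not in set(chosen_syn.tolist())]
    if len(remaining) < n_non:
        raise SaturationError("not enough nonsynonymously mutable codons")
    for i in rng.choice(remaining, size=n_non, replace=False):
        opts = _nonsyn_options(out[i])
        out[i] = opts[rng.integers(len(opts))]
    if has_stop:
        out.append(codons[-1])
    return "".join(out)


# ------------------------------------------------------------------ packing


class _Packer:
    """Tracks occupied intervals per chromosome; rejection-samples free slots."""

    PAD = 200
    MAX_ATTEMPTS = 1000

    def __init__(self, chrom_lengths: dict, rng: np.random.Generator):
        self.lengths = chrom_lengths
        self.occupied = {c: [] for c in chrom_lengths}
        self.rng = rng

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start - self.PAD, end + self.PAD))

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return not any(s < end and start < e for s, e in self.occupied[chrom])

    def place(self, chrom: str, length: int) -> int:
        L = self.lengths[chrom]
        for _ in range(self.MAX_ATTEMPTS):
            start = int(self.rng.integers(0, max(L - length, 1)))
            if self._free(chrom, start, start + length):
                self.reserve(chrom, start, start + length)
                return start
        raise PackingError(
            f"could not place a {length}-bp feature on {chrom} after "
            f"{self.MAX_ATTEMPTS} attempts")


def _mutate_dna(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions at the given per-base rate (never to the same base)."""
    out = arr.copy()
    hit = rng.random(out.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


# ------------------------------------------------------------------ generator


def generate_genome(plan: GenomePlan):
    """Build the synthetic genome.

    Returns (genome, ledger, genes, tes): a GenomeSet, the TruthLedger, the
    gene models, and the TE annotation. Centromeres and telomeres are laid
    out first; genes and SDs are packed into remaining space by rejection
    sampling.
    """
    plan.validate()
    root = np.random.SeedSequence(plan.seed)
    (ss_bg, ss_mono, ss_cen, ss_gene, ss_sd, ss_te, ss_place) = root.spawn(7)
    rng_bg = np.random.default_rng(ss_bg)
    rng_mono = np.random.default_rng(ss_mono)
    rng_cen = np.random.default_rng(ss_cen)
    rng_gene = np.random.default_rng(ss_gene)
    rng_sd = np.random.default_rng(ss_sd)
    rng_te = np.random.default_rng(ss_te)

    chroms = plan.chrom_names()
    L = plan.chrom_length
    seqs = {c: rng_bg.integers(0, 4, size=L, dtype=np.uint8) for c in chroms}
    ledger = TruthLedger(chrom_lengths={c: L for c in chroms})
    genes: list[GeneModel] = []
    tes: list[TEAnnotation] = []
    packer = _Packer({c: L for c in chroms}, np.random.default_rng(ss_place))

    # satellite blocks get a wide berth: other features keep their distance
    # the way repeats and genes segregate in real assemblies
    SAT_PAD = 2500

    # --- telomeres
    tel_span = 7 * plan.telomere_copies
    tel5 = _encode("CCCTAAA" * plan.telomere_copies)
    tel3 = _encode(TELOMERE_MOTIF * plan.telomere_copies)
    for c in chroms:
        seqs[c][:tel_span] = tel5
        seqs[c][L - tel_span:] = tel3
        packer.reserve(c, 0, tel_span + SAT_PAD)
        packer.reserve(c, L - tel_span - SAT_PAD, L)
        ledger.telomeres.append(
            {"chrom": c, "end": "five_prime", "start": 0, "stop": tel_span,
             "copies": plan.telomere_copies})
        ledger.telomeres.append(
            {"chrom": c, "end": "three_prime", "start": L - tel_span, "stop": L,
             "copies": plan.telomere_copies})

    # --- centromeres: one shared monomer, mutated per copy, TE chunks between runs
    monomer = _decode(rng_mono.integers(0, 4, size=plan.cen_monomer_length,
                                        dtype=np.uint8))
    ledger.monomer = monomer
    mono_arr = _encode(monomer)
    gene_counter = [0]
    cen_gene_slots = []

    def _new_gene_id():
        gene_counter[0] += 1
        return f"g{gene_counter[0]:04d}"

    run_copies = 20
    te_chunk = plan.te_length
    for c in chroms:
        span = plan.cen_array_span
        cen_start = (L - span) // 2
        packer.reserve(c, cen_start - SAT_PAD, cen_start + span + SAT_PAD)
        pos = cen_start
        end = cen_start + span
        cen_te = []
        next_is_te = False
        genes_left = plan.n_cen_genes_per_chrom
        te_bp = gypsy_bp = 0
        n_other = 0
        while pos < end:
            if next_is_te and pos + te_chunk <= end:
                if genes_left and rng_cen.random() < 0.3:
                    cen_gene_slots.append((c, pos))
                    genes_left -= 1
                    pos += te_chunk
                else:
                    # track the target Gypsy share exactly rather than
                    # sampling: per-chromosome fractions stay on target
                    if gypsy_bp <= plan.cen_gypsy_fraction * (te_bp + te_chunk):
                        fam = "Gypsy"
                        gypsy_bp += te_chunk
                    else:
                        fam = "Copia" if n_other % 2 == 0 else "other"
                        n_other += 1
                    te_bp += te_chunk
                    cen_te.append(TEAnnotation(c, pos, pos + te_chunk, fam))
                    pos += te_chunk
                next_is_te = False
            else:
                n = min(run_copies, max((end - pos) // plan.cen_monomer_length, 0))
                if n == 0:
                    break
                for _ in range(n):
                    copy = _mutate_dna(mono_arr, plan.cen_monomer_divergence,
                                       rng_cen)
                    seqs[c][pos: pos + plan.cen_monomer_length] = copy
                    pos += plan.cen_monomer_length
                next_is_te = True
        tes.extend(cen_te)
        ledger.centromeres.append(
            {"chrom": c, "start": cen_start, "end": cen_start + span,
             "te_bp": sum(t.end - t.start for t in cen_te),
             "gypsy_bp": sum(t.end - t.start for t in cen_te
                             if t.family == "Gypsy")})

    # --- helper to plant a gene whose CDS overwrites background
    def _plant_gene(chrom, start, cds):
        gid = _new_gene_id()
        seqs[chrom][start: start + len(cds)] = _encode(cds)
        g = GeneModel(gid, chrom, start, start + len(cds), "+")
        genes.append(g)
        return g

    for c, pos in cen_gene_slots:
        cds = random_cds(min(plan.gene_codons, te_chunk // 3 - 2), rng_gene)
        _plant_gene(c, pos, cds)

    # --- segmental duplications (each hosts one duplicated gene when it fits)
    pair_counter = [0]

    def _new_pair_id():
        pair_counter[0] += 1
        return f"P{pair_counter[0]:03d}"

    for i, (sd_len, ident, kind) in enumerate(plan.sd_specs):
        src_chrom = chroms[i % len(chroms)]
        if kind == "intra":
            dst_chrom = src_chrom
        else:
            dst_chrom = chroms[(i + 1 + i // len(chroms)) % len(chroms)]
            if dst_chrom == src_chrom:
                dst_chrom = chroms[(i + 2) % len(chroms)]
        src = packer.place(src_chrom, sd_len)
        dst = packer.place(dst_chrom, sd_len)
        cds_len = 3 * plan.gene_codons
        host_gene = sd_len >= cds_len + 400
        gene_a = gene_b = None
        divergence = 1.0 - ident
        ks_t = -0.75 * math.log(1.0 - 4.0 * divergence / 3.0) if divergence else 0.0
        if host_gene:
            g_off = (sd_len - cds_len) // 2
            cds_a = random_cds(plan.gene_codons, rng_gene)
            gene_a = _plant_gene(src_chrom, src + g_off, cds_a)
        seg = seqs[src_chrom][src: src + sd_len]
        copy = _mutate_dna(seg, divergence, rng_sd)
        if host_gene:
            cds_b = mutate_cds_to_target_ks(
                cds_a, ks_t, ks_t, seed=rng_sd.integers(2 ** 31))
            copy[g_off: g_off + cds_len] = _encode(cds_b)
        seqs[dst_chrom][dst: dst + sd_len] = copy
        if host_gene:
            gid_b = _new_gene_id()
            gene_b = GeneModel(gid_b, dst_chrom, dst + g_off,
                               dst + g_off + cds_len, "+")
            genes.append(gene_b)
        realized = global_identity(_decode(seg), _decode(copy))
        ledger.sds.append(
            {"chrom_a": src_chrom, "start_a": src, "end_a": src + sd_len,
             "chrom_b": dst_chrom, "start_b": dst, "end_b": dst + sd_len,
             "kind": kind, "identity_target": ident,
             "identity_realized": realized})
        if host_gene:
            ledger.gene_pairs.append(
                {"pair_id": _new_pair_id(), "gene_a": gene_a.gene_id,
                 "gene_b": gene_b.gene_id, "origin": "SD",
                 "ks_target": ks_t, "ka_target": ks_t, "category": None})

    # --- collinear (WGD-like) duplicated gene runs across chromosome pairs
    cds_len = 3 * plan.gene_codons
    gene_pitch = cds_len + 600
    for b in range(plan.n_collinear_blocks):
        ca = chroms[(2 * b) % len(chroms)]
        cb = chroms[(2 * b + 1) % len(chroms)] if len(chroms) > 1 else ca
        span = plan.genes_per_block * gene_pitch
        sa = packer.place(ca, span)
        sb = packer.place(cb, span)
        for j in range(plan.genes_per_block):
            cds_a = random_cds(plan.gene_codons, rng_gene)
            cds_b = mutate_cds_to_target_ks(
                cds_a, plan.wgd_ks_target, plan.wgd_ks_target / 4.0,
                seed=rng_gene.integers(2 ** 31))
            ga = _plant_gene(ca, sa + j * gene_pitch, cds_a)
            gb = _plant_gene(cb, sb + j * gene_pitch, cds_b)
            ledger.gene_pairs.append(
                {"pair_id": _new_pair_id(), "gene_a": ga.gene_id,
                 "gene_b": gb.gene_id, "origin": "WGD",
                 "ks_target": plan.wgd_ks_target,
                 "ka_target": plan.wgd_ks_target / 4.0, "category": None})

    # --- dispersed duplicate pairs with per-pair Ks targets
    for j in range(plan.n_gene_pairs):
        ks_t = plan.ks_targets[j % len(plan.ks_targets)]
        ca = chroms[rng_gene.integers(len(chroms))]
        cb = chroms[rng_gene.integers(len(chroms))]
        cds_a = random_cds(plan.gene_codons, rng_gene)
        cds_b = mutate_cds_to_target_ks(
            cds_a, ks_t, ks_t / 4.0, seed=rng_gene.integers(2 ** 31))
        ga = _plant_gene(ca, packer.place(ca, cds_len), cds_a)
        gb = _plant_gene(cb, packer.place(cb, cds_len), cds_b)
        ledger.gene_pairs.append(
            {"pair_id": _new_pair_id(), "gene_a": ga.gene_id,
             "gene_b": gb.gene_id, "origin": "DISPERSED", "ks_target": ks_t,
             "ka_target": ks_t / 4.0, "category": None})

    # --- background singleton genes and scattered TEs
    for c in chroms:
        for _ in range(plan.n_background_genes_per_chrom):
            cds = random_cds(plan.gene_codons, rng_gene)
            _plant_gene(c, packer.place(c, len(cds)), cds)
        for _ in range(plan.n_te_per_chrom):
            u = rng_te.random()
            fam = "Gypsy" if u < 0.4 else ("Copia" if u < 0.8 else "other")
            start = packer.place(c, plan.te_length)
            tes.append(TEAnnotation(c, start, start + plan.te_length, fam))

    # assign planted expression categories round-robin over all pairs
    cats = ["AED", "Sub", "NoDiff"]
    for i, p in enumerate(ledger.gene_pairs):
        p["category"] = cats[i % 3]

    genome = GenomeSet({c: _decode(seqs[c]) for c in chroms})
    ledger.check_bounds()
    genes.sort(key=lambda g: (g.chrom, g.start))
    tes.sort(key=lambda t: (t.chrom, t.start))
    return genome, ledger, genes, tes


# ------------------------------------------------------------------ expression


def simulate_expression(pairs: pd.DataFrame, design: ExpressionDesign,
                        background_genes=(), gene_lengths=None, seed=0):
    """Negative-binomial counts for duplicate pairs with planted categories.

    ``pairs`` needs columns pair_id, gene_a, gene_b, category. Returns
    (counts, tpm, truth) where truth records each pair's dominant gene and
    affected samples. AED pairs have the dominant gene's mean raised
    ``fold``-fold in ceil(M/3)+1 samples and never lowered; Sub pairs have
    each gene raised in at least one sample; NoDiff pairs share means.
    """
    M = design.n_samples
    if M < 3:
        raise ValueError("an AED/Sub distinction needs at least 3 samples")
    if (pairs["category"].isna()).any():
        raise ValueError("every pair needs a planted category")
    rng = np.random.default_rng(seed)
    samples = design.samples
    gene_rows = {}
    truth = []
    k_aed = math.ceil(M / 3) + 1 if M > 3 else math.ceil(M / 3)

    def _nb(mean_vec):
        mean_vec = np.asarray(mean_vec, dtype=float)
        if design.dispersion <= 0:
            return rng.poisson(mean_vec)
        r = 1.0 / design.dispersion
        p = r / (r + mean_vec)
        return rng.negative_binomial(r, p)

    for _, row in pairs.iterrows():
        shared = design.base_mean * np.exp(
            rng.normal(0.0, design.shared_log_sd, size=M))
        mult_a = np.ones(M)
        mult_b = np.ones(M)
        cat = row["category"]
        dominant = None
        if cat == "AED":
            dominant = row["gene_a"] if rng.random() < 0.5 else row["gene_b"]
            idx = rng.choice(M, size=min(k_aed, M), replace=False)
            (mult_a if dominant == row["gene_a"] else mult_b)[idx] = design.fold
        elif cat == "Sub":
            n_a = math.ceil(M / 3)
            idx = rng.choice(M, size=n_a + 1, replace=False)
            mult_a[idx[:n_a]] = design.fold
            mult_b[idx[n_a:]] = design.fold
        elif cat != "NoDiff":
            raise ValueError(f"unknown category {cat!r}")
        noise_a = np.exp(rng.normal(0.0, design.indep_log_sd, size=M))
        noise_b = np.exp(rng.normal(0.0, design.indep_log_sd, size=M))
        mean_a = shared * mult_a * noise_a
        mean_b = shared * mult_b * noise_b
        rows_a, rows_b = [], []
        for s in range(M):
            rows_a.extend(_nb([mean_a[s]] * design.n_replicates))
            rows_b.extend(_nb([mean_b[s]] * design.n_replicates))
        gene_rows[row["gene_a"]] = rows_a
        gene_rows[row["gene_b"]] = rows_b
        truth.append({"pair_id": row["pair_id"], "category": cat,
                      "dominant_gene": dominant})

    for g in background_genes:
        if g in gene_rows:
            continue
        shared = design.base_mean * np.exp(
            rng.normal(0.0, design.shared_log_sd, size=M))
        rows = []
        for s in range(M):
            rows.extend(_nb([shared[s]] * design.n_replicates))
        gene_rows[g] = rows

    columns = [f"{s}.r{r + 1}" for s in samples for r in range(design.n_replicates)]
    counts = pd.DataFrame.from_dict(gene_rows, orient="index", columns=columns)
    counts.index.name = "gene_id"
    if gene_lengths is None:
        lengths = pd.Series(1000.0, index=counts.index)
    else:
        lengths = pd.Series({g: gene_lengths.get(g, 1000.0) for g in counts.index})
    from .expression import tpm as _tpm
    tpm = _tpm(counts, lengths)
    return counts, tpm, pd.DataFrame(truth)


# ------------------------------------------------------------------ methylation


def simulate_methylation(genome: GenomeSet, genes, methylation_means: dict,
                         depth: int = 20, seed: int = 0, gene_means: dict = None,
                         regions: dict = None) -> pd.DataFrame:
    """Bismark-style CX report with binomial methylated counts per cytosine.

    One row per cytosine on both strands, context called from the reference,
    counts ~ Binomial(depth, context mean). ``gene_means`` (gene_id ->
    {context: mean}) overrides the genome-wide means inside gene bodies.
    ``regions`` ({chrom: [(start, end), ...]}) restricts output to intervals.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    gene_index = {}
    if gene_means:
        for g in genes:
            if g.gene_id in gene_means:
                gene_index.setdefault(g.chrom, []).append(g)
    for chrom in sorted(genome):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        ivs = (regions or {}).get(chrom) if regions else [(0, len(seq))]
        if ivs is None:
            continue
        for (rs, re_) in ivs:
            sub = arr[rs:re_]
            for strand in "+-":
                if strand == "+":
                    is_c = sub == ord("C")
                    pos = np.nonzero(is_c)[0] + rs
                    pos = pos[pos + 2 < len(seq)]
                    n1 = arr[pos + 1]
                    n2 = arr[pos + 2]
                    tri = [seq[p: p + 3] for p in pos]
                else:
                    is_g = sub == ord("G")
                    pos = np.nonzero(is_g)[0] + rs
                    pos = pos[pos - 2 >= 0]
                    comp = {ord("A"): ord("T"), ord("T"): ord("A"),
                            ord("C"): ord("G"), ord("G"): ord("C")}
                    n1 = np.array([comp.get(b, b) for b in arr[pos - 1]],
                                  dtype=np.uint8)
                    n2 = np.array([comp.get(b, b) for b in arr[pos - 2]],
                                  dtype=np.uint8)
                    tri = [revcomp(seq[p - 2: p + 1]) for p in pos]
                context = np.where(
                    n1 == ord("G"), "CG",
                    np.where(n2 == ord("G"), "CHG", "CHH"))
                p = np.array([methylation_means[c] for c in context])
                for g in gene_index.get(chrom, []):
                    inside = (pos >= g.start) & (pos < g.end)
                    if inside.any():
                        over = gene_means[g.gene_id]
                        for ctx, mean in over.items():
                            p[inside & (context == ctx)] = mean
                meth = rng.binomial(depth, p)
                frames.append(pd.DataFrame({
                    "chrom": chrom, "position": pos + 1, "strand": strand,
                    "count_methylated": meth,
                    "count_unmethylated": depth - meth,
                    "context": context, "trinucleotide": tri,
                }))
    if not frames:
        return pd.DataFrame(columns=seqio.CX_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "position", "strand"],
                          kind="stable").reset_index(drop=True)


# ------------------------------------------------------------------ bundle


def write_bundle(plan: GenomePlan, outdir, depth: int = 20,
                 methylation_regions: str = "genes") -> dict:
    """Generate everything and write the standard file bundle.

    Returns a dict of paths. Methylation is restricted to gene bodies plus
    2-kb flanks by default (``methylation_regions="genome"`` covers all)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, ledger, genes, tes = generate_genome(plan)
    pairs = ledger.pair_table()
    counts, tpm, expr_truth = simulate_expression(
        pairs, plan.expression_design,
        background_genes=[g.gene_id for g in genes],
        gene_lengths={g.gene_id: g.length for g in genes},
        seed=plan.seed + 1)
    if methylation_regions == "genes":
        regions = {}
        for g in genes:
            regions.setdefault(g.chrom, []).append(
                (max(0, g.start - 2000),
                 min(len(genome[g.chrom]), g.end + 2000)))
        from .models import merge_intervals
        regions = {c: merge_intervals(v) for c, v in regions.items()}
    else:
        regions = None
    cx = simulate_methylation(genome, genes, plan.methylation_means,
                              depth=depth, seed=plan.seed + 2, regions=regions)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "tes": outdir / "te.bed",
        "counts": outdir / "counts.tsv",
        "tpm": outdir / "tpm.tsv",
        "cx": outdir / "methylation.cx.tsv",
        "ledger": outdir / "truth.json",
        "pairs": outdir / "pairs.tsv",
    }
    seqio.write_fasta(genome, paths["genome"])
    seqio.write_gff3(genes, paths["genes"])
    seqio.write_te_bed(tes, paths["tes"])
    seqio.write_counts(counts, paths["counts"])
    seqio.write_counts(tpm.round(4), paths["tpm"])
    seqio.write_cx_report(cx, paths["cx"])
    ledger.to_json(paths["ledger"])
    merged = pairs.merge(expr_truth[["pair_id", "dominant_gene"]], on="pair_id")
    merged.to_csv(paths["pairs"], sep="\t", index=False)
    return paths
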