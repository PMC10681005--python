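"""Segmental-duplication (SD) detection and summarization.

An SD is a duplicated segment >= 1 kb at >= 90% nucleotide identity that is
not part of a whole-genome-duplication collinear block. Candidates come
from a minimal seed-chain-extend genome self-alignment (31-mer matches off
the self-diagonal, chained by diagonal proximity, polished by global
alignment); external SEDEF/minimap2 alignments can be substituted via PAF
or BLAST tabular input. Identity is gap-compressed:
matches / (matches + mismatches + gap openings).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .align import global_align, parse_cigar
from .models import (GenomeSet, SDGenePair, SDRecord, merge_intervals,
                     reciprocal_overlap, revcomp)

MIN_SD_LEN = 1000
MIN_SD_IDENTITY = 0.90


# --------------------------------------------------------------- self-align


def _kmer_codes(seq: str, k: int):
    """Forward and reverse-complement 2-bit codes for every k-mer."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(arr.size, 255, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    valid = code != 255
    n = arr.size - k + 1
    if n <= 0:
        return None, None, None
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        c = code[i: n + i]
        fwd = (fwd << 2) | c
        rev = rev | ((3 - c) << (2 * i))
        ok &= valid[i: n + i]
    return fwd, rev, ok


def self_align(genome: GenomeSet, k: int = 31, min_chain_seeds: int = 5,
               max_kmer_occ: int = 20, band: int = 100,
               max_seed_gap: int = 2000, min_self_distance: int = 100,
               extend_margin: int = 300, mask: dict = None):
    """Candidate local duplications from a k-mer seed-chain-extend scan.

    k-mers occurring more than ``max_kmer_occ`` times (satellite and
    telomere arrays) are skipped; ``mask`` ({chrom: [(start, end), ...]}),
    typically the detected tandem-array intervals, excludes seeds the way a
    soft-masked assembly would. The trivial self-diagonal and near-diagonal
    same-chromosome matches closer than ``min_self_distance`` are excluded.
    Chains of >= ``min_chain_seeds`` seeds on one (anti)diagonal band become
    candidates, polished by global alignment into SDRecords carrying
    gap-compressed identity and an alignment coordinate map.
    """
    chroms = sorted(genome)
    if any(len(genome[c]) < k for c in chroms):
        raise ValueError(f"k={k} exceeds the shortest chromosome")
    all_codes = []
    for ci, c in enumerate(chroms):
        fwd, rev, ok = _kmer_codes(genome[c], k)
        if fwd is None:
            continue
        if mask and c in mask:
            for ms, me in mask[c]:
                ok[max(0, ms - k + 1): me] = False
        canon = np.minimum(fwd, rev)
        strand = fwd <= rev
        idx = np.nonzero(ok)[0]
        all_codes.append((canon[idx], np.full(idx.size, ci, dtype=np.int32),
                          idx.astype(np.int64), strand[idx]))
    canon = np.concatenate([x[0] for x in all_codes])
    chrom_i = np.concatenate([x[1] for x in all_codes])
    pos = np.concatenate([x[2] for x in all_codes])
    strand = np.concatenate([x[3] for x in all_codes])

    order = np.argsort(canon, kind="stable")
    canon_s = canon[order]
    bounds = np.concatenate(
        ([0], np.nonzero(np.diff(canon_s))[0] + 1, [canon_s.size]))
    sizes = np.diff(bounds)
    eligible = np.nonzero((sizes >= 2) & (sizes <= max_kmer_occ))[0]

    # bucket seed matches by (chrom_a, chrom_b, orientation)
    buckets: dict[tuple, list] = {}
    for gi in eligible:
        g = order[bounds[gi]: bounds[gi + 1]]
        occ = sorted(zip(chrom_i[g].tolist(), pos[g].tolist(),
                         strand[g].tolist()))
        for x in range(len(occ)):
            ca, pa, sa = occ[x]
            for y in range(x + 1, len(occ)):
                cb, pb, sb = occ[y]
                if ca == cb and abs(pb - pa) < min_self_distance:
                    continue
                orient = "+" if sa == sb else "-"
                key = (ca, cb, orient)
                diag = pb - pa if orient == "+" else pb + pa
                buckets.setdefault(key, []).append((diag, pa, pb))

    candidates = []
    for (ca, cb, orient), seeds in buckets.items():
        seeds.sort()
        cluster = [seeds[0]]
        clusters = []
        for s in seeds[1:]:
            if (s[0] - cluster[-1][0] <= band
                    and abs(s[1] - cluster[-1][1]) <= max_seed_gap):
                cluster.append(s)
            else:
                clusters.append(cluster)
                cluster = [s]
        clusters.append(cluster)
        for cl in clusters:
            if len(cl) < min_chain_seeds:
                continue
            pa = [s[1] for s in cl]
            pb = [s[2] for s in cl]
            a0, a1 = min(pa), max(pa) + k
            b0, b1 = min(pb), max(pb) + k
            a0 = max(0, a0 - extend_margin)
            a1 = min(len(genome[chroms[ca]]), a1 + extend_margin)
            b0 = max(0, b0 - extend_margin)
            b1 = min(len(genome[chroms[cb]]), b1 + extend_margin)
            candidates.append((ca, a0, a1, cb, b0, b1, orient))

    out = []
    seen = set()
    for ca, a0, a1, cb, b0, b1, orient in candidates:
        if ca == cb and reciprocal_overlap((a0, a1), (b0, b1)) > 0.5:
            continue  # palindromic / foldback self-hit
        seq_a = genome[chroms[ca]][a0:a1]
        seq_b = genome[chroms[cb]][b0:b1]
        if orient == "-":
            seq_b = revcomp(seq_b)
        _, cigar = global_align(seq_a, seq_b)
        trimmed = _trim_alignment(cigar)
        if trimmed is None:
            continue
        (alo, ahi, blo, bhi), (m, x, go), pairs = trimmed
        denom = m + x + go
        ident = m / denom if denom else 0.0
        ga0, ga1 = a0 + alo, a0 + ahi
        if orient == "+":
            gb0, gb1 = b0 + blo, b0 + bhi
            cmap = np.array([(a0 + pa, b0 + pb) for pa, pb in pairs],
                            dtype=np.int64).reshape(-1, 2)
        else:
            gb0, gb1 = b1 - bhi, b1 - blo
            cmap = np.array([(a0 + pa, b1 - 1 - pb) for pa, pb in pairs],
                            dtype=np.int64).reshape(-1, 2)
        rec = SDRecord(chrom_a=chroms[ca], start_a=ga0, end_a=ga1,
                       chrom_b=chroms[cb], start_b=gb0, end_b=gb1,
                       identity=ident, length=ga1 - ga0, strand=orient,
                       coord_map=cmap)
        key = rec.key()
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    out.sort(key=lambda r: (r.chrom_a, r.start_a, r.chrom_b, r.start_b))
    return out


_TRIM_MATCH, _TRIM_MISMATCH, _TRIM_GAP = 1.0, -2.0, -3.0


def _trim_alignment(cigar: str):
    """Best-scoring contiguous alignment window (Kadane over cigar runs).

    Flanking low-identity sequence pulled in by the extension margin scores
    negatively (+1 match, -2 mismatch, -3 per gap base) and is trimmed off;
    optimal boundaries always fall on run boundaries because runs are
    homogeneous. Returns ((a_lo, a_hi, b_lo, b_hi), (matches, mismatches,
    gap_openings), match_anchor_pairs) in alignment offsets, or None."""
    runs = parse_cigar(cigar)
    pa = pb = 0
    cur = None   # (score, a_start, b_start, run_index)
    best = None  # (score, a_lo, a_hi, b_lo, b_hi, run_lo, run_hi)
    positions = []
    for ri, (n, op) in enumerate(runs):
        positions.append((pa, pb))
        if op == "=":
            score = _TRIM_MATCH * n
        elif op == "X":
            score = _TRIM_MISMATCH * n
        else:
            score = _TRIM_GAP * n
        if cur is None or cur[0] < 0:
            cur = (score, pa, pb, ri)
        else:
            cur = (cur[0] + score, cur[1], cur[2], cur[3])
        da = n if op in "=XI" else 0
        db = n if op in "=XD" else 0
        pa += da
        pb += db
        if cur[0] > 0 and (best is None or cur[0] > best[0]):
            best = (cur[0], cur[1], pa, cur[2], pb, cur[3], ri)
    if best is None:
        return None
    _, a_lo, a_hi, b_lo, b_hi, r_lo, r_hi = best
    m = x = go = 0
    pairs = []
    pa, pb = positions[r_lo]
    for n, op in runs[r_lo: r_hi + 1]:
        if op == "=":
            m += n
            pairs.append((pa, pb))
            pairs.append((pa + n - 1, pb + n - 1))
            pa += n
            pb += n
        elif op == "X":
            x += n
            pa += n
            pb += n
        elif op == "I":
            go += 1
            pa += n
        else:
            go += 1
            pb += n
    return (a_lo, a_hi, b_lo, b_hi), (m, x, go), pairs


# --------------------------------------------------------------- filtering


def block_regions(blocks, genes, max_segment_gap: int = 10_000):
    """Genomic regions of each collinear block's two sides.

    Each side is the union of its anchor genes' spans, merged through
    intergenic gaps up to ``max_segment_gap`` bp; distant stray anchors stay
    separate segments instead of inflating the block to its convex hull, so
    only regions that actually carry collinear genes exclude SDs."""
    gidx = {g.gene_id: g for g in genes}

    def side(gs):
        ivs = sorted((g.start, g.end) for g in gs)
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s - merged[-1][1] <= max_segment_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [tuple(x) for x in merged]

    out = []
    for b in blocks:
        ga = [gidx[p[0]] for p in b.pairs if p[0] in gidx]
        gb = [gidx[p[1]] for p in b.pairs if p[1] in gidx]
        if not ga or not gb:
            continue
        out.append(((b.chrom_a, side(ga)), (b.chrom_b, side(gb))))
    return out


def _covered(chrom, start, end, region):
    rc, parts = region
    if rc != chrom or end <= start:
        return 0.0
    ov = sum(max(0, min(end, pe) - max(start, ps)) for ps, pe in parts)
    return ov / (end - start)


def filter_sds(candidates, collinear_regions=(), min_len: int = MIN_SD_LEN,
               min_identity: float = MIN_SD_IDENTITY,
               wgd_overlap: float = 0.8):
    """Apply the SD definition: length >= 1 kb AND identity >= 90% (both
    inclusive) AND not explained by a whole-genome-duplication collinear
    block (both intervals covered >= ``wgd_overlap`` by the block's two
    sides, in either pairing)."""
    kept = []
    for sd in candidates:
        if sd.length < min_len or sd.identity < min_identity:
            continue
        if sd.chrom_a == sd.chrom_b and reciprocal_overlap(
                (sd.start_a, sd.end_a), (sd.start_b, sd.end_b)) > 0.5:
            continue
        in_block = False
        for ra, rb in collinear_regions:
            direct = (_covered(sd.chrom_a, sd.start_a, sd.end_a, ra)
                      >= wgd_overlap
                      and _covered(sd.chrom_b, sd.start_b, sd.end_b, rb)
                      >= wgd_overlap)
            flipped = (_covered(sd.chrom_a, sd.start_a, sd.end_a, rb)
                       >= wgd_overlap
                       and _covered(sd.chrom_b, sd.start_b, sd.end_b, ra)
                       >= wgd_overlap)
            if direct or flipped:
                in_block = True
                break
        if not in_block:
            kept.append(sd)
    return kept


# --------------------------------------------------------------- gene pairs


def _project(sd: SDRecord, start: int, end: int):
    """Project an interval on interval_a onto interval_b coordinates."""
    if sd.coord_map is not None and len(sd.coord_map) >= 2:
        xs = sd.coord_map[:, 0].astype(float)
        ys = sd.coord_map[:, 1].astype(float)
        srt = np.argsort(xs)
        lo = float(np.interp(start, xs[srt], ys[srt]))
        hi = float(np.interp(end, xs[srt], ys[srt]))
    else:
        span_a = max(sd.end_a - sd.start_a, 1)
        f0 = (start - sd.start_a) / span_a
        f1 = (end - sd.start_a) / span_a
        span_b = sd.end_b - sd.start_b
        if sd.strand == "+":
            lo, hi = sd.start_b + f0 * span_b, sd.start_b + f1 * span_b
        else:
            lo, hi = sd.end_b - f1 * span_b, sd.end_b - f0 * span_b
    a, b = sorted((lo, hi))
    return int(a), int(b) + 1


def assign_sd_gene_pairs(sds, genes, min_gene_overlap: float = 0.5):
    """Duplicated gene pairs: for each SD, genes with >= 50% of their length
    on interval_a are projected through the alignment map; the partner is
    the interval_b gene with maximal reciprocal overlap to the projection,
    itself required to have >= 50% of its length inside interval_b. Pairs
    are deduplicated (unordered gene ids) keeping the highest-identity SD."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    best: dict[tuple, SDGenePair] = {}
    for sd in sds:
        genes_a = [g for g in by_chrom.get(sd.chrom_a, [])
                   if g.length and
                   max(0, min(g.end, sd.end_a) - max(g.start, sd.start_a))
                   / g.length >= min_gene_overlap]
        genes_b = [g for g in by_chrom.get(sd.chrom_b, [])
                   if g.length and
                   max(0, min(g.end, sd.end_b) - max(g.start, sd.start_b))
                   / g.length >= min_gene_overlap]
        for ga in genes_a:
            ps, pe = _project(sd, max(ga.start, sd.start_a),
                              min(ga.end, sd.end_a))
            cand = [(reciprocal_overlap((ps, pe), (gb.start, gb.end)), gb)
                    for gb in genes_b if gb.gene_id != ga.gene_id]
            cand = [(ro, gb) for ro, gb in cand if ro > 0]
            if not cand:
                continue
            _, gb = max(cand, key=lambda x: (x[0], x[1].gene_id))
            ov_a = max(0, min(ga.end, sd.end_a) - max(ga.start, sd.start_a)) \
                / ga.length
            ov_b = max(0, min(gb.end, sd.end_b) - max(gb.start, sd.start_b)) \
                / gb.length
            key = tuple(sorted((ga.gene_id, gb.gene_id)))
            pair = SDGenePair(ga.gene_id, gb.gene_id, sd, ov_a, ov_b)
            if key not in best or sd.identity > best[key].sd.identity:
                best[key] = pair
    return sorted(best.values(), key=lambda p: (p.gene_a, p.gene_b))


# --------------------------------------------------------------- summaries


def summarize_sds(sds, genome: GenomeSet) -> dict:
    """Counts, intra/inter split, mean lengths, >10 kb fraction, and the
    merged-union genome coverage; fractions as percentages to 2 decimals."""
    from .pipeline import ratio_summary

    n = len(sds)
    intra = [s for s in sds if s.kind == "intra"]
    inter = [s for s in sds if s.kind == "inter"]
    big = [s for s in sds if s.length > 10_000]
    per_chrom: dict[str, list] = {}
    for s in sds:
        per_chrom.setdefault(s.chrom_a, []).append((s.start_a, s.end_a))
        per_chrom.setdefault(s.chrom_b, []).append((s.start_b, s.end_b))
    covered = sum(e - s for c, ivs in per_chrom.items()
                  for s, e in merge_intervals(ivs))
    gsize = genome.total_length
    return {
        "n_sds": n,
        "n_intra": len(intra),
        "n_inter": len(inter),
        "intra_pct": ratio_summary(len(intra), n, mode="percent") if n else 0.0,
        "inter_pct": ratio_summary(len(inter), n, mode="percent") if n else 0.0,
        "mean_len_intra": float(np.mean([s.length for s in intra]))
        if intra else 0.0,
        "mean_len_inter": float(np.mean([s.length for s in inter]))
        if inter else 0.0,
        "gt10kb_pct": ratio_summary(len(big), n, mode="percent") if n else 0.0,
        "coverage_bp": int(covered),
        "genome_bp": int(gsize),
        "coverage_pct": ratio_summary(covered, gsize, mode="percent")
        if gsize else 0.0,
    }


def compare_sd_ks(intra_ks, inter_ks):
    """Two-sided Wilcoxon rank-sum (normal approximation, tie-corrected)
    comparison of intra- vs inter-chromosomal SD gene-pair Ks values.

    Returns (mean_intra, mean_inter, p_value, u_statistic); NaNs when a
    group is empty. Non-finite Ks values are excluded."""
    x = np.asarray([v for v in intra_ks if np.isfinite(v)], dtype=float)
    y = np.asarray([v for v in inter_ks if np.isfinite(v)], dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(x.mean()), float(y.mean()), float(res.pvalue), \
        float(res.statistic)


def sds_to_frame(sds) -> pd.DataFrame:
    rows = [{"chrom_a": s.chrom_a, "start_a": s.start_a, "end_a": s.end_a,
             "chrom_b": s.chrom_b, "start_b": s.start_b, "end_b": s.end_b,
             "identity": round(s.identity, 4), "length": s.length,
             "kind": s.kind, "strand": s.strand} for s in sds]
    return pd.DataFrame(rows)
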