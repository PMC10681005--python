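"""Collinear gene blocks and whole-genome-duplication (WGD) pair extraction.

Homologous gene pairs (anchors) are found by translated-CDS similarity,
chained into strictly monotone collinear blocks by sparse dynamic
programming, and blocks whose median Ks falls in the recent-WGD window
(0.15-0.30 for the Maleae event) yield WGD duplicate pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from statistics import median

import numpy as np
from Bio.Seq import Seq

from .align import protein_identity
from .models import CollinearBlock, WgdPair

log = logging.getLogger(__name__)

WGD_KS_WINDOW = (0.15, 0.30)


# ----------------------------------------------------------------- anchors


def _translate(cds: str):
    if len(cds) % 3:
        return None
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot or not prot:
        return None
    return prot


def gene_ranks(genes):
    """Per-chromosome gene order index (by start coordinate)."""
    ranks = {}
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        for i, g in enumerate(sorted(gs, key=lambda x: x.start)):
            ranks[g.gene_id] = (chrom, i)
    return ranks


def homolog_pairs(genes, genome, min_protein_identity: float = 0.5,
                  tandem_max_rank_gap: int = 5, prefilter_k: int = 5):
    """Anchor pairs: reciprocal-best and near-best (within 5% of each gene's
    best score) translated-CDS matches.

    A shared-peptide-k-mer prefilter limits the all-vs-all comparison;
    identity is edit-distance protein identity. Untranslatable CDS are
    skipped with a warning; tandem duplicates (same chromosome, rank
    distance <= ``tandem_max_rank_gap``) are excluded from anchors.
    """
    prots = {}
    for g in genes:
        p = _translate(g.cds_sequence(genome))
        if p is None:
            log.warning("untranslatable CDS for %s; skipped", g.gene_id)
            continue
        prots[g.gene_id] = p
    ranks = gene_ranks(genes)
    kindex: dict[str, set] = {}
    for gid, p in prots.items():
        for i in range(0, max(len(p) - prefilter_k + 1, 0), 2):
            kindex.setdefault(p[i: i + prefilter_k], set()).add(gid)
    cand_pairs = set()
    for gids in kindex.values():
        if len(gids) < 2 or len(gids) > 50:
            continue
        for a, b in itertools.combinations(sorted(gids), 2):
            cand_pairs.add((a, b))
    scores = {}
    for a, b in cand_pairs:
        ident = protein_identity(prots[a], prots[b])
        if ident >= min_protein_identity:
            scores[(a, b)] = ident
    best = {}
    for (a, b), s in scores.items():
        best[a] = max(best.get(a, 0.0), s)
        best[b] = max(best.get(b, 0.0), s)
    anchors = []
    for (a, b), s in sorted(scores.items()):
        if s < 0.95 * best[a] or s < 0.95 * best[b]:
            continue
        ca, ra = ranks[a]
        cb, rb = ranks[b]
        if ca == cb and abs(ra - rb) <= tandem_max_rank_gap:
            continue
        anchors.append((a, b, s))
    return anchors


# ----------------------------------------------------------------- chaining


GAP_PENALTY = 0.01


def _chain_score(chain, gap_penalty=GAP_PENALTY):
    """pairs - gap_penalty * total skipped ranks on both chromosomes."""
    gaps = 0
    for (ra0, rb0), (ra1, rb1) in zip(chain, chain[1:]):
        gaps += (abs(ra1 - ra0) - 1) + (abs(rb1 - rb0) - 1)
    return len(chain) - gap_penalty * gaps


def _best_chain_dp(points, orientation: str, max_gap: int,
                   gap_penalty=GAP_PENALTY):
    """Highest-scoring strictly monotone chain over (ra, rb) points."""
    sgn = 1 if orientation == "+" else -1
    pts = sorted(range(len(points)), key=lambda i: (points[i][0],
                                                    sgn * points[i][1]))
    score = [1.0] * len(points)
    back = [-1] * len(points)
    for ii, i in enumerate(pts):
        ra, rb = points[i]
        for j in pts[:ii]:
            ra_j, rb_j = points[j]
            if ra_j >= ra:
                continue
            if (sgn > 0 and rb_j >= rb) or (sgn < 0 and rb_j <= rb):
                continue
            ga, gb = ra - ra_j - 1, abs(rb - rb_j) - 1
            if ga > max_gap or gb > max_gap:
                continue
            s = score[j] + 1.0 - gap_penalty * (ga + gb)
            if s > score[i]:
                score[i] = s
                back[i] = j
    if not points:
        return [], 0.0
    end = max(range(len(points)), key=lambda i: score[i])
    chain = []
    i = end
    while i != -1:
        chain.append(i)
        i = back[i]
    chain.reverse()
    return chain, score[end]


def chain_blocks(anchors, genes, min_block_pairs: int = 5,
                 max_gap_genes: int = 25):
    """Collinear blocks by iterated sparse DP chaining.

    Anchors are grouped by chromosome pair; within each group the
    best-scoring monotone chain (either orientation) is extracted, its
    anchors retired, and the search repeated while chains reach
    ``min_block_pairs``. Score = pairs - 0.01 x skipped gene ranks.
    """
    ranks = gene_ranks(genes)
    grouped: dict[tuple, list] = {}
    for a, b, s in anchors:
        ca, ra = ranks[a]
        cb, rb = ranks[b]
        if (ca, cb) > ((cb, ca)):
            a, b, ca, ra, cb, rb = b, a, cb, rb, ca, ra
        grouped.setdefault((ca, cb), []).append((a, b, ra, rb))
    blocks = []
    for (ca, cb), items in sorted(grouped.items()):
        pool = list(items)
        while True:
            points = [(ra, rb) for _, _, ra, rb in pool]
            best = None
            for orientation in "+-":
                chain, score = _best_chain_dp(points, orientation,
                                              max_gap_genes)
                if chain and (best is None or score > best[1]):
                    best = (chain, score, orientation)
            if best is None or len(best[0]) < min_block_pairs:
                break
            chain, _, orientation = best
            pairs = [(pool[i][0], pool[i][1]) for i in chain]
            blocks.append(CollinearBlock(pairs, ca, cb, orientation))
            used = set(chain)
            pool = [x for i, x in enumerate(pool) if i not in used]
    return blocks


def brute_force_best_chain(points, max_gap: int, gap_penalty=GAP_PENALTY):
    """Exhaustive maximum-score monotone chain (oracle; <= ~12 anchors)."""
    best_score, best_chain = 0.0, []
    n = len(points)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            pts = [points[i] for i in combo]
            pts_sorted = sorted(pts)
            ra = [p[0] for p in pts_sorted]
            rb = [p[1] for p in pts_sorted]
            if len(set(ra)) < len(ra):
                continue
            inc = all(b1 > b0 for b0, b1 in zip(rb, rb[1:]))
            dec = all(b1 < b0 for b0, b1 in zip(rb, rb[1:]))
            if not (inc or dec):
                continue
            if any(a1 - a0 - 1 > max_gap or abs(b1 - b0) - 1 > max_gap
                   for (a0, b0), (a1, b1) in zip(pts_sorted, pts_sorted[1:])):
                continue
            s = _chain_score(pts_sorted, gap_penalty)
            if s > best_score:
                best_score, best_chain = s, pts_sorted
    return best_chain, best_score


# ----------------------------------------------------------------- WGD pairs


def extract_wgd_pairs(blocks, ks_table: dict, window=WGD_KS_WINDOW):
    """WGD pairs from blocks whose median Ks lies in the closed window.

    ``ks_table`` maps frozenset({gene_a, gene_b}) -> KaKsResult (or an
    object with ks/ka/ratio attributes). Blocks with no defined Ks are
    excluded with a log message. Sets ``median_ks`` on each block."""
    lo, hi = window
    out = []
    for bi, block in enumerate(blocks):
        ks_vals = []
        for a, b in block.pairs:
            r = ks_table.get(frozenset((a, b)))
            if r is not None and np.isfinite(r.ks):
                ks_vals.append(r.ks)
        if not ks_vals:
            log.info("block %d has no defined Ks; excluded", bi)
            block.median_ks = math.nan
            continue
        block.median_ks = float(median(ks_vals))
        if lo <= block.median_ks <= hi:
            for a, b in block.pairs:
                r = ks_table.get(frozenset((a, b)))
                out.append(WgdPair(
                    a, b, bi,
                    ks=r.ks if r else math.nan,
                    ka=r.ka if r else math.nan,
                    ka_ks=r.ratio if r else math.nan))
    return out


# ----------------------------------------------------------------- random


def random_pairs(gene_ids, n: int = 10_000, seed: int = 0):
    """n distinct unordered gene pairs sampled uniformly without replacement
    (all pairs when fewer exist)."""
    ids = sorted(set(gene_ids))
    m = len(ids)
    if m < 2:
        raise ValueError("need at least 2 genes")
    total = m * (m - 1) // 2
    if n >= total:
        return [(a, b) for a, b in itertools.combinations(ids, 2)]
    rng = np.random.default_rng(seed)
    chosen = set()
    while len(chosen) < n:
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        if i > j:
            i, j = j, i
        chosen.add((int(i), int(j)))
    return sorted((ids[i], ids[j]) for i, j in chosen)
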