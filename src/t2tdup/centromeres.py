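"""Centromeric satellite discovery and centromere calling.

The centromeric satellite is found as a tandem array of a ~198-bp monomer:
a bespoke period scan (k-mer spaced-match voting for candidate periods,
then self-match verification at each period) yields arrays and their
monomer instances; monomers are clustered greedily at 80% identity to build
a consensus; the genome is re-scanned with the consensus to produce a
monomer-density track; and one centromere per chromosome is called as the
longest run of dense bins, annotated with gene density and the Gypsy
fraction of overlapping transposable-element bases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align import banded_identity, infix_identity
from .models import (CentromereCall, GenomeSet, MonomerCluster, TandemArray,
                     merge_intervals, revcomp)

DEFAULT_BIN = 10_000


# ------------------------------------------------------------- tandem arrays


def _candidate_periods(seq: str, min_period: int, max_period: int,
                       k: int = 12, min_votes: int = 10):
    """Periods supported by many spaced k-mer self-matches."""
    if len(seq) < k + min_period:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    # hash k-mers by polynomial rolling encoding (4 bits per base is enough)
    enc = arr.astype(np.int64)
    kmers = np.zeros(len(arr) - k + 1, dtype=np.int64)
    for i in range(k):
        kmers = kmers * 131 + enc[i: len(arr) - k + 1 + i]
    order = np.argsort(kmers, kind="stable")
    votes = np.zeros(max_period + 1, dtype=np.int64)
    sorted_k = kmers[order]
    boundaries = np.nonzero(np.diff(sorted_k))[0] + 1
    start = 0
    for b in list(boundaries) + [len(sorted_k)]:
        group = np.sort(order[start:b])
        start = b
        if 2 <= len(group) <= 1000:
            d = np.diff(group)
            d = d[(d >= min_period) & (d <= max_period)]
            np.add.at(votes, d, 1)
    cands = [int(p) for p in np.nonzero(votes >= min_votes)[0]
             if p >= min_period]
    cands.sort(key=lambda p: (p, -votes[p]))
    return cands


def find_tandem_arrays(seq: str, min_period: int = 2, max_period: int = 500,
                       min_copies: int = 10, min_identity: float = 0.8,
                       chrom: str = ""):
    """Maximal tandem-repeat intervals where consecutive period-length
    windows match at >= min_identity.

    Candidate periods come from spaced k-mer voting; each is verified by the
    self-match profile m[i] = [seq[i] == seq[i+p]] averaged over one period.
    Smaller periods are scanned first and intervals already explained by a
    smaller period are not re-reported at its multiples.
    """
    if not (2 <= min_period <= max_period):
        raise ValueError("need 2 <= min_period <= max_period")
    n = len(seq)
    if n < 2 * min_period:
        return []
    max_period = min(max_period, n // 2)
    if max_period < min_period:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    arrays: list[TandemArray] = []
    claimed: list[tuple] = []
    for p in _candidate_periods(seq, min_period, max_period,
                                min_votes=max(3, min_copies // 2)):
        m = (arr[:-p] == arr[p:]).astype(np.float32)
        if len(m) < p:
            continue
        kernel = np.ones(p) / p
        q = np.convolve(m, kernel, mode="valid")  # q[i] ~ identity of window i
        good = q >= min_identity
        # log-likelihood weights for the array-start changepoint refinement
        w = np.where(m > 0, 1.28, -2.01)
        # maximal runs of good positions
        edges = np.flatnonzero(np.diff(np.concatenate(([0], good.view(np.int8),
                                                       [0]))))
        for rs, re_ in zip(edges[::2], edges[1::2]):
            a, b = int(rs), int(re_) + 2 * p - 1
            b = min(b, n)
            # refine the array start: the threshold crossing of the windowed
            # profile leads the true boundary, which also fixes the monomer
            # phase; maximize the in-array log-likelihood suffix sum
            lo = max(0, a - p)
            hi = min(a + p, len(w))
            if hi > lo:
                seg = w[lo:hi]
                suffix = np.cumsum(seg[::-1])[::-1]
                a = lo + int(np.argmax(suffix))
            copies = (b - a) // p
            if copies < min_copies:
                continue
            if any(min(b, ce) - max(a, cs) > 0.5 * (b - a)
                   for cs, ce in claimed):
                continue
            ident = float(m[a: b - p].mean()) if b - p > a else 1.0
            monomers = [seq[a + t * p: a + (t + 1) * p] for t in range(copies)]
            arrays.append(TandemArray(chrom, a, a + copies * p, p, copies,
                                      ident, monomers))
            claimed.append((a, b))
    arrays.sort(key=lambda t: t.start)
    return arrays


def genome_tandem_arrays(genome: GenomeSet, **kwargs):
    out = []
    for chrom in sorted(genome):
        out.extend(find_tandem_arrays(genome[chrom], chrom=chrom, **kwargs))
    return out


# ------------------------------------------------------------- clustering


def cluster_monomers(monomers, identity_threshold: float = 0.8):
    """Greedy length-descending clustering of monomer sequences.

    A monomer joins the first cluster whose representative it matches at
    >= the identity threshold (banded global identity, better of the two
    strand orientations; the member is stored in the representative's
    orientation); the consensus is the per-column majority over members of
    the representative's length.
    """
    if not monomers:
        raise ValueError("no monomers to cluster")
    ordered = sorted((m.upper() for m in monomers), key=len, reverse=True)
    reps: list[str] = []
    members: list[list] = []
    for m in ordered:
        rc = revcomp(m)
        for i, rep in enumerate(reps):
            idf = banded_identity(m, rep)
            idr = banded_identity(rc, rep)
            if max(idf, idr) >= identity_threshold:
                members[i].append(m if idf >= idr else rc)
                break
        else:
            reps.append(m)
            members.append([m])
    clusters = []
    for rep, mem in zip(reps, members):
        width = len(rep)
        same_len = [x for x in mem if len(x) == width] or [rep]
        mat = np.frombuffer("".join(same_len).encode(),
                            dtype=np.uint8).reshape(len(same_len), width)
        consensus = bytes(
            np.array([np.bincount(col, minlength=256).argmax()
                      for col in mat.T], dtype=np.uint8)).decode()
        clusters.append(MonomerCluster(mem, consensus, len(mem)))
    clusters.sort(key=lambda c: -c.genome_copies)
    return clusters


# ------------------------------------------------------------- density track


def scan_consensus(genome: GenomeSet, consensus: str,
                   hit_identity: float = 0.7, bin_size: int = DEFAULT_BIN):
    """Monomer-density track: per bin, the fraction of bases in consensus hits.

    The genome is tiled with consensus-length windows; a window is a hit when
    it aligns at >= hit_identity to the doubled consensus (which contains
    every rotation of the monomer) on either strand. Overlapping hits are
    merged before densities are computed.
    """
    if len(consensus) < 50:
        raise ValueError("consensus shorter than 50 bp")
    p = len(consensus)
    doubled = consensus * 2
    doubled_rc = revcomp(doubled)
    track = {}
    for chrom in sorted(genome):
        seq = genome[chrom]
        hits = []
        for start in range(0, len(seq) - p + 1, p):
            w = seq[start: start + p]
            if (infix_identity(w, doubled) >= hit_identity
                    or infix_identity(w, doubled_rc) >= hit_identity):
                hits.append((start, start + p))
        merged = merge_intervals(hits)
        nbins = (len(seq) + bin_size - 1) // bin_size
        density = np.zeros(nbins)
        for s, e in merged:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo, hi = b * bin_size, min((b + 1) * bin_size, len(seq))
                density[b] += max(0, min(e, hi) - max(s, lo))
        sizes = np.minimum(np.arange(1, nbins + 1) * bin_size, len(seq)) \
            - np.arange(nbins) * bin_size
        track[chrom] = density / sizes
    return track


def track_frame(track, bin_size: int = DEFAULT_BIN) -> pd.DataFrame:
    rows = []
    for chrom, dens in track.items():
        for i, d in enumerate(dens):
            rows.append({"chrom": chrom, "bin_start": i * bin_size,
                         "density": float(d)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- calling


def call_centromeres(track, genes=(), tes=(), min_monomer_density: float = 0.3,
                     bin_size: int = DEFAULT_BIN, chrom_lengths=None):
    """One centromere per chromosome: the maximal run of dense bins.

    Ties are broken by the longer run, then by the leftmost. Chromosomes
    with no qualifying bin yield no call (flagged by absence). Gene density
    (genes/Mb, by midpoint) and the Gypsy fraction of overlapping TE bases
    annotate each call.
    """
    calls = []
    for chrom in sorted(track):
        dens = np.asarray(track[chrom])
        good = dens >= min_monomer_density
        best = None  # (length_bins, -start) maximized
        i = 0
        while i < len(good):
            if good[i]:
                j = i
                while j + 1 < len(good) and good[j + 1]:
                    j += 1
                if best is None or (j - i) > best[1] - best[0]:
                    best = (i, j)
                i = j + 1
            else:
                i += 1
        if best is None:
            continue
        start = best[0] * bin_size
        end = (best[1] + 1) * bin_size
        if chrom_lengths and chrom in chrom_lengths:
            end = min(end, chrom_lengths[chrom])
        span = end - start
        n_genes = sum(1 for g in genes
                      if g.chrom == chrom and start <= g.midpoint < end)
        te_bp = gypsy_bp = 0
        for t in tes:
            if t.chrom != chrom:
                continue
            ov = max(0, min(t.end, end) - max(t.start, start))
            te_bp += ov
            if t.family == "Gypsy":
                gypsy_bp += ov
        calls.append(CentromereCall(
            chrom, start, end,
            monomer_density=float(dens[best[0]: best[1] + 1].mean()),
            gene_density=n_genes / (span / 1e6),
            te_gypsy_fraction=(gypsy_bp / te_bp) if te_bp else float("nan"),
        ))
    return calls


def centromeric_gene_expression(calls, genes, tpm: pd.DataFrame,
                                threshold: float = 1.0):
    """(n_genes, n_expressed, percent) for genes inside centromere calls.

    A gene is centromeric when its midpoint lies in a call; expressed when
    its maximum TPM over all columns exceeds the threshold. The percentage
    is NaN when no gene is centromeric.
    """
    from .pipeline import ratio_summary

    by_chrom = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    cen_genes = [g.gene_id for g in genes
                 if any(s <= g.midpoint < e
                        for s, e in by_chrom.get(g.chrom, []))]
    n = len(cen_genes)
    if n == 0:
        return 0, 0, float("nan")
    present = [g for g in cen_genes if g in tpm.index]
    n_expr = int((tpm.loc[present].max(axis=1) > threshold).sum())
    return n, n_expr, ratio_summary(n_expr, n, mode="percent")
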