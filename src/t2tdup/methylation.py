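"""Gene-body cytosine methylation in the CG/CHG/CHH plant contexts.

Levels are weighted fractions — summed methylated reads over summed total
reads across the covered cytosines of a gene body — never means of
per-site fractions. Context is called from the reference sequence
(minus-strand cytosines on the reverse complement).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GeneMethylation, revcomp

log = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")


def call_context(sequence: str, position: int, strand: str = "+") -> str:
    """Context of the cytosine at ``position`` (0-based) on ``strand``.

    CG when the next base is G; CHG when the next is H (A/C/T) and the one
    after is G; CHH otherwise. Requires two downstream bases on the strand.
    """
    sequence = sequence.upper()
    if strand == "+":
        tri = sequence[position: position + 3]
    elif strand == "-":
        tri = revcomp(sequence[position - 2: position + 1])
    else:
        raise ValueError(f"bad strand {strand!r}")
    if not tri or tri[0] != "C":
        raise ValueError(f"no cytosine at {position} on strand {strand}")
    if len(tri) < 3:
        raise ValueError("need two downstream bases to call the context")
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def gene_levels(records: pd.DataFrame, genes, min_coverage: int = 1):
    """Weighted gene-body methylation level per gene per context.

    Both strands are pooled; cytosines with total coverage below
    ``min_coverage`` are excluded. Genes with no covered cytosine in a
    context get level NaN."""
    out = []
    cov = records["count_methylated"] + records["count_unmethylated"]
    recs = records[cov >= min_coverage]
    by_chrom = {c: sub.sort_values("position")
                for c, sub in recs.groupby("chrom")}
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            rows = None
        else:
            pos = sub["position"].to_numpy()
            lo = np.searchsorted(pos, g.start + 1, side="left")
            hi = np.searchsorted(pos, g.end, side="right")
            rows = sub.iloc[lo:hi]
        for ctx in CONTEXTS:
            if rows is None or not len(rows):
                out.append(GeneMethylation(g.gene_id, ctx, math.nan, 0))
                continue
            cs = rows[rows["context"] == ctx]
            meth = int(cs["count_methylated"].sum())
            total = meth + int(cs["count_unmethylated"].sum())
            level = meth / total if total else math.nan
            out.append(GeneMethylation(g.gene_id, ctx, level, len(cs)))
    return out


def levels_frame(levels) -> pd.DataFrame:
    return pd.DataFrame([{"gene_id": g.gene_id, "context": g.context,
                          "level": g.level, "n_cytosines": g.n_cytosines}
                         for g in levels])


def category_profiles(records: pd.DataFrame, genes, categories: dict,
                      min_coverage: int = 1, body_bins: int = 60,
                      flank_bins: int = 20, flank: int = 2000):
    """Per-category, per-context summaries plus a scaled metagene track.

    ``categories`` maps gene_id -> group label. The metagene track covers
    the 5' flank (``flank_bins`` bins over ``flank`` bp), the gene body
    scaled to ``body_bins`` bins, and the 3' flank; bin levels are weighted
    within a gene then averaged across the genes of a category. Empty
    categories are omitted with a warning."""
    lv = levels_frame(gene_levels(records, genes, min_coverage))
    lv["category"] = lv["gene_id"].map(categories)
    lv = lv.dropna(subset=["category"])
    summary = (lv.dropna(subset=["level"])
               .groupby(["category", "context"])["level"]
               .agg(["mean", "median", "count"]).reset_index())
    wanted = set(categories.values())
    for cat in sorted(wanted - set(summary["category"])):
        log.warning("category %r has no measured genes; omitted", cat)

    total_bins = body_bins + 2 * flank_bins
    cov = records["count_methylated"] + records["count_unmethylated"]
    recs = records[cov >= min_coverage]
    by_chrom = {c: sub.sort_values("position")
                for c, sub in recs.groupby("chrom")}
    acc: dict[tuple, list] = {}
    for g in genes:
        cat = categories.get(g.gene_id)
        if cat is None:
            continue
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        lo0, hi0 = g.start - flank, g.end + flank
        pos = sub["position"].to_numpy()
        lo = np.searchsorted(pos, lo0 + 1, side="left")
        hi = np.searchsorted(pos, hi0, side="right")
        rows = sub.iloc[lo:hi]
        if not len(rows):
            continue
        p0 = rows["position"].to_numpy() - 1  # back to 0-based
        rel = np.empty(len(rows))
        before = p0 < g.start
        after = p0 >= g.end
        body = ~(before | after)
        rel[before] = (p0[before] - (g.start - flank)) / flank * flank_bins
        glen = max(g.end - g.start, 1)
        rel[body] = flank_bins + (p0[body] - g.start) / glen * body_bins
        rel[after] = flank_bins + body_bins + \
            (p0[after] - g.end) / flank * flank_bins
        if g.strand == "-":
            rel = total_bins - rel
        bins = np.clip(rel.astype(int), 0, total_bins - 1)
        meth = rows["count_methylated"].to_numpy()
        tot = meth + rows["count_unmethylated"].to_numpy()
        ctxs = rows["context"].to_numpy()
        for ctx in CONTEXTS:
            sel = ctxs == ctx
            if not sel.any():
                continue
            msum = np.bincount(bins[sel], weights=meth[sel],
                               minlength=total_bins)
            tsum = np.bincount(bins[sel], weights=tot[sel],
                               minlength=total_bins)
            with np.errstate(invalid="ignore"):
                gene_track = np.where(tsum > 0, msum / np.maximum(tsum, 1),
                                      np.nan)
            acc.setdefault((cat, ctx), []).append(gene_track)
    track_rows = []
    for (cat, ctx), tracks in sorted(acc.items()):
        mat = np.vstack(tracks)
        finite = np.isfinite(mat)
        n_per_bin = finite.sum(axis=0)
        mean_track = np.where(
            n_per_bin > 0,
            np.where(finite, mat, 0.0).sum(axis=0) / np.maximum(n_per_bin, 1),
            np.nan)
        for b in range(total_bins):
            track_rows.append({"category": cat, "context": ctx, "bin": b,
                               "mean_level": float(mean_track[b]),
                               "n_genes": int(np.isfinite(mat[:, b]).sum())})
    track = pd.DataFrame(track_rows,
                         columns=["category", "context", "bin",
                                  "mean_level", "n_genes"])
    return summary, track


def methylation_expression_correlation(levels_by_sample: dict,
                                       expr_by_sample: pd.DataFrame,
                                       pairs: pd.DataFrame,
                                       fdr: float = 0.05):
    """Per-gene methylation/expression correlation and per-pair flags.

    ``levels_by_sample`` maps context -> DataFrame (genes x samples) of
    gene-body levels; ``expr_by_sample`` is replicate-mean TPM per sample.
    Pearson r is computed per gene and context against log2(TPM+1) over the
    shared samples, BH-corrected across all genes x contexts; a pair is
    flagged when either member is significant in a context. Constant
    vectors are excluded."""
    logex = np.log2(expr_by_sample + 1.0)
    rows = []
    for ctx, lv in levels_by_sample.items():
        common = [s for s in lv.columns if s in logex.columns]
        if len(common) < 4:
            raise ValueError("need >= 4 shared samples")
        for gene in lv.index:
            if gene not in logex.index:
                continue
            x = lv.loc[gene, common].to_numpy(dtype=float)
            y = logex.loc[gene, common].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"gene_id": gene, "context": ctx,
                         "r": float(r), "p": float(p)})
    gene_table = pd.DataFrame(rows, columns=["gene_id", "context", "r", "p"])
    if len(gene_table):
        gene_table["q"] = multipletests(gene_table["p"], method="fdr_bh")[1]
        gene_table["significant"] = gene_table["q"] < fdr
    else:
        gene_table["q"] = []
        gene_table["significant"] = []
    sig = {(r.gene_id, r.context) for r in gene_table.itertuples()
           if r.significant}
    pair_rows = []
    for row in pairs.itertuples():
        entry = {"pair_id": row.pair_id, "gene_a": row.gene_a,
                 "gene_b": row.gene_b}
        any_sig = False
        for ctx in levels_by_sample:
            flag = (row.gene_a, ctx) in sig or (row.gene_b, ctx) in sig
            entry[f"sig_{ctx}"] = flag
            any_sig = any_sig or flag
        entry["significant"] = any_sig
        pair_rows.append(entry)
    return gene_table, pd.DataFrame(pair_rows)
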