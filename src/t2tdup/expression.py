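"""Expression divergence of duplicated gene pairs.

Pairs are classified from replicated multi-sample expression:

* Sub (sub-/neo-functionalized): each gene is significantly higher than its
  partner in at least one sample;
* AED (asymmetrically expressed duplicate): one gene is significantly
  higher in at least one third of the samples (ceil(M/3)) and the partner
  is higher in none;
* NoDiff: everything else.

Per-sample comparisons are Welch t-tests on log2(TPM+1) between the two
genes' replicates, Benjamini-Hochberg corrected across all pair x sample
tests, gated jointly on FDR < 0.05 and |log2 fold change| >= 1.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import DivergenceCategory, PairSampleStatus

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.05
DEFAULT_LFC = 1.0


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from a count matrix and effective lengths.

    rate = count / length; TPM = rate / column_sum(rate) x 1e6. Every
    column sums to 1e6 (all-zero columns stay zero, with a warning)."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        log.warning("all-zero count column(s): %s", list(colsum.index[zero]))
        colsum = colsum.replace(0, np.nan)
    out = rate.div(colsum, axis=1) * 1e6
    return out.fillna(0.0)


def split_columns(columns):
    """Map 'sample.rep' column labels to {sample: [columns]} preserving order."""
    groups: dict[str, list] = {}
    for col in columns:
        sample = col.rsplit(".", 1)[0]
        groups.setdefault(sample, []).append(col)
    return groups


def sample_means(tpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean TPM per sample (genes x samples)."""
    groups = split_columns(tpm_matrix.columns)
    return pd.DataFrame({s: tpm_matrix[cols].mean(axis=1)
                         for s, cols in groups.items()})


def pair_sample_tests(pairs: pd.DataFrame, tpm_matrix: pd.DataFrame,
                      fdr: float = DEFAULT_FDR, lfc: float = DEFAULT_LFC):
    """Per-pair, per-sample differential calls.

    ``pairs`` needs columns pair_id, gene_a, gene_b. Welch t-test on
    log2(TPM+1) between the two genes' replicates within each sample;
    BH correction spans all pair x sample tests of the run; a direction is
    called only when q < fdr AND |log2fc| >= lfc."""
    groups = split_columns(tpm_matrix.columns)
    if any(len(cols) < 2 for cols in groups.values()):
        raise ValueError("every sample needs >= 2 replicates")
    logm = np.log2(tpm_matrix + 1.0)
    records = []
    for _, row in pairs.iterrows():
        ga, gb = row["gene_a"], row["gene_b"]
        for sample, cols in groups.items():
            xa = logm.loc[ga, cols].to_numpy(dtype=float)
            xb = logm.loc[gb, cols].to_numpy(dtype=float)
            ma = float(tpm_matrix.loc[ga, cols].mean())
            mb = float(tpm_matrix.loc[gb, cols].mean())
            if ma == mb:
                l2fc = 0.0
            elif mb == 0.0:
                l2fc = math.inf
            elif ma == 0.0:
                l2fc = -math.inf
            else:
                l2fc = math.log2(ma / mb)
            if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]) \
                    and xa[0] == xb[0]:
                p = 1.0
            else:
                p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
                if not np.isfinite(p):
                    p = 1.0
            records.append([row["pair_id"], sample, l2fc, p])
    df = pd.DataFrame(records, columns=["pair_id", "sample", "log2fc", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    statuses = []
    for r in df.itertuples():
        call = "no_difference"
        if r.q < fdr and abs(r.log2fc) >= lfc:
            call = "a_higher" if r.log2fc > 0 else "b_higher"
        statuses.append(PairSampleStatus(r.pair_id, r.sample, call,
                                         r.log2fc, r.q))
    return statuses


def classify_pair(statuses, gene_a: str, gene_b: str) -> DivergenceCategory:
    """Category of one pair from its per-sample statuses.

    Sub takes precedence (each gene higher somewhere); AED requires one gene
    higher in >= ceil(M/3) samples with the partner higher in none."""
    m = len(statuses)
    if m == 0:
        raise ValueError("no per-sample statuses")
    pair_id = statuses[0].pair_id
    na = sum(1 for s in statuses if s.call == "a_higher")
    nb = sum(1 for s in statuses if s.call == "b_higher")
    third = math.ceil(m / 3)
    if na >= 1 and nb >= 1:
        return DivergenceCategory(pair_id, "Sub")
    if na >= third and nb == 0:
        return DivergenceCategory(pair_id, "AED", dominant_gene=gene_a)
    if nb >= third and na == 0:
        return DivergenceCategory(pair_id, "AED", dominant_gene=gene_b)
    return DivergenceCategory(pair_id, "NoDiff")


def classify_pairs(pairs: pd.DataFrame, tpm_matrix: pd.DataFrame,
                   fdr: float = DEFAULT_FDR, lfc: float = DEFAULT_LFC):
    """End-to-end: per-sample tests then one category per pair."""
    statuses = pair_sample_tests(pairs, tpm_matrix, fdr=fdr, lfc=lfc)
    by_pair: dict[str, list] = {}
    for s in statuses:
        by_pair.setdefault(s.pair_id, []).append(s)
    cats = []
    for _, row in pairs.iterrows():
        cats.append(classify_pair(by_pair[row["pair_id"]],
                                  row["gene_a"], row["gene_b"]))
    assert len(cats) == len(pairs)
    return cats, statuses


def category_counts(categories) -> dict:
    out = {"AED": 0, "Sub": 0, "NoDiff": 0}
    for c in categories:
        out[c.category] += 1
    return out


def pair_correlations(pair_groups: dict, tpm_matrix: pd.DataFrame):
    """Pearson r of replicate-mean log2(TPM+1) profiles for each pair,
    reported per group (e.g. SD, WGD, random).

    Returns (DataFrame[group, gene_a, gene_b, r], excluded) where
    ``excluded`` counts pairs dropped for a zero-variance member."""
    groups = split_columns(tpm_matrix.columns)
    if len(groups) < 3:
        raise ValueError("need >= 3 samples for pair correlations")
    logm = np.log2(tpm_matrix + 1.0)
    prof = pd.DataFrame({s: logm[cols].mean(axis=1)
                         for s, cols in groups.items()})
    rows = []
    excluded = {g: 0 for g in pair_groups}
    for group, pairs in pair_groups.items():
        for ga, gb in pairs:
            if ga not in prof.index or gb not in prof.index:
                excluded[group] += 1
                continue
            x = prof.loc[ga].to_numpy()
            y = prof.loc[gb].to_numpy()
            if x.std() == 0 or y.std() == 0:
                excluded[group] += 1
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"group": group, "gene_a": ga, "gene_b": gb, "r": r})
    return pd.DataFrame(rows, columns=["group", "gene_a", "gene_b", "r"]), \
        excluded
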