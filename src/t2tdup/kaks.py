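"""Nei-Gojobori (NG86) Ka/Ks estimation on codon-aligned duplicate pairs.

The method counts, for each codon, the fraction of the nine possible
single-base substitutions that are synonymous (site counting), averages
observed per-codon differences over all mutational pathways that avoid stop
codons (difference counting), and applies the Jukes-Cantor multiple-hit
correction d = -3/4 ln(1 - 4/3 p) to the synonymous and nonsynonymous
proportions separately. Equal codon frequencies are assumed (classic NG86);
the standard nuclear genetic code is the only one supported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .align import protein_aligner
from .models import KaKsResult

BASES = "ACGT"

CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
_AA = {c: str(Seq(c).translate()) for c in CODONS}
STOP_CODONS = frozenset(c for c, aa in _AA.items() if aa == "*")
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def translate_codon(codon: str) -> str:
    return _AA[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def _site_fractions(codon: str):
    """Per-codon synonymous/nonsynonymous site counts.

    For each of the three positions the fraction of the three possible
    substitutions that preserve the amino acid; changes creating a stop codon
    count as nonsynonymous.
    """
    s = 0.0
    aa = _AA[codon]
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut not in STOP_CODONS and _AA[mut] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


_SITES = {c: _site_fractions(c) for c in SENSE_CODONS}


def ng_count_sites(codon: str):
    """(synonymous, nonsynonymous) fractional site counts; s + n = 3."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no NG site counts")
    if codon not in _SITES:
        raise ValueError(f"not a standard codon: {codon!r}")
    return _SITES[codon]


def _pathway_counts(a: str, b: str):
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0, False
    syn_totals = []
    for order in itertools.permutations(diff_pos):
        cur = a
        syn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _AA[nxt] == _AA[cur]:
                syn += 1
            cur = nxt
        if ok:
            syn_totals.append(syn)
    if not syn_totals:
        # every pathway passes through a stop: all changes nonsynonymous
        return 0.0, float(k), True
    sd = float(np.mean(syn_totals))
    return sd, k - sd, False


_DIFFS = {}
for _a in SENSE_CODONS:
    for _b in SENSE_CODONS:
        _DIFFS[(_a, _b)] = _pathway_counts(_a, _b)


def ng_count_diffs(codon_a: str, codon_b: str):
    """Pathway-averaged (synonymous, nonsynonymous) observed differences.

    Pathways through stop codons are excluded; when no stop-free pathway
    exists all differences are counted as nonsynonymous (flagged upstream).
    sd + nd equals the number of differing positions whenever at least one
    stop-free pathway exists.
    """
    key = (codon_a.upper(), codon_b.upper())
    if key not in _DIFFS:
        raise ValueError(f"stop or non-standard codon in pair {key}")
    sd, nd, _ = _DIFFS[key]
    return sd, nd


def codon_align(cds_a: str, cds_b: str):
    """Protein-guided codon alignment of two CDS.

    Translates both CDS, aligns the proteins globally (BLOSUM62, affine
    gaps), back-translates the alignment to codons, and drops gap columns
    and codons containing ambiguity characters. Returns (codons_a, codons_b)
    as equal-length lists of 3-mers.
    """
    for name, cds in (("cds_a", cds_a), ("cds_b", cds_b)):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"{name} length {len(cds)} not divisible by 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    cod_a = [cds_a[i: i + 3] for i in range(0, len(cds_a), 3)]
    cod_b = [cds_b[i: i + 3] for i in range(0, len(cds_b), 3)]
    for name, cods in (("cds_a", cod_a), ("cds_b", cod_b)):
        for i, c in enumerate(cods[:-1]):
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon in {name} at codon {i}")
    # trailing stop codons are trimmed before alignment
    if cod_a and cod_a[-1] in STOP_CODONS:
        cod_a = cod_a[:-1]
    if cod_b and cod_b[-1] in STOP_CODONS:
        cod_b = cod_b[:-1]
    prot_a = "".join(_AA.get(c, "X") for c in cod_a)
    prot_b = "".join(_AA.get(c, "X") for c in cod_b)
    aln = protein_aligner().align(prot_a, prot_b)[0]
    out_a, out_b = [], []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for off in range(ea - sa):
            ca, cb = cod_a[sa + off], cod_b[sb + off]
            if set(ca) <= set(BASES) and set(cb) <= set(BASES):
                out_a.append(ca)
                out_b.append(cb)
    return out_a, out_b


SATURATION = 0.75


def ng_kaks(codons_a, codons_b) -> KaKsResult:
    """NG86 Ka/Ks on a gap-free codon alignment (two equal-length codon lists)."""
    if len(codons_a) != len(codons_b):
        raise ValueError("codon lists differ in length")
    if not codons_a:
        raise ValueError("empty codon alignment")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, _ = ng_count_sites(ca)
        sb, _ = ng_count_sites(cb)
        s_a += sa
        s_b += sb
        d_s, d_n = ng_count_diffs(ca, cb)
        sd += d_s
        nd += d_n
    n_codons = len(codons_a)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0

    def jc(p):
        if p >= SATURATION:
            return math.nan
        return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) if p > 0 else 0.0

    ks = jc(ps)
    ka = jc(pn)
    if math.isnan(ks) or math.isnan(ka):
        status = "saturated"
        ratio = math.nan
    elif ks == 0.0:
        status = "ks_zero"
        ratio = math.inf if ka > 0 else math.nan
    else:
        status = "ok"
        ratio = ka / ks
    return KaKsResult(
        n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
        pn=pn, ps=ps, ka=ka, ks=ks, ratio=ratio, status=status,
    )


def kaks_pair(cds_a: str, cds_b: str) -> KaKsResult:
    """Convenience: protein-guided codon alignment followed by NG86."""
    return ng_kaks(*codon_align(cds_a, cds_b))


def ks_histogram(ks_values, bin_width: float = 0.01, max_ks: float = 2.0) -> pd.DataFrame:
    """Binned Ks counts. NaN values are dropped; values above ``max_ks``
    accumulate in the last bin."""
    ks = np.asarray([k for k in ks_values if np.isfinite(k)], dtype=float)
    edges = np.arange(0.0, max_ks + bin_width, bin_width)
    if ks.size == 0:
        return pd.DataFrame({"bin_start": edges[:-1], "count": 0})
    clipped = np.clip(ks, 0.0, max_ks - bin_width / 2)
    counts, _ = np.histogram(clipped, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "count": counts})


def fraction_below(ks_values, threshold: float) -> float:
    """Fraction of finite Ks values strictly below ``threshold`` (percent/100)."""
    ks = np.asarray([k for k in ks_values if np.isfinite(k)], dtype=float)
    if ks.size == 0:
        return math.nan
    return float(np.mean(ks < threshold))
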