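"""Telomeric repeat-array detection at chromosome ends.

The plant telomere repeat is the 7-mer TTTAGGG on the plus strand at the
3' end; its reverse complement CCCTAAA marks the 5' end. A terminal search
window is scanned for the maximal run of non-overlapping motif copies whose
overall purity (motif bases / run span) clears a threshold; one call per
chromosome end at most.
"""

from __future__ import annotations

import pandas as pd

from .models import GenomeSet, TelomereCall, revcomp
from .synth import TELOMERE_MOTIF


def _match_positions(seq: str, motif: str):
    """All (possibly overlapping) motif match start positions."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _nonoverlapping(positions, m: int):
    out = []
    last = -m
    for p in positions:
        if p >= last + m:
            out.append(p)
            last = p
    return out


def best_run(seq: str, motif: str, min_purity: float):
    """Maximal run of motif copies with purity >= min_purity.

    Returns (start, end, copies, purity) or None. Non-overlapping matches
    are compressed into perfectly tandem blocks; every purity-optimal run
    starts and ends on block boundaries (extending into an adjacent perfect
    block can only raise both copy count and purity), so an exhaustive
    search over block ranges is equivalent to one over match ranges.
    """
    m = len(motif)
    pos = _nonoverlapping(_match_positions(seq, motif), m)
    if not pos:
        return None
    blocks = []  # (start, n_copies)
    bs, n = pos[0], 1
    for prev, cur in zip(pos, pos[1:]):
        if cur == prev + m:
            n += 1
        else:
            blocks.append((bs, n))
            bs, n = cur, 1
    blocks.append((bs, n))

    best = None
    copies_cum = [0]
    for _, bn in blocks:
        copies_cum.append(copies_cum[-1] + bn)
    for i in range(len(blocks)):
        for j in range(i, len(blocks)):
            copies = copies_cum[j + 1] - copies_cum[i]
            start = blocks[i][0]
            end = blocks[j][0] + blocks[j][1] * m
            purity = copies * m / (end - start)
            if purity < min_purity:
                continue
            if best is None or copies > best[2] or (
                    copies == best[2] and start < best[0]):
                best = (start, end, copies, purity)
    return best


def scan_telomeres(genome: GenomeSet, motif: str = TELOMERE_MOTIF,
                   window: int = 150_000, min_copies: int = 10,
                   min_purity: float = 0.8):
    """Scan both ends of every chromosome for telomeric arrays.

    The reverse-complement motif is used at the 5' end. At most one call per
    end: the maximal qualifying run inside the terminal window.
    """
    if len(motif) != 7:
        raise ValueError("telomere motif must be 7 bp")
    if window < len(motif):
        raise ValueError("window shorter than the motif")
    motif = motif.upper()
    rc = revcomp(motif)
    calls = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        w = min(window, len(seq))
        run = best_run(seq[:w], rc, min_purity)
        if run and run[2] >= min_copies:
            s, e, c, p = run
            calls.append(TelomereCall(chrom, "five_prime", s, e, c, p))
        tail_off = len(seq) - w
        run = best_run(seq[tail_off:], motif, min_purity)
        if run and run[2] >= min_copies:
            s, e, c, p = run
            calls.append(TelomereCall(chrom, "three_prime",
                                      tail_off + s, tail_off + e, c, p))
    return calls


def telomere_census(calls, chromosomes=None) -> pd.DataFrame:
    """Per-chromosome end status plus the genome total.

    Status is "T2T" with both ends called, "one-ended" with one, "none"
    otherwise. The total equals the number of calls (<= 2 per chromosome).
    """
    by_chrom: dict[str, set] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, set()).add(c.end)
    if chromosomes is None:
        chromosomes = sorted(by_chrom)
    rows = []
    for chrom in chromosomes:
        ends = by_chrom.get(chrom, set())
        status = {2: "T2T", 1: "one-ended", 0: "none"}[len(ends)]
        rows.append({"chrom": chrom,
                     "five_prime": "five_prime" in ends,
                     "three_prime": "three_prime" in ends,
                     "n_ends": len(ends), "status": status})
    df = pd.DataFrame(rows, columns=["chrom", "five_prime", "three_prime",
                                     "n_ends", "status"])
    df.attrs["total"] = len(calls)
    return df


def calls_to_bed(calls):
    """BED rows with name TEL:<end>:<copies>."""
    return [(c.chrom, c.start, c.stop, f"TEL:{c.end}:{c.copy_number}")
            for c in calls]
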