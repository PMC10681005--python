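"""Pairwise-alignment helpers built on edlib (DNA) and Biopython (protein)."""

from __future__ import annotations

import re

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str):
    """Yield (length, op) pairs from an extended cigar string."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_stats(cigar: str):
    """(matches, mismatches, gap_openings, gap_bases) from an extended cigar."""
    matches = mismatches = gap_open = gap_bases = 0
    for n, op in parse_cigar(cigar):
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
        elif op in "ID":
            gap_open += 1
            gap_bases += n
        else:  # 'M' should not occur with edlib task="path"
            raise ValueError(f"ambiguous cigar op {op!r}; extended cigar required")
    return matches, mismatches, gap_open, gap_bases


def gap_compressed_identity(cigar: str) -> float:
    """matches / (matches + mismatches + gap openings)."""
    m, x, go, _ = cigar_stats(cigar)
    denom = m + x + go
    return m / denom if denom else 0.0


def global_align(a: str, b: str):
    """Global (Needleman-Wunsch, unit costs) DNA alignment.

    Returns (edit_distance, cigar).
    """
    r = edlib.align(a, b, mode="NW", task="path")
    return r["editDistance"], r["cigar"]


def global_identity(a: str, b: str) -> float:
    """Alignment-column identity of a global alignment: matches / columns."""
    if not a or not b:
        return 0.0
    _, cigar = global_align(a, b)
    cols = sum(n for n, _ in parse_cigar(cigar))
    m, _, _, _ = cigar_stats(cigar)
    return m / cols


def banded_identity(a: str, b: str, max_divergence: float = 0.5) -> float:
    """Global identity with a banded early-exit: distances above the band
    return 0.0 (treated as "no match"). Cheaper than a full NW for screening."""
    k = int(max_divergence * max(len(a), len(b))) + 1
    r = edlib.align(a, b, mode="NW", task="distance", k=k)
    if r["editDistance"] < 0:
        return 0.0
    return 1.0 - r["editDistance"] / max(len(a), len(b))


def infix_identity(query: str, target: str) -> float:
    """Best-infix (HW-mode) identity of ``query`` inside ``target``:
    1 - editDistance/len(query)."""
    if not query:
        return 0.0
    r = edlib.align(query, target, mode="HW", task="distance")
    return max(0.0, 1.0 - r["editDistance"] / len(query))


def coord_map_from_cigar(cigar: str, a_start: int, b_start: int):
    """Matched-position pairs (a_pos, b_pos) along an alignment path.

    Only '=' columns are emitted; the result supports piecewise-linear
    projection of coordinates from sequence A onto sequence B.
    """
    import numpy as np

    pa, pb = a_start, b_start
    pairs = []
    for n, op in parse_cigar(cigar):
        if op in "=X":
            if op == "=":
                pairs.append((pa, pb))
                pairs.append((pa + n - 1, pb + n - 1))
            pa += n
            pb += n
        elif op == "D":   # gap in query a (edlib: D consumes target)
            pb += n
        elif op == "I":   # gap in target b
            pa += n
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


_protein_aligner = None


def protein_aligner() -> Align.PairwiseAligner:
    """Shared global protein aligner: BLOSUM62, affine gaps (-11/-1)."""
    global _protein_aligner
    if _protein_aligner is None:
        al = Align.PairwiseAligner()
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11
        al.extend_gap_score = -1
        al.mode = "global"
        # do not penalize terminal gaps more than internal ones
        _protein_aligner = al
    return _protein_aligner


def protein_identity(a: str, b: str) -> float:
    """Edit-distance protein identity (banded screen for homolog search)."""
    if not a or not b:
        return 0.0
    r = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - r["editDistance"] / max(len(a), len(b))
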