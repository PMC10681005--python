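"""Core record types shared across the toolkit.

All genomic coordinates are 0-based half-open on the plus strand unless a
serializer notes otherwise (GFF3 is written 1-based closed, BED 0-based
half-open, CX reports 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np


class GenomeSet(dict):
    """Named chromosome sequences: a ``dict`` of name -> upper-case string.

    Kept as a thin dict subclass so callers can build one from any mapping;
    helper constructors normalize case.
    """

    @classmethod
    def from_sequences(cls, sequences: dict) -> "GenomeSet":
        return cls({name: str(seq).upper() for name, seq in sequences.items()})

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.values())


@dataclass
class GeneModel:
    """A protein-coding gene with a single-mRNA CDS.

    ``cds_parts`` are 0-based half-open genomic intervals in transcription
    order; for minus-strand genes the spliced CDS is reverse-complemented.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds_parts: list = field(default_factory=list)

    def __post_init__(self):
        if not self.cds_parts:
            self.cds_parts = [(self.start, self.end)]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def cds_sequence(self, genome: GenomeSet) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in sorted(self.cds_parts))
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


@dataclass
class TEAnnotation:
    chrom: str
    start: int
    end: int
    family: str  # "Gypsy" | "Copia" | "other"


@dataclass
class TelomereCall:
    chrom: str
    end: str  # "five_prime" | "three_prime"
    start: int
    stop: int
    copy_number: int
    purity: float

    @property
    def interval(self):
        return (self.start, self.stop)


@dataclass
class TandemArray:
    """A maximal tandem-repeat interval with its repeat period."""

    chrom: str
    start: int
    end: int
    period: int
    n_copies: int
    identity: float
    monomers: list = field(default_factory=list)


@dataclass
class MonomerCluster:
    members: list
    consensus: str
    genome_copies: int

    @property
    def period(self) -> int:
        return len(self.consensus)


@dataclass
class CentromereCall:
    chrom: str
    start: int
    end: int
    monomer_density: float
    gene_density: float = float("nan")   # genes per Mb
    te_gypsy_fraction: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SDRecord:
    """A segmental-duplication call: two intervals plus alignment stats.

    ``identity`` is gap-compressed: matches / (matches + mismatches + gap
    openings). ``coord_map`` (optional) holds matched (pos_a, pos_b) anchor
    points from the alignment path, used to project gene coordinates from
    interval_a onto interval_b.
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float
    length: int
    strand: str = "+"
    coord_map: Optional[np.ndarray] = None

    @property
    def kind(self) -> str:
        return "intra" if self.chrom_a == self.chrom_b else "inter"

    @property
    def interval_a(self):
        return (self.chrom_a, self.start_a, self.end_a)

    @property
    def interval_b(self):
        return (self.chrom_b, self.start_b, self.end_b)

    def key(self):
        a = (self.chrom_a, self.start_a, self.end_a)
        b = (self.chrom_b, self.start_b, self.end_b)
        return (a, b) if a <= b else (b, a)


@dataclass
class SDGenePair:
    gene_a: str
    gene_b: str
    sd: SDRecord
    overlap_a: float
    overlap_b: float


@dataclass
class CollinearBlock:
    pairs: list            # ordered list of (gene_a, gene_b)
    chrom_a: str
    chrom_b: str
    orientation: str = "+"
    median_ks: float = float("nan")


@dataclass
class WgdPair:
    gene_a: str
    gene_b: str
    block_index: int
    ks: float = float("nan")
    ka: float = float("nan")
    ka_ks: float = float("nan")


@dataclass
class KaKsResult:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float
    ks: float
    ratio: float
    status: str  # "ok" | "ks_zero" | "saturated"


@dataclass
class PairSampleStatus:
    pair_id: str
    sample: str
    call: str        # "a_higher" | "b_higher" | "no_difference"
    log2fc: float
    q: float


@dataclass
class DivergenceCategory:
    pair_id: str
    category: str    # "AED" | "Sub" | "NoDiff"
    dominant_gene: Optional[str] = None


@dataclass
class GeneMethylation:
    gene_id: str
    context: str     # "CG" | "CHG" | "CHH"
    level: float     # weighted fraction, NaN when no covered cytosine
    n_cytosines: int = 0


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """min(overlap/|a|, overlap/|b|) for two (start, end) intervals."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def merge_intervals(intervals):
    """Merge overlapping/adjacent (start, end) intervals; returns sorted list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def to_dict(obj):
    """dataclass -> plain dict with numpy arrays dropped (for JSON bundles)."""
    d = asdict(obj)
    return {k: v for k, v in d.items() if not isinstance(v, np.ndarray)}
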