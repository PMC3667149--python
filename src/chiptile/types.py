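"""Core in-memory containers shared across the pipeline.

All internal coordinates are 0-based, half-open (BED-like). Conversions to
1-based inclusive conventions (GFF, fixedStep WIG) happen only inside the
format readers/writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT letters map to N-preserving complements."""
    return seq.translate(COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes A=0,C=1,G=2,T=3; any other letter -> 4.

    Code 4 marks positions ineligible for motif matching and excluded from
    base-composition statistics.
    """
    arr = np.full(len(seq), 4, dtype=np.uint8)
    up = seq.upper()
    for base, code in BASE_INDEX.items():
        arr[np.frombuffer(up.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"interval end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand symbol: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """Stranded gene with transcript bounds, exons and CDS bounds.

    ``exons`` are 0-based half-open (start, end) pairs inside
    [tx_start, tx_end); ``cds_start``/``cds_end`` bound the coding region.
    TSS/TES follow strand orientation: the TSS of a minus-strand gene is its
    tx_end coordinate.
    """

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -: {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise ValueError("tx_end must exceed tx_start")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError("exon outside transcript bounds")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError("CDS outside transcript bounds")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass
class ProbeTrack:
    """Sorted tiling-array probes on one chromosome with log2 enrichment ratios."""

    chrom: str
    positions: np.ndarray  # probe start coordinates, strictly increasing
    ratios: np.ndarray  # log2(ChIP/input) per probe
    spacing: int  # nominal probe spacing in bp

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ratios = np.asarray(self.ratios, dtype=np.float64)
        if self.positions.shape != self.ratios.shape:
            raise ValueError("positions and ratios must have equal length")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")
        if self.spacing < 1:
            raise ValueError("probe spacing must be >= 1")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class Peak:
    """A called enriched region.

    ``score`` is the highest cutoff-ladder percentage at which any sub-region
    of the peak qualifies; ``n_probes`` counts probes above that cutoff inside
    the peak.
    """

    interval: GenomicInterval
    score: float
    n_probes: int
    mean_ratio: float
    fdr: float = float("nan")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PWM:
    """Position weight matrix: 4 x width count matrix (rows A,C,G,T)."""

    id: str
    counts: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if np.any(self.counts.sum(axis=0) + 4 * self.pseudocount <= 0):
            raise ValueError("every column sum must be positive after pseudocounts")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def frequencies(self, pseudocount: float | None = None) -> np.ndarray:
        """Column-normalized base frequencies with additive pseudocounts."""
        pc = self.pseudocount if pseudocount is None else pseudocount
        padded = self.counts + pc
        return padded / padded.sum(axis=0, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            id=self.id + "_rc",
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass
class MotifModel:
    """Result of Gibbs motif discovery: PWM, site assignments, and score."""

    pwm: PWM
    sites: list[tuple[int, int, str]]  # (sequence index, offset, strand)
    score: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.background = np.asarray(self.background, dtype=np.float64)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if not np.isfinite(self.score):
            raise ValueError("motif score must be finite")
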