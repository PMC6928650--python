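"""Core domain types for SVA retrotransposon distribution analysis.

Coordinates are 0-based half-open internally (BED convention).  Locus
strings written for humans ("chr19:20,000,001-24,000,000") are 1-based
inclusive, matching the convention of genome browsers and the primary
literature on SVA loci.

SVA (SINE-VNTR-Alu) elements fall into seven subfamilies ordered by
evolutionary age: A, B and C are shared across multiple primate species
(the "old" class), while D, E, F and F1 are restricted to higher
primates or are human-specific (the "young" class).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

SUBFAMILIES: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "F1")
OLD_SUBFAMILIES: frozenset[str] = frozenset({"A", "B", "C"})
YOUNG_SUBFAMILIES: frozenset[str] = frozenset({"D", "E", "F", "F1"})


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "."


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap under half-open semantics (abutting spans do not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True, slots=True)
class SvaElement:
    """A single SVA annotation: interval plus subfamily and provenance.

    The age class is derived from the subfamily, never stored: old for
    A-C, young for D-F1.
    """

    interval: GenomicInterval
    subfamily: str
    source: str = "reference"  # "reference" | "rip"
    raw_id: str = ""

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown SVA subfamily {self.subfamily!r}")
        if self.source not in ("reference", "rip"):
            raise ValueError(f"source must be 'reference' or 'rip', got {self.source!r}")

    @property
    def age_class(self) -> str:
        return "old" if self.subfamily in OLD_SUBFAMILIES else "young"


@dataclass(frozen=True, slots=True)
class TranscriptModel:
    """A transcript span with its identifiers."""

    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def symbol(self) -> str:
        """Gene symbol, falling back to gene_id when no symbol is annotated."""
        return self.gene_symbol or self.gene_id


# Six subfamilies with published ChIP-exo enrichment statistics (no F1 column
# exists in the source data set).
ZFP_SUBFAMILIES: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")


@dataclass(slots=True)
class ZfpRecord:
    """One zinc-finger protein with per-SVA-subfamily binding enrichment.

    Enrichment p-values are stored as log10 values so that extreme
    significances (down to 1e-320 in the published ChIP-exo data) survive
    without floating-point underflow.  p = 1 maps to 0.0.
    """

    protein: str
    interval: GenomicInterval
    log10_pvalues: dict[str, float]
    in_dense_locus: bool | None = None
    significant: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ZFP_SUBFAMILIES) - set(self.log10_pvalues)
        if missing:
            raise ValueError(f"{self.protein}: missing p-value columns {sorted(missing)}")
        bad = {k: v for k, v in self.log10_pvalues.items() if v > 1e-9}
        if bad:
            raise ValueError(f"{self.protein}: log10 p-values must be <= 0, got {bad}")


_LOCUS_RE = re.compile(
    r"^\s*(?P<chrom>[\w.]+)\s*:\s*(?P<start>[\d,]+)\s*[-–—]\s*(?P<end>[\d,]+)\s*$"
)


def parse_locus_string(text: str) -> GenomicInterval:
    """Parse a browser-style locus string into a half-open interval.

    The string is read as 1-based inclusive ("chr19:20,000,001-24,000,000"
    means the 4 Mb window span [20_000_000, 24_000_000) in 0-based
    half-open coordinates).  Thousands separators and en-dashes are
    accepted.
    """
    m = _LOCUS_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse locus string {text!r}")
    start_1 = int(m.group("start").replace(",", ""))
    end_1 = int(m.group("end").replace(",", ""))
    if start_1 < 1 or end_1 < start_1:
        raise ValueError(f"invalid locus coordinates in {text!r}")
    return GenomicInterval(m.group("chrom"), start_1 - 1, end_1)


def format_locus_string(interval: GenomicInterval, thousands: bool = True) -> str:
    """Render a half-open interval as a 1-based inclusive locus string."""
    fmt = "{:,}" if thousands else "{}"
    return (
        f"{interval.chrom}:{fmt.format(interval.start + 1)}"
        f"-{fmt.format(interval.end)}"
    )


def snap_to_windows(interval: GenomicInterval, window_size: int) -> GenomicInterval:
    """Expand an interval outward to the enclosing window-grid boundaries."""
    start = (interval.start // window_size) * window_size
    end = -(-interval.end // window_size) * window_size
    return GenomicInterval(interval.chrom, start, end, interval.strand)
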