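"""Locus characterisation and subfamily-composition comparison.

Given a window-aligned locus, this module counts its transcripts and
distinct genes, classifies genes as zinc-finger genes by symbol
pattern, and reports SVA-per-transcript and SVA-per-gene ratios.  The
subfamily composition of a locus (percent share of each SVA subfamily
A-F1) is compared against the genome-wide composition as fold changes,
the framing used to show e.g. the depletion of the oldest subfamilies
and the strong over-representation of SVA E at zinc-finger gene
clusters.

Zinc-finger classification is by gene-symbol regex (ZNF*, ZKSCAN*,
ZSCAN*, ZIK*, ZFP* by default): no annotation source encodes
"zinc-finger gene" directly, and KRAB-domain status in particular is a
protein-domain property, so it is only accepted as an explicit
user-supplied gene list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    OLD_SUBFAMILIES,
    SUBFAMILIES,
    GenomicInterval,
    Strand,
    SvaElement,
    TranscriptModel,
)

DEFAULT_ZNF_INCLUDE: tuple[str, ...] = (
    r"^ZNF\d",
    r"^ZKSCAN\d",
    r"^ZSCAN\d",
    r"^ZIK\d",
    r"^ZFP\d",
)


def round2(x: float) -> float:
    """Round half away from zero to 2 decimal places (printed-value convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ZnfPatterns:
    """Ordered include/exclude regex lists for zinc-finger gene symbols."""

    include: tuple[str, ...] = DEFAULT_ZNF_INCLUDE
    exclude: tuple[str, ...] = ()


def classify_znf(gene_symbol: str, patterns: ZnfPatterns | None = None) -> bool:
    """Classify a gene symbol as a zinc-finger gene (case-insensitive).

    An exclude match vetoes; otherwise any include match classifies the
    symbol as zinc-finger.
    """
    if not gene_symbol:
        raise ValueError("gene_symbol must be non-empty")
    patterns = patterns or ZnfPatterns()
    for pat in patterns.exclude:
        if re.search(pat, gene_symbol, re.IGNORECASE):
            return False
    return any(re.search(pat, gene_symbol, re.IGNORECASE) for pat in patterns.include)


@dataclass(frozen=True)
class LocusSummary:
    """Gene/transcript/SVA census of one window-aligned locus.

    Ratios and percentages are rounded to 2 decimal places; they are
    NaN when their denominator is zero.  ``n_krab_znf`` is None unless
    a KRAB gene list was supplied.
    """

    interval: GenomicInterval
    n_genes: int
    n_transcripts: int
    n_znf_genes: int
    pct_znf: float
    sva_counts: dict[str, int]
    n_sva_total: int
    transcripts_per_sva: float
    genes_per_sva: float
    n_krab_znf: int | None = None


def _starts_in(interval: GenomicInterval, start: int, chrom: str) -> bool:
    return interval.contains_point(chrom, start)


def summarize_locus(
    interval: GenomicInterval,
    transcripts: Sequence[TranscriptModel],
    elements: Sequence[SvaElement],
    znf_patterns: ZnfPatterns | None = None,
    krab_list: Iterable[str] | None = None,
) -> LocusSummary:
    """Characterise a locus: genes, transcripts, zinc-finger fraction, SVA ratios.

    Membership uses the same start-coordinate rule as window counting,
    so locus totals equal sums of the window table over the locus
    windows.  Genes are distinct gene_ids among member transcripts; a
    gene is zinc-finger when its symbol matches ``znf_patterns``.
    """
    member_tx = [
        t for t in transcripts if _starts_in(interval, t.interval.start, t.interval.chrom)
    ]
    gene_symbols: dict[str, str] = {}
    for t in member_tx:
        gene_symbols.setdefault(t.gene_id, t.symbol)

    znf_genes = {g for g, sym in gene_symbols.items() if classify_znf(sym, znf_patterns)}
    n_genes = len(gene_symbols)
    n_tx = len(member_tx)

    sva_counts = {s: 0 for s in SUBFAMILIES}
    for el in elements:
        if _starts_in(interval, el.interval.start, el.interval.chrom):
            sva_counts[el.subfamily] += 1
    n_sva = sum(sva_counts.values())

    n_krab = None
    if krab_list is not None:
        krab = {k.upper() for k in krab_list}
        n_krab = sum(
            1 for g in znf_genes if gene_symbols[g].upper() in krab or g.upper() in krab
        )

    return LocusSummary(
        interval=interval,
        n_genes=n_genes,
        n_transcripts=n_tx,
        n_znf_genes=len(znf_genes),
        pct_znf=round2(100 * len(znf_genes) / n_genes) if n_genes else float("nan"),
        sva_counts=sva_counts,
        n_sva_total=n_sva,
        transcripts_per_sva=round2(n_tx / n_sva) if n_sva else float("nan"),
        genes_per_sva=round2(n_genes / n_sva) if n_sva else float("nan"),
        n_krab_znf=n_krab,
    )


@dataclass(frozen=True)
class CompositionComparison:
    """Per-subfamily genome vs locus percent shares and fold changes.

    Keys are the seven subfamilies plus the age-class aggregates "old"
    (A-C) and "young" (D-F1).  ``fold_change`` is locus share divided
    by genome share, 2 decimal places; 0.00 when the subfamily is
    absent from the locus, NaN when its genome share is zero.
    """

    genome_share: dict[str, float]
    locus_share: dict[str, float]
    fold_change: dict[str, float]


def subfamily_counts(elements: Iterable[SvaElement]) -> dict[str, int]:
    counts = {s: 0 for s in SUBFAMILIES}
    for el in elements:
        counts[el.subfamily] += 1
    return counts


def _shares(counts: Mapping[str, float]) -> dict[str, float]:
    total = sum(counts.get(s, 0) for s in SUBFAMILIES)
    if total == 0:
        raise ValueError("element set is empty")
    shares = {s: 100.0 * counts.get(s, 0) / total for s in SUBFAMILIES}
    shares["old"] = sum(shares[s] for s in OLD_SUBFAMILIES)
    shares["young"] = 100.0 - shares["old"]
    return shares


def composition_fold_change(
    locus_elements: Sequence[SvaElement], genome_elements: Sequence[SvaElement]
) -> CompositionComparison:
    """Compare a locus's subfamily composition against the genome-wide one."""
    return fold_change_from_counts(
        subfamily_counts(locus_elements), subfamily_counts(genome_elements)
    )


def fold_change_from_counts(
    locus_counts: Mapping[str, float], genome_counts: Mapping[str, float]
) -> CompositionComparison:
    """Fold changes from raw per-subfamily counts (locus and genome)."""
    return fold_change_from_shares(locus_counts, _shares(genome_counts))


def fold_change_from_shares(
    locus_counts: Mapping[str, float], genome_share: Mapping[str, float]
) -> CompositionComparison:
    """Fold changes from locus counts against a published genome share vector.

    ``genome_share`` maps subfamilies to percent shares (aggregates
    "old"/"young" are derived when absent).
    """
    locus_share = _shares(locus_counts)
    gshare = dict(genome_share)
    if "old" not in gshare:
        gshare["old"] = sum(gshare[s] for s in OLD_SUBFAMILIES)
    if "young" not in gshare:
        gshare["young"] = 100.0 - gshare["old"]
    fold: dict[str, float] = {}
    for key in list(SUBFAMILIES) + ["old", "young"]:
        if gshare.get(key, 0.0) == 0.0:
            fold[key] = float("nan")
        elif locus_share[key] == 0.0:
            fold[key] = 0.0
        else:
            fold[key] = round2(locus_share[key] / gshare[key])
    return CompositionComparison(
        genome_share={k: round2(v) for k, v in gshare.items()},
        locus_share={k: round2(v) for k, v in locus_share.items()},
        fold_change=fold,
    )


@dataclass(frozen=True)
class ProximityAnnotation:
    """An element's positional relation to the nearest gene.

    relation is within_gene, upstream, downstream, intergenic, or
    intergenic_unoriented (nearest transcript has unknown strand).
    distance_bp is 0 within genes, else the gap to the nearer boundary
    of the nearest transcript.
    """

    element: SvaElement
    relation: str
    distance_bp: int
    nearest_gene: str


def annotate_proximity(
    elements: Sequence[SvaElement],
    transcripts: Sequence[TranscriptModel],
    upstream_window: int = 10_000,
) -> tuple[list[ProximityAnnotation], float]:
    """Relate each element to the nearest transcript and compute the genic fraction.

    An element overlapping any transcript span is within_gene.
    Otherwise the nearest transcript (by gap to its nearer boundary) is
    found; when the gap is at most ``upstream_window`` the relation is
    upstream or downstream of that transcript per its strand, else
    intergenic.  genic_fraction is the share of elements within_gene or
    upstream within the window — the quantity behind the observation
    that ~60% of SVAs sit in genes or within 10 kb upstream.
    """
    trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        trees.setdefault(t.interval.chrom, IntervalTree()).addi(
            t.interval.start, t.interval.end, t
        )
        by_chrom.setdefault(t.interval.chrom, []).append(t)

    # sorted boundary arrays for nearest-neighbour lookup
    sorted_by_start: dict[str, tuple[np.ndarray, list[TranscriptModel]]] = {}
    sorted_by_end: dict[str, tuple[np.ndarray, list[TranscriptModel]]] = {}
    for chrom, txs in by_chrom.items():
        s = sorted(txs, key=lambda t: t.interval.start)
        e = sorted(txs, key=lambda t: t.interval.end)
        sorted_by_start[chrom] = (np.array([t.interval.start for t in s]), s)
        sorted_by_end[chrom] = (np.array([t.interval.end for t in e]), e)

    annotations: list[ProximityAnnotation] = []
    n_genic = 0
    for el in elements:
        chrom = el.interval.chrom
        tree = trees.get(chrom)
        if tree is not None:
            hits = tree.overlap(el.interval.start, el.interval.end)
            if hits:
                nearest = min(hits, key=lambda h: (h.begin, h.end)).data
                annotations.append(
                    ProximityAnnotation(el, "within_gene", 0, nearest.gene_id)
                )
                n_genic += 1
                continue
        nearest_t, gap, side = _nearest_transcript(
            el, sorted_by_start.get(chrom), sorted_by_end.get(chrom)
        )
        if nearest_t is None:
            annotations.append(ProximityAnnotation(el, "intergenic", -1, ""))
            continue
        relation = _relation(nearest_t.interval.strand, side, gap, upstream_window)
        if relation == "upstream" and gap <= upstream_window:
            n_genic += 1
        annotations.append(ProximityAnnotation(el, relation, gap, nearest_t.gene_id))

    fraction = n_genic / len(elements) if elements else float("nan")
    return annotations, fraction


def _nearest_transcript(
    el: SvaElement,
    by_start: tuple[np.ndarray, list[TranscriptModel]] | None,
    by_end: tuple[np.ndarray, list[TranscriptModel]] | None,
) -> tuple[TranscriptModel | None, int, str]:
    """Nearest non-overlapping transcript: (transcript, gap bp, 'before'|'after').

    'before' means the element lies before the transcript start.
    """
    best: tuple[TranscriptModel | None, int, str] = (None, -1, "")
    if by_start is not None:
        starts, txs = by_start
        i = int(np.searchsorted(starts, el.interval.end))
        if i < len(starts):
            gap = int(starts[i] - el.interval.end)
            best = (txs[i], gap, "before")
    if by_end is not None:
        ends, txs = by_end
        i = int(np.searchsorted(ends, el.interval.start, side="right")) - 1
        if i >= 0:
            gap = int(el.interval.start - ends[i])
            if best[0] is None or gap < best[1]:
                best = (txs[i], gap, "after")
    return best


def _relation(strand: Strand, side: str, gap: int, upstream_window: int) -> str:
    if gap > upstream_window:
        return "intergenic"
    if strand == Strand.UNKNOWN:
        return "intergenic_unoriented"
    if side == "before":
        return "upstream" if strand == Strand.PLUS else "downstream"
    return "downstream" if strand == Strand.PLUS else "upstream"
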