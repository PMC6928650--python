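"""KRAB zinc-finger protein binding-enrichment filtering and cross-referencing.

Consumes a published ChIP-exo enrichment table (per-protein,
per-SVA-subfamily binding p-values; Imbeault et al. 2017 profiled 159
KRAB-ZFPs) and answers three questions: which proteins are
significantly enriched for binding at least one SVA subfamily, which
of those reside inside SVA-dense cluster calls, and whether every
old-subfamily (A-C) binder lies inside a dense locus.

All p-value arithmetic happens in log10 space: the published table
contains values as small as 1e-320, below the double-precision
underflow threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomicInterval, ZfpRecord, ZFP_SUBFAMILIES

OLD_ZFP_SUBFAMILIES = ("A", "B", "C")


@dataclass(frozen=True)
class ZfpEnrichmentReport:
    """Summary of significance filtering and dense-locus cross-referencing."""

    records: tuple[ZfpRecord, ...]
    n_significant: int
    n_in_dense: int
    pct_in_dense: float  # NaN when n_significant == 0
    old_binder_containment: bool
    violating_proteins: tuple[str, ...]


def filter_enriched(
    records: list[ZfpRecord], log10_alpha: float = -20.0
) -> list[ZfpRecord]:
    """Mark per-subfamily significance and keep proteins passing anywhere.

    A subfamily is significant for a protein when its log10 p-value is
    at or below ``log10_alpha`` (default -20, i.e. p <= 1e-20).  A
    protein is retained iff it is significant for at least one
    subfamily.  No multiple-testing correction is applied; the cutoff
    is already extreme relative to the 159 x 6 tests of the source
    screen.  Input records are not mutated.
    """
    kept: list[ZfpRecord] = []
    for rec in records:
        significance = {
            s: rec.log10_pvalues[s] <= log10_alpha for s in ZFP_SUBFAMILIES
        }
        if any(significance.values()):
            kept.append(
                ZfpRecord(
                    protein=rec.protein,
                    interval=rec.interval,
                    log10_pvalues=dict(rec.log10_pvalues),
                    significant=significance,
                )
            )
    return kept


def significant_subfamilies(record: ZfpRecord) -> set[str]:
    return {s for s, sig in record.significant.items() if sig}


def crossref_dense_loci(
    significant_records: list[ZfpRecord],
    dense_intervals: list[GenomicInterval],
) -> ZfpEnrichmentReport:
    """Flag significant proteins whose gene interval overlaps a dense locus.

    Overlap is any-overlap under half-open semantics (a protein exactly
    abutting a locus boundary does not overlap).  ``dense_intervals``
    can come from cluster calls or be given explicitly.
    """
    if not dense_intervals:
        raise ValueError("dense_intervals must be non-empty")
    flagged: list[ZfpRecord] = []
    for rec in significant_records:
        in_dense = any(rec.interval.overlaps(d) for d in dense_intervals)
        flagged.append(
            ZfpRecord(
                protein=rec.protein,
                interval=rec.interval,
                log10_pvalues=dict(rec.log10_pvalues),
                in_dense_locus=in_dense,
                significant=dict(rec.significant),
            )
        )
    n_sig = len(flagged)
    n_in = sum(1 for r in flagged if r.in_dense_locus)
    containment, violators = old_binder_containment(flagged)
    return ZfpEnrichmentReport(
        records=tuple(flagged),
        n_significant=n_sig,
        n_in_dense=n_in,
        pct_in_dense=100.0 * n_in / n_sig if n_sig else float("nan"),
        old_binder_containment=containment,
        violating_proteins=tuple(violators),
    )


def old_binder_containment(records: list[ZfpRecord]) -> tuple[bool, list[str]]:
    """Test whether every old-subfamily binder lies within a dense locus.

    True iff each protein significant for any of SVA A, B or C has
    ``in_dense_locus`` set.  Vacuously true for an empty record set.
    Returns the violating protein names alongside the verdict.
    """
    violators = [
        rec.protein
        for rec in records
        if any(rec.significant.get(s, False) for s in OLD_ZFP_SUBFAMILIES)
        and not rec.in_dense_locus
    ]
    return (not violators, violators)


def report_to_tsv(report: ZfpEnrichmentReport, path) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(f"sig_{s}" for s in ZFP_SUBFAMILIES)
        fh.write(f"protein\tchrom\tstart\tend\tin_dense_locus\t{cols}\n")
        for r in report.records:
            sigs = "\t".join(
                "Y" if r.significant.get(s, False) else "N" for s in ZFP_SUBFAMILIES
            )
            fh.write(
                f"{r.protein}\t{r.interval.chrom}\t{r.interval.start}\t"
                f"{r.interval.end}\t{'Y' if r.in_dense_locus else 'N'}\t{sigs}\n"
            )
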