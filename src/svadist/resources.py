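"""Loaders for the small published reference tables bundled with the package.

Three published inputs ship with the package: the Imbeault et al. (2017)
ChIP-exo SVA binding-enrichment table for the 15 KRAB-ZFPs passing the
1e-20 cutoff, the SVA-dense locus intervals called on the hg19 reference
SVA set, the per-subfamily SVA counts at the three 1 Mb zinc-finger loci
on chromosomes 4, 7 and 19, and the genome-wide hg19 SVA subfamily
composition (percent shares).
"""

from __future__ import annotations

from importlib import resources

from .annotation_io import read_zfp_table
from .core import GenomicInterval, ZfpRecord, parse_locus_string


def _data_path(name: str):
    return resources.files("svadist.data").joinpath(name)


def load_zfp_enrichment_table() -> list[ZfpRecord]:
    """The published 15-protein ChIP-exo SVA binding-enrichment table."""
    with resources.as_file(_data_path("imbeault_sva_zfp_enrichment.tsv")) as p:
        return read_zfp_table(p)


def load_dense_loci() -> list[GenomicInterval]:
    """SVA-dense locus intervals from the hg19 reference-set analysis.

    The chr7 locus spans two megabases (63-65 Mb): the zinc-finger gene
    cluster there extends into the megabase adjacent to the dense
    window, and the published dense-locus membership of ZNF736 requires
    the extended span.
    """
    loci: list[GenomicInterval] = []
    with resources.as_file(_data_path("sva_dense_loci.bed")) as p:
        with open(p) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) >= 3:
                    loci.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return loci


def load_znf_loci_subfamily_counts() -> dict[str, dict[str, int]]:
    """Published per-subfamily SVA counts at the three 1 Mb zinc-finger loci.

    Returns {locus string: {subfamily: count}}; locus strings are
    1-based inclusive.
    """
    out: dict[str, dict[str, int]] = {}
    with resources.as_file(_data_path("znf_loci_sva_subfamily_counts.tsv")) as p:
        with open(p) as fh:
            next(fh)
            for line in fh:
                locus, subfamily, count = line.rstrip("\n").split("\t")
                out.setdefault(locus, {})[subfamily] = int(count)
    return out


def load_znf_loci_intervals() -> list[GenomicInterval]:
    return [parse_locus_string(s) for s in load_znf_loci_subfamily_counts()]


def load_genome_subfamily_shares() -> dict[str, float]:
    """Genome-wide hg19 SVA subfamily composition as percent shares."""
    shares: dict[str, float] = {}
    with resources.as_file(_data_path("hg19_sva_subfamily_composition.tsv")) as p:
        with open(p) as fh:
            next(fh)
            for line in fh:
                subfamily, pct = line.rstrip("\n").split("\t")
                shares[subfamily] = float(pct)
    return shares
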