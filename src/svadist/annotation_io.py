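"""Readers and writers for element, transcript, RIP and ZFP annotation tables.

Supported input dialects:

* RepeatMasker — both the UCSC Table Browser dump (tab-separated, header
  row, 0-based ``genoStart``) and the native ``.out`` file (space-aligned,
  three header lines, 1-based begin coordinate).  The two are
  auto-detected by header sniffing.
* BED6 / BED12 — standard 0-based half-open BED.
* Flat TSV — header row naming the columns.

All coordinates are normalised to 0-based half-open on ingest.  ZFP
enrichment p-values are parsed into log10 space directly from their
textual mantissa/exponent so that values far below the double-precision
underflow threshold (the published table reaches 1.14e-320) are kept
exact rather than collapsing to 0 or -inf.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import (
    SUBFAMILIES,
    ZFP_SUBFAMILIES,
    GenomicInterval,
    Strand,
    SvaElement,
    TranscriptModel,
    ZfpRecord,
    parse_locus_string,
)

#: Default mapping from annotation name fields to SVA subfamily labels.
#: RepeatMasker emits "SVA_A" .. "SVA_F"; an "SVA_F1" label (or a bare
#: subfamily letter) is accepted for sets that carry explicit F1 calls.
DEFAULT_SUBFAMILY_MAP: dict[str, str] = {
    **{f"SVA_{s}": s for s in SUBFAMILIES},
    **{s: s for s in SUBFAMILIES},
}


class ParseError(ValueError):
    """Raised for malformed annotation files; message names the line."""


def _parse_strand(token: str) -> Strand:
    if token in ("+",):
        return Strand.PLUS
    if token in ("-", "C"):  # RepeatMasker uses "C" for the reverse strand
        return Strand.MINUS
    return Strand.UNKNOWN


def _int_field(token: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(token.replace(",", ""))
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed {what} field {token!r}") from None


def _make_interval(
    chrom: str, start: int, end: int, strand: Strand, path: str, lineno: int
) -> GenomicInterval:
    if start < 0 or start >= end:
        raise ParseError(
            f"{path}:{lineno}: invalid coordinates {chrom}:{start}-{end} "
            "(require 0 <= start < end)"
        )
    return GenomicInterval(chrom, start, end, strand)


# ---------------------------------------------------------------------------
# element reading


def _sniff_repeatmasker_dialect(lines: Sequence[str]) -> str:
    """Distinguish a UCSC table dump from a native .out file."""
    for line in lines[:5]:
        if "genoStart" in line or line.startswith("#bin") or "repName" in line:
            return "ucsc"
        if "SW" in line and ("perc" in line or "score" in line):
            return "native"
    # Native .out data lines are space-aligned; UCSC dumps are tab-separated.
    for line in lines:
        if line.strip() and not line.startswith("#"):
            return "ucsc" if "\t" in line else "native"
    return "ucsc"


def read_elements(
    path: str | Path,
    format: str = "bed6",
    subfamily_map: Mapping[str, str] | None = None,
    source: str = "reference",
) -> tuple[list[SvaElement], int]:
    """Read SVA elements from ``path``.

    Parameters
    ----------
    format
        One of ``repeatmasker_out``, ``bed6``, ``tsv``.
    subfamily_map
        Name-field -> subfamily mapping; defaults to the RepeatMasker
        labels ("SVA_A" -> "A", ...).  Records whose name does not map
        are skipped, not errored, because repeat annotation dumps carry
        every repeat class.
    source
        Provenance tag for the returned elements ("reference" or "rip").

    Returns
    -------
    (elements, n_skipped)
        Parsed elements and the count of records skipped for an
        unmappable name.
    """
    path = Path(path)
    smap = dict(DEFAULT_SUBFAMILY_MAP if subfamily_map is None else subfamily_map)
    if format == "bed6":
        return _read_elements_bed(path, smap, source)
    if format == "tsv":
        return _read_elements_tsv(path, smap, source)
    if format == "repeatmasker_out":
        return _read_elements_repeatmasker(path, smap, source)
    raise ValueError(f"unknown element format {format!r}")


def _read_elements_bed(
    path: Path, smap: Mapping[str, str], source: str
) -> tuple[list[SvaElement], int]:
    elements: list[SvaElement] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 4")
            name = fields[3]
            if name not in smap:
                skipped += 1
                continue
            start = _int_field(fields[1], str(path), lineno, "start")
            end = _int_field(fields[2], str(path), lineno, "end")
            strand = _parse_strand(fields[5]) if len(fields) >= 6 else Strand.UNKNOWN
            interval = _make_interval(fields[0], start, end, strand, str(path), lineno)
            elements.append(SvaElement(interval, smap[name], source=source))
    return elements, skipped


def _read_elements_tsv(
    path: Path, smap: Mapping[str, str], source: str
) -> tuple[list[SvaElement], int]:
    elements: list[SvaElement] = []
    skipped = 0
    with open(path) as fh:
        header_line = fh.readline()
        header = [h.strip().lower() for h in header_line.rstrip("\n").split("\t")]
        idx = {name: i for i, name in enumerate(header)}
        for required in ("chrom", "start", "end"):
            if required not in idx:
                raise ParseError(f"{path}:1: TSV header missing column {required!r}")
        name_col = next((c for c in ("subfamily", "name") if c in idx), None)
        if name_col is None:
            raise ParseError(f"{path}:1: TSV header needs a 'subfamily' or 'name' column")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name = fields[idx[name_col]]
            if name not in smap:
                skipped += 1
                continue
            start = _int_field(fields[idx["start"]], str(path), lineno, "start")
            end = _int_field(fields[idx["end"]], str(path), lineno, "end")
            strand = (
                _parse_strand(fields[idx["strand"]]) if "strand" in idx else Strand.UNKNOWN
            )
            raw_id = fields[idx["raw_id"]] if "raw_id" in idx and idx["raw_id"] < len(fields) else ""
            row_source = (
                fields[idx["source"]]
                if "source" in idx and idx["source"] < len(fields) and fields[idx["source"]]
                else source
            )
            interval = _make_interval(
                fields[idx["chrom"]], start, end, strand, str(path), lineno
            )
            elements.append(SvaElement(interval, smap[name], source=row_source, raw_id=raw_id))
    return elements, skipped


def _read_elements_repeatmasker(
    path: Path, smap: Mapping[str, str], source: str
) -> tuple[list[SvaElement], int]:
    with open(path) as fh:
        lines = fh.readlines()
    dialect = _sniff_repeatmasker_dialect(lines)
    elements: list[SvaElement] = []
    skipped = 0
    if dialect == "ucsc":
        header: list[str] | None = None
        for lineno, line in enumerate(lines, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if header is None:
                header = [h.lstrip("#").strip() for h in line.split("\t")]
                idx = {name: i for i, name in enumerate(header)}
                for required in ("genoName", "genoStart", "genoEnd", "repName"):
                    if required not in idx:
                        raise ParseError(
                            f"{path}:1: UCSC RepeatMasker dump missing column {required!r}"
                        )
                continue
            fields = line.split("\t")
            name = fields[idx["repName"]]
            if name not in smap:
                skipped += 1
                continue
            start = _int_field(fields[idx["genoStart"]], str(path), lineno, "genoStart")
            end = _int_field(fields[idx["genoEnd"]], str(path), lineno, "genoEnd")
            strand = (
                _parse_strand(fields[idx["strand"]]) if "strand" in idx else Strand.UNKNOWN
            )
            raw_id = fields[idx["id"]] if "id" in idx and idx["id"] < len(fields) else ""
            interval = _make_interval(
                fields[idx["genoName"]], start, end, strand, str(path), lineno
            )
            elements.append(SvaElement(interval, smap[name], source=source, raw_id=raw_id))
    else:
        # Native .out: 3 header lines, whitespace-aligned columns, 1-based begin.
        for lineno, line in enumerate(lines, 1):
            stripped = line.strip()
            if not stripped or lineno <= 3 and not stripped[0].isdigit():
                continue
            fields = stripped.split()
            if len(fields) < 11:
                raise ParseError(
                    f"{path}:{lineno}: RepeatMasker .out line has {len(fields)} fields, need >= 11"
                )
            name = fields[9]
            if name not in smap:
                skipped += 1
                continue
            begin_1 = _int_field(fields[5], str(path), lineno, "begin")
            end = _int_field(fields[6], str(path), lineno, "end")
            strand = _parse_strand(fields[8])
            raw_id = fields[14] if len(fields) >= 15 else ""
            interval = _make_interval(fields[4], begin_1 - 1, end, strand, str(path), lineno)
            elements.append(SvaElement(interval, smap[name], source=source, raw_id=raw_id))
    return elements, skipped


def read_rips(
    path: str | Path,
    format: str = "bed6",
    subfamily_map: Mapping[str, str] | None = None,
) -> tuple[list[SvaElement], int]:
    """Read a retrotransposon insertion polymorphism (RIP) site list.

    RIP lists are structurally identical to element lists; the elements
    are tagged ``source="rip"``.
    """
    return read_elements(path, format=format, subfamily_map=subfamily_map, source="rip")


# ---------------------------------------------------------------------------
# split-read / overlap correction


def merge_split_elements(
    elements: Iterable[SvaElement], max_gap: int = 5000
) -> list[SvaElement]:
    """Merge annotation rows that represent fragments of one element.

    Repeat annotation pipelines frequently split a single insertion into
    several rows (e.g. when a nested repeat interrupts it).  Two rules
    are applied per (chrom, subfamily, source) group:

    * rows sharing a non-empty ``raw_id`` are merged unconditionally;
    * rows with an empty ``raw_id`` are merged when they overlap or lie
      within ``max_gap`` bp of each other.

    The merged element spans min(start)..max(end).  Output count never
    exceeds input count and covered bases never decrease.  The operation
    is idempotent.
    """
    merged: list[SvaElement] = []
    by_group: dict[tuple[str, str, str], list[SvaElement]] = {}
    for el in elements:
        key = (el.interval.chrom, el.subfamily, el.source)
        by_group.setdefault(key, []).append(el)

    for (chrom, subfamily, source), group in by_group.items():
        with_id: dict[str, list[SvaElement]] = {}
        anonymous: list[SvaElement] = []
        for el in group:
            if el.raw_id:
                with_id.setdefault(el.raw_id, []).append(el)
            else:
                anonymous.append(el)
        for raw_id, frags in with_id.items():
            merged.append(_merge_fragments(frags, chrom, subfamily, source, raw_id))
        anonymous.sort(key=lambda e: e.interval.start)
        run: list[SvaElement] = []
        for el in anonymous:
            if run and el.interval.start <= run[-1].interval.end + max_gap:
                run.append(el)
            else:
                if run:
                    merged.append(_merge_fragments(run, chrom, subfamily, source, ""))
                run = [el]
        if run:
            merged.append(_merge_fragments(run, chrom, subfamily, source, ""))

    merged.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.subfamily))
    return merged


def _merge_fragments(
    frags: list[SvaElement], chrom: str, subfamily: str, source: str, raw_id: str
) -> SvaElement:
    if len(frags) == 1:
        return frags[0]
    strands = {f.interval.strand for f in frags}
    strand = strands.pop() if len(strands) == 1 else Strand.UNKNOWN
    interval = GenomicInterval(
        chrom,
        min(f.interval.start for f in frags),
        max(f.interval.end for f in frags),
        strand,
    )
    return SvaElement(interval, subfamily, source=source, raw_id=raw_id)


# ---------------------------------------------------------------------------
# transcripts


def read_transcripts(path: str | Path, format: str = "tsv") -> list[TranscriptModel]:
    """Read transcript models from a flat TSV or BED12 file.

    The flat TSV carries columns chrom, start, end, strand,
    transcript_id, gene_id, gene_symbol (header row, any order).  For
    BED12 the transcript span is chromStart-chromEnd; exon blocks are
    ignored, and the name field serves as both transcript and gene id.
    Duplicate transcript_ids are a validation error.
    """
    path = Path(path)
    if format == "tsv":
        transcripts = _read_transcripts_tsv(path)
    elif format == "bed12":
        transcripts = _read_transcripts_bed12(path)
    else:
        raise ValueError(f"unknown transcript format {format!r}")

    seen: dict[str, int] = {}
    for t in transcripts:
        seen[t.transcript_id] = seen.get(t.transcript_id, 0) + 1
    dups = sorted(tid for tid, n in seen.items() if n > 1)
    if dups:
        raise ParseError(f"{path}: duplicate transcript_id values: {', '.join(dups)}")
    return transcripts


def _read_transcripts_tsv(path: Path) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        header = [h.strip().lower() for h in fh.readline().rstrip("\n").split("\t")]
        idx = {name: i for i, name in enumerate(header)}
        for required in ("chrom", "start", "end", "transcript_id", "gene_id"):
            if required not in idx:
                raise ParseError(f"{path}:1: transcript TSV missing column {required!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            start = _int_field(fields[idx["start"]], str(path), lineno, "start")
            end = _int_field(fields[idx["end"]], str(path), lineno, "end")
            strand = (
                _parse_strand(fields[idx["strand"]]) if "strand" in idx else Strand.UNKNOWN
            )
            symbol = (
                fields[idx["gene_symbol"]]
                if "gene_symbol" in idx and idx["gene_symbol"] < len(fields)
                else ""
            )
            interval = _make_interval(
                fields[idx["chrom"]], start, end, strand, str(path), lineno
            )
            out.append(
                TranscriptModel(
                    interval,
                    transcript_id=fields[idx["transcript_id"]],
                    gene_id=fields[idx["gene_id"]],
                    gene_symbol=symbol,
                )
            )
    return out


def _read_transcripts_bed12(path: Path) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED12 line has {len(fields)} fields, need >= 6")
            start = _int_field(fields[1], str(path), lineno, "start")
            end = _int_field(fields[2], str(path), lineno, "end")
            interval = _make_interval(
                fields[0], start, end, _parse_strand(fields[5]), str(path), lineno
            )
            out.append(
                TranscriptModel(interval, transcript_id=fields[3], gene_id=fields[3])
            )
    return out


# ---------------------------------------------------------------------------
# ZFP enrichment table

_SCI_NOTATION_RE = re.compile(
    r"^\s*(?P<mantissa>\d+(?:\.\d+)?)\s*[x×*]\s*10\s*\^?\(?\s*(?P<exp>[−\-+]?\d+)\s*\)?\s*$"
)
_E_NOTATION_RE = re.compile(
    r"^\s*(?P<mantissa>\d+(?:\.\d+)?)\s*[eE]\s*(?P<exp>[−\-+]?\d+)\s*$"
)


def parse_pvalue_log10(text: str) -> float:
    """Parse a p-value string to its log10, without float underflow.

    Accepts plain decimals ("0.13", "1.00"), e-notation ("4.53e-89") and
    typeset scientific notation ("4.53 × 10^−89"), including the Unicode
    minus sign.  The mantissa and decimal exponent are combined in log
    space, so "1.14 × 10^-320" yields about -319.94 rather than -inf.
    """
    text = text.strip()
    for regex in (_SCI_NOTATION_RE, _E_NOTATION_RE):
        m = regex.match(text)
        if m:
            mantissa = float(m.group("mantissa"))
            if mantissa <= 0:
                raise ValueError(f"p-value mantissa must be positive in {text!r}")
            exp = int(m.group("exp").replace("−", "-"))
            return math.log10(mantissa) + exp
    try:
        p = float(text.replace("−", "-"))
    except ValueError:
        raise ValueError(f"cannot parse p-value {text!r}") from None
    if p <= 0 or p > 1:
        raise ValueError(f"p-value {text!r} outside (0, 1]")
    return math.log10(p)


def read_zfp_table(path: str | Path) -> list[ZfpRecord]:
    """Read a ZFP-vs-SVA binding-enrichment TSV.

    Expected columns (header row, case-insensitive): ``protein``,
    ``position`` (browser-style 1-based locus string), and one p-value
    column per subfamily A-F named ``sva_a`` .. ``sva_f``.  An optional
    ``sva_locus`` column (Y/N) is ignored on read; dense-locus status is
    assigned analytically downstream.
    """
    path = Path(path)
    records: list[ZfpRecord] = []
    with open(path) as fh:
        header = [h.strip().lower() for h in fh.readline().rstrip("\n").split("\t")]
        idx = {name: i for i, name in enumerate(header)}
        for required in ("protein", "position"):
            if required not in idx:
                raise ParseError(f"{path}:1: ZFP table missing column {required!r}")
        pcols = {}
        for s in ZFP_SUBFAMILIES:
            col = f"sva_{s.lower()}"
            if col not in idx:
                raise ParseError(f"{path}:1: ZFP table missing p-value column {col!r}")
            pcols[s] = idx[col]
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                interval = parse_locus_string(fields[idx["position"]])
                log10_pvalues = {
                    s: min(0.0, parse_pvalue_log10(fields[c])) for s, c in pcols.items()
                }
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(
                ZfpRecord(
                    protein=fields[idx["protein"]],
                    interval=interval,
                    log10_pvalues=log10_pvalues,
                )
            )
    return records


# ---------------------------------------------------------------------------
# chrom sizes and writers


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals from a BED3+ file (names/scores ignored)."""
    out: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 3")
            start = _int_field(fields[1], str(path), lineno, "start")
            end = _int_field(fields[2], str(path), lineno, "end")
            out.append(_make_interval(fields[0], start, end, Strand.UNKNOWN, str(path), lineno))
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC chrom.sizes file (chrom<TAB>length)."""
    sizes: dict[str, int] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            length = _int_field(fields[1], str(path), lineno, "length")
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: chromosome length must be > 0")
            sizes[fields[0]] = length
    return sizes


def write_elements_bed6(elements: Iterable[SvaElement], path: str | Path) -> None:
    """Write elements as BED6 (name = subfamily label)."""
    with open(path, "w") as fh:
        for el in sorted(elements, key=lambda e: (e.interval.chrom, e.interval.start)):
            fh.write(
                f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}\t"
                f"{el.subfamily}\t0\t{el.interval.strand.value}\n"
            )


def write_elements_tsv(elements: Iterable[SvaElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tsubfamily\tsource\traw_id\n")
        for el in elements:
            fh.write(
                f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}\t"
                f"{el.interval.strand.value}\t{el.subfamily}\t{el.source}\t{el.raw_id}\n"
            )


def write_transcripts_tsv(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\ttranscript_id\tgene_id\tgene_symbol\n")
        for t in transcripts:
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"{t.interval.strand.value}\t{t.transcript_id}\t{t.gene_id}\t{t.gene_symbol}\n"
            )
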