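"""End-to-end analysis pipeline: load annotations, count, correlate, call
clusters, characterise loci, compare compositions and cross-reference ZFPs.

The command-line interface (:mod:`svadist.cli`) is a thin wrapper over
:func:`run_full_analysis`.  Every output table starts with a header
comment carrying the tool version and a hash of the effective
configuration, so a result file is traceable to the run that made it;
the optional timestamp line can be suppressed for byte-identical reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .annotation_io import (
    read_chrom_sizes,
    read_elements,
    read_rips,
    read_transcripts,
    read_zfp_table,
)
from .core import parse_locus_string, snap_to_windows
from .distribution import (
    call_clusters,
    correlation_by_chromosome,
    correlations_to_tsv,
    clusters_to_bed,
    density_correlation,
    top_density_windows,
)
from .locus import ZnfPatterns, composition_fold_change, summarize_locus
from .windows import WindowGrid, apply_gap_mask, count_by_window
from .zfp import crossref_dense_loci, filter_enriched, report_to_tsv

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (CLI exit status 2)."""


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location for one analysis run."""

    chrom_sizes: str | None = None
    elements: str | None = None
    transcripts: str | None = None
    rips: str | None = None
    zfp_table: str | None = None
    gap_mask: str | None = None
    krab_list: str | None = None
    element_format: str = "bed6"
    transcript_format: str = "tsv"
    rip_format: str = "bed6"
    window_size: int = 1_000_000
    old_threshold: int = 4
    young_threshold: int = 6
    correlation_method: str = "pearson"
    znf_include: tuple[str, ...] = ()
    log10_alpha: float = -20.0
    merge_max_gap: int = 5000
    loci: tuple[str, ...] = ()  # user-named loci for composition comparison
    outdir: str = "svadist_out"
    seed: int = 0
    timestamp: bool = False

    def validate(self) -> None:
        if self.chrom_sizes is None:
            raise ConfigError("missing required field: chrom_sizes")
        if self.elements is None:
            raise ConfigError("missing required field: elements")
        if self.old_threshold < 1 or self.young_threshold < 1:
            raise ConfigError("thresholds must be >= 1")
        for name in ("chrom_sizes", "elements", "transcripts", "rips", "zfp_table",
                     "gap_mask", "krab_list"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name}: file not found: {path}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        # output location and timestamping do not affect the analysis
        payload.pop("outdir", None)
        payload.pop("timestamp", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    lines = [f"# svadist v{__version__} config={config.config_hash()}"]
    if config.timestamp:
        lines.append(f"# generated {datetime.now(timezone.utc).isoformat()}")
    return "\n".join(lines) + "\n"


def _write_with_header(path: Path, config: PipelineConfig, write_body) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    write_body(tmp)
    with open(tmp) as fh:
        body = fh.read()
    tmp.unlink()
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write(body)


def run_full_analysis(config: PipelineConfig) -> dict[str, Path]:
    """Run every applicable stage and write the report bundle.

    Produces, in order: window count table, correlation table, cluster
    calls, per-cluster locus summaries, composition comparisons for
    user-named loci, the ZFP enrichment report (when a table is given)
    and the RIP distribution analysis (when a RIP list is given).
    Returns a name -> path map of the written files.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    sizes = read_chrom_sizes(config.chrom_sizes)
    grid = WindowGrid(sizes, config.window_size)

    elements, skipped = read_elements(config.elements, format=config.element_format)
    if skipped:
        logger.warning("elements: skipped %d records with unmappable names", skipped)
    from .annotation_io import merge_split_elements

    elements = merge_split_elements(elements, max_gap=config.merge_max_gap)

    transcripts = (
        read_transcripts(config.transcripts, format=config.transcript_format)
        if config.transcripts
        else []
    )
    rips = []
    if config.rips:
        rips, rip_skipped = read_rips(config.rips, format=config.rip_format)
        if rip_skipped:
            logger.warning("rips: skipped %d records with unmappable names", rip_skipped)

    table = count_by_window(elements, transcripts, rips, grid)
    for cls, n in table.unplaced.items():
        if n:
            logger.warning("unplaced %s records (chromosome not in grid): %d", cls, n)
    if config.gap_mask:
        from .annotation_io import read_bed_intervals

        table = apply_gap_mask(table, read_bed_intervals(config.gap_mask))

    counts_path = outdir / "window_counts.tsv"
    _write_with_header(counts_path, config, table.to_tsv)
    outputs["window_counts"] = counts_path

    corr = correlation_by_chromosome(table, method=config.correlation_method)
    corr_path = outdir / "correlations.tsv"
    _write_with_header(corr_path, config, lambda p: correlations_to_tsv(corr, p))
    outputs["correlations"] = corr_path

    calls = call_clusters(table, config.old_threshold, config.young_threshold)
    clusters_path = outdir / "clusters.bed"
    _write_with_header(clusters_path, config, lambda p: clusters_to_bed(calls, p))
    outputs["clusters"] = clusters_path

    znf_patterns = ZnfPatterns(include=config.znf_include) if config.znf_include else None
    krab = None
    if config.krab_list:
        krab = [line.strip() for line in open(config.krab_list) if line.strip()]

    summaries_path = outdir / "cluster_locus_summaries.tsv"
    _write_with_header(
        summaries_path,
        config,
        lambda p: _write_locus_summaries(
            p, [c.interval for c in calls], transcripts, elements, znf_patterns, krab
        ),
    )
    outputs["cluster_locus_summaries"] = summaries_path

    if config.loci:
        comp_path = outdir / "composition.tsv"
        _write_with_header(
            comp_path,
            config,
            lambda p: _write_composition(p, config.loci, elements, config.window_size),
        )
        outputs["composition"] = comp_path

    if config.zfp_table:
        records = read_zfp_table(config.zfp_table)
        significant = filter_enriched(records, config.log10_alpha)
        dense = [c.interval for c in calls]
        if dense:
            report = crossref_dense_loci(significant, dense)
            zfp_path = outdir / "zfp_report.tsv"
            _write_with_header(zfp_path, config, lambda p: report_to_tsv(report, p))
            outputs["zfp_report"] = zfp_path
            summary = {
                "n_input": len(records),
                "n_significant": report.n_significant,
                "n_in_dense": report.n_in_dense,
                "pct_in_dense": None
                if report.n_significant == 0
                else round(report.pct_in_dense, 2),
                "old_binder_containment": report.old_binder_containment,
                "violating_proteins": list(report.violating_proteins),
            }
            json_path = outdir / "zfp_summary.json"
            with open(json_path, "w") as fh:
                fh.write(_header(config))
                json.dump(summary, fh, indent=2)
                fh.write("\n")
            outputs["zfp_summary"] = json_path
        else:
            logger.warning("no dense clusters called; skipping ZFP cross-reference")

    if config.rips:
        rip_path = outdir / "rip_analysis.tsv"
        _write_with_header(
            rip_path, config, lambda p: _write_rip_analysis(p, table, config)
        )
        outputs["rip_analysis"] = rip_path

    return outputs


def _write_locus_summaries(path, intervals, transcripts, elements, znf_patterns, krab):
    with open(path, "w") as fh:
        fh.write(
            "locus\tn_genes\tn_transcripts\tn_znf_genes\tpct_znf\tn_krab_znf\t"
            "n_sva_total\ttranscripts_per_sva\tgenes_per_sva\n"
        )
        for iv in intervals:
            s = summarize_locus(iv, transcripts, elements, znf_patterns, krab)
            locus = f"{iv.chrom}:{iv.start + 1}-{iv.end}"
            krab_txt = "." if s.n_krab_znf is None else str(s.n_krab_znf)
            fh.write(
                f"{locus}\t{s.n_genes}\t{s.n_transcripts}\t{s.n_znf_genes}\t"
                f"{s.pct_znf:.2f}\t{krab_txt}\t{s.n_sva_total}\t"
                f"{s.transcripts_per_sva:.2f}\t{s.genes_per_sva:.2f}\n"
            )


def _write_composition(path, loci, elements, window_size):
    with open(path, "w") as fh:
        fh.write("locus\tsubfamily\tgenome_share\tlocus_share\tfold_change\n")
        for locus_str in loci:
            interval = snap_to_windows(parse_locus_string(locus_str), window_size)
            locus_elements = [
                e
                for e in elements
                if interval.contains_point(e.interval.chrom, e.interval.start)
            ]
            if not locus_elements:
                logger.warning("locus %s contains no elements; skipped", locus_str)
                continue
            comp = composition_fold_change(locus_elements, elements)
            for key in list(comp.fold_change):
                fh.write(
                    f"{locus_str}\t{key}\t{comp.genome_share[key]:.2f}\t"
                    f"{comp.locus_share[key]:.2f}\t{comp.fold_change[key]:.2f}\n"
                )


def _write_rip_analysis(path, table, config):
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        res = density_correlation(
            table, x="n_transcripts", y="n_rips", method=config.correlation_method
        )
        r_txt = "NA" if not res.defined else f"{res.r:.6f}"
        fh.write(f"rip_transcript_correlation_r\t{r_txt}\n")
        fh.write(f"rip_correlation_n_windows\t{res.n_windows}\n")
        top = top_density_windows(table, "n_rips")
        for iv, count in top:
            fh.write(f"top_rip_window\t{iv.chrom}:{iv.start + 1}-{iv.end} ({count} RIPs)\n")
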