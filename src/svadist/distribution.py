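"""Density-distribution analysis over the window count table.

Three questions are answered here: how element density tracks
transcript density (per chromosome and genome-wide), where elements
cluster beyond age-class density thresholds, and which windows carry
the most insertions.

Cluster calling follows the density thresholds used for reference SVAs:
a window is old-dense at >= 4 elements of subfamilies A-C per Mb, and
young-dense at >= 6 elements of D-F1 per Mb.  Runs of consecutive
flagged windows are merged into one cluster call; a merged run
containing both old-dense and young-dense windows is classed "both" —
in the hg19 reference set this overlap occurs only at the 4 Mb
zinc-finger locus chr19:20-24 Mb.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core import GenomicInterval
from .windows import WindowCountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation between two count columns over a set of windows.

    ``r`` is NaN (undefined) when either series is constant or fewer
    than three windows are available.
    """

    scope: str
    n_windows: int
    r: float
    method: str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class ClusterCall:
    """A maximal run of consecutive threshold-passing windows."""

    interval: GenomicInterval
    cluster_class: str  # "old" | "young" | "both"
    chrom: str
    window_indices: tuple[int, ...]
    n_old: int
    n_young: int


def _scope_frame(
    table: WindowCountTable, scope: str, exclude_partial: bool, exclude_gaps: bool
) -> pd.DataFrame:
    df = table.df
    if scope != "genome":
        df = df[df["chrom"] == scope]
        if df.empty:
            raise ValueError(f"scope {scope!r} not present in the table")
    if exclude_partial:
        df = df[~df["is_partial"]]
    if exclude_gaps and "is_gap" in df.columns:
        df = df[~df["is_gap"]]
    return df


def density_correlation(
    table: WindowCountTable,
    x: str = "n_transcripts",
    y: str = "n_sva_total",
    scope: str = "genome",
    method: str = "pearson",
    exclude_partial: bool = False,
    exclude_gaps: bool = True,
) -> CorrelationResult:
    """Correlate two count columns across the scope's windows.

    Returns an undefined (NaN) result, with a logged warning, when a
    series is constant or fewer than 3 windows remain — degenerate
    density tables are an expected input, not an error.
    """
    df = _scope_frame(table, scope, exclude_partial, exclude_gaps)
    xs = df[x].to_numpy(dtype=float)
    ys = df[y].to_numpy(dtype=float)
    n = len(xs)
    if n < 3 or xs.std() == 0 or ys.std() == 0:
        logger.warning(
            "correlation undefined for scope=%s (n=%d, constant series or too few windows)",
            scope,
            n,
        )
        return CorrelationResult(scope=scope, n_windows=n, r=float("nan"), method=method)
    if method == "pearson":
        r = float(stats.pearsonr(xs, ys).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(xs, ys).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(scope=scope, n_windows=n, r=r, method=method)


def correlation_by_chromosome(
    table: WindowCountTable,
    x: str = "n_transcripts",
    y: str = "n_sva_total",
    method: str = "pearson",
    **kwargs,
) -> list[CorrelationResult]:
    """Per-chromosome correlations plus the genome-wide value (scope 'genome')."""
    scopes = list(dict.fromkeys(table.df["chrom"])) + ["genome"]
    return [
        density_correlation(table, x=x, y=y, scope=s, method=method, **kwargs)
        for s in scopes
    ]


def flag_windows(
    table: WindowCountTable, old_threshold: int = 4, young_threshold: int = 6
) -> pd.DataFrame:
    """Flag density-threshold-passing windows per age class.

    Returns the window frame with boolean ``old_hit`` and ``young_hit``
    columns: old_hit iff n_sva_old >= old_threshold, young_hit iff
    n_sva_young >= young_threshold.
    """
    if old_threshold < 1 or young_threshold < 1:
        raise ValueError("thresholds must be >= 1")
    df = table.df.copy()
    df["old_hit"] = df["n_sva_old"] >= old_threshold
    df["young_hit"] = df["n_sva_young"] >= young_threshold
    return df


def merge_clusters(flags: pd.DataFrame, grid=None) -> list[ClusterCall]:
    """Merge consecutive flagged windows into maximal cluster calls.

    A call's class is "both" when the merged run contains at least one
    old-dense and at least one young-dense window; otherwise "old" or
    "young".  Calls never span a chromosome boundary, and the union of
    all call windows is exactly the set of flagged windows.
    """
    calls: list[ClusterCall] = []
    for chrom, sub in flags.groupby("chrom", sort=False):
        sub = sub.sort_values("window_index")
        run_rows: list[pd.Series] = []
        prev_index: int | None = None
        for _, row in sub.iterrows():
            hit = bool(row["old_hit"] or row["young_hit"])
            consecutive = prev_index is not None and row["window_index"] == prev_index + 1
            if hit and run_rows and consecutive:
                run_rows.append(row)
            elif hit:
                if run_rows:
                    calls.append(_make_call(chrom, run_rows))
                run_rows = [row]
            else:
                if run_rows:
                    calls.append(_make_call(chrom, run_rows))
                run_rows = []
            prev_index = int(row["window_index"]) if hit else None
        if run_rows:
            calls.append(_make_call(chrom, run_rows))
    calls.sort(key=lambda c: (c.chrom, c.window_indices[0]))
    return calls


def _make_call(chrom: str, rows: list[pd.Series]) -> ClusterCall:
    has_old = any(bool(r["old_hit"]) for r in rows)
    has_young = any(bool(r["young_hit"]) for r in rows)
    cls = "both" if (has_old and has_young) else ("old" if has_old else "young")
    interval = GenomicInterval(chrom, int(rows[0]["start"]), int(rows[-1]["end"]))
    return ClusterCall(
        interval=interval,
        cluster_class=cls,
        chrom=chrom,
        window_indices=tuple(int(r["window_index"]) for r in rows),
        n_old=int(sum(r["n_sva_old"] for r in rows)),
        n_young=int(sum(r["n_sva_young"] for r in rows)),
    )


def call_clusters(
    table: WindowCountTable, old_threshold: int = 4, young_threshold: int = 6
) -> list[ClusterCall]:
    """flag_windows + merge_clusters in one step."""
    return merge_clusters(flag_windows(table, old_threshold, young_threshold))


def top_density_windows(
    table: WindowCountTable, column: str = "n_rips"
) -> list[tuple[GenomicInterval, int]]:
    """All windows attaining the maximum count for ``column`` (ties kept).

    Sorted by (chrom, window index).  When the maximum is 0 every window
    is returned and a degenerate-maximum warning is logged.
    """
    df = table.df
    if df.empty:
        raise ValueError("window table is empty")
    max_count = int(df[column].max())
    if max_count == 0:
        logger.warning("top_density_windows: maximum of %s is 0 (degenerate)", column)
    hits = df[df[column] == max_count].sort_values(["chrom", "window_index"])
    return [
        (GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])), max_count)
        for _, r in hits.iterrows()
    ]


def clusters_to_bed(calls: list[ClusterCall], path) -> None:
    """Write cluster calls as BED (name = class, score = n_old + n_young)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.cluster_class}\t{c.n_old + c.n_young}\t.\n"
            )


def correlations_to_tsv(results: list[CorrelationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("scope\tn_windows\tr\tmethod\n")
        for res in results:
            r_txt = "NA" if not res.defined else f"{res.r:.6f}"
            fh.write(f"{res.scope}\t{res.n_windows}\t{r_txt}\t{res.method}\n")
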