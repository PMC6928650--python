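"""Fixed-width window partitioning and per-window density counting.

Each chromosome is cut into non-overlapping windows (1 Mb by default,
the scale at which retrotransposon density is conventionally reported).
Every element, transcript and RIP record is assigned to exactly one
window by its start coordinate (midpoint and any-overlap rules are
available as options), and counts are tallied per window and per SVA
subfamily and age class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    OLD_SUBFAMILIES,
    SUBFAMILIES,
    GenomicInterval,
    SvaElement,
    TranscriptModel,
)

SUBFAMILY_COLUMNS = [f"n_{s}" for s in SUBFAMILIES]
COUNT_COLUMNS = SUBFAMILY_COLUMNS + [
    "n_sva_old",
    "n_sva_young",
    "n_sva_total",
    "n_transcripts",
    "n_rips",
]


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping fixed-width partition of a set of chromosomes."""

    chrom_lengths: dict[str, int]
    window_size: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    def n_windows(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.window_size)

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.chrom_lengths)

    def window_interval(self, chrom: str, index: int) -> GenomicInterval:
        start = index * self.window_size
        end = min(start + self.window_size, self.chrom_lengths[chrom])
        return GenomicInterval(chrom, start, end)


def assign_window(
    interval: GenomicInterval, grid: WindowGrid, rule: str = "start"
) -> tuple[str, int]:
    """Assign an interval to a single window of the grid.

    rule="start" uses floor(start / window_size); rule="midpoint" uses
    the interval midpoint.  Raises KeyError when the chromosome is not
    in the grid (callers collect these as unplaced records).
    """
    if interval.chrom not in grid.chrom_lengths:
        raise KeyError(interval.chrom)
    if rule == "start":
        pos = interval.start
    elif rule == "midpoint":
        pos = (interval.start + interval.end) // 2
    else:
        raise ValueError(f"unknown assignment rule {rule!r}")
    index = min(pos // grid.window_size, grid.n_windows(interval.chrom) - 1)
    return interval.chrom, index


@dataclass
class WindowCountTable:
    """Per-window counts of SVA elements, transcripts and RIPs.

    ``df`` has one row per (chrom, window_index), zero-filled, with
    per-subfamily counts, age-class totals, transcript and RIP counts,
    and an ``is_partial`` flag for trailing windows shorter than the
    window size.  ``unplaced`` tallies records on chromosomes absent
    from the grid, per input class.
    """

    df: pd.DataFrame
    grid: WindowGrid
    unplaced: dict[str, int] = field(
        default_factory=lambda: {"elements": 0, "transcripts": 0, "rips": 0}
    )

    def window_label(self, chrom: str, index: int) -> str:
        iv = self.grid.window_interval(chrom, index)
        return f"{chrom}:{iv.start + 1:,}-{iv.end:,}"

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "window", [
            self.window_label(c, i) for c, i in zip(out["chrom"], out["window_index"])
        ])
        out.to_csv(path, sep="\t", index=False)


def _empty_table(grid: WindowGrid) -> pd.DataFrame:
    rows = []
    for chrom, length in grid.chrom_lengths.items():
        n = grid.n_windows(chrom)
        for i in range(n):
            start = i * grid.window_size
            end = min(start + grid.window_size, length)
            rows.append((chrom, i, start, end, end - start < grid.window_size))
    df = pd.DataFrame(rows, columns=["chrom", "window_index", "start", "end", "is_partial"])
    for col in COUNT_COLUMNS:
        df[col] = 0
    return df


def count_by_window(
    elements: list[SvaElement] | None,
    transcripts: list[TranscriptModel] | None,
    rips: list[SvaElement] | None,
    grid: WindowGrid,
    rule: str = "start",
) -> WindowCountTable:
    """Build the complete per-window count table.

    Every window of every chromosome appears (zero-filled).  Records on
    chromosomes missing from the grid are tallied in ``unplaced`` per
    input class rather than silently dropped.
    """
    df = _empty_table(grid)
    index_of = {
        (c, i): row for row, (c, i) in enumerate(zip(df["chrom"], df["window_index"]))
    }
    unplaced = {"elements": 0, "transcripts": 0, "rips": 0}

    counts = {col: np.zeros(len(df), dtype=np.int64) for col in COUNT_COLUMNS}

    for el in elements or []:
        try:
            key = assign_window(el.interval, grid, rule)
        except KeyError:
            unplaced["elements"] += 1
            continue
        row = index_of[key]
        counts[f"n_{el.subfamily}"][row] += 1
        age = "n_sva_old" if el.subfamily in OLD_SUBFAMILIES else "n_sva_young"
        counts[age][row] += 1
        counts["n_sva_total"][row] += 1

    for t in transcripts or []:
        try:
            key = assign_window(t.interval, grid, rule)
        except KeyError:
            unplaced["transcripts"] += 1
            continue
        counts["n_transcripts"][index_of[key]] += 1

    for rip in rips or []:
        try:
            key = assign_window(rip.interval, grid, rule)
        except KeyError:
            unplaced["rips"] += 1
            continue
        counts["n_rips"][index_of[key]] += 1

    for col, arr in counts.items():
        df[col] = arr
    return WindowCountTable(df=df, grid=grid, unplaced=unplaced)


def apply_gap_mask(
    table: WindowCountTable, gaps: list[GenomicInterval]
) -> WindowCountTable:
    """Flag windows whose span is entirely covered by assembly gaps.

    Adds an ``is_gap`` column.  Gapped windows are excluded from
    correlation analyses but retained for cluster calling (annotated).
    """
    df = table.df.copy()
    is_gap = np.zeros(len(df), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in gaps:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for chrom, spans in by_chrom.items():
        spans.sort()
        # merge gap spans, then test full coverage per window
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        mask_rows = df["chrom"] == chrom
        for row in df.index[mask_rows]:
            w_start, w_end = df.at[row, "start"], df.at[row, "end"]
            is_gap[row] = any(s <= w_start and e >= w_end for s, e in merged)
    df["is_gap"] = is_gap
    return WindowCountTable(df=df, grid=table.grid, unplaced=dict(table.unplaced))
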