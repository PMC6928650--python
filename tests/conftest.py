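import numpy as np
import pytest

from svadist.core import GenomicInterval, Strand, SvaElement, TranscriptModel
from svadist.windows import WindowGrid


@pytest.fixture
def grid3() -> WindowGrid:
    """A 3-chromosome grid with a trailing partial window on chrT3."""
    return WindowGrid(
        {"chrT1": 10_000_000, "chrT2": 7_000_000, "chrT3": 4_500_000},
        window_size=1_000_000,
    )


def random_elements(rng: np.random.Generator, grid: WindowGrid, n: int) -> list[SvaElement]:
    """Uniform random 2 kb elements across a grid's chromosomes."""
    from svadist.core import SUBFAMILIES

    chroms = sorted(grid.chrom_lengths)
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = grid.chrom_lengths[chrom]
        start = int(rng.integers(0, length - 1))
        end = min(start + 2000, length)
        subfam = SUBFAMILIES[int(rng.integers(0, len(SUBFAMILIES)))]
        out.append(SvaElement(GenomicInterval(chrom, start, end), subfam, raw_id=f"e{i}"))
    return out


def make_transcript(
    chrom: str,
    start: int,
    end: int,
    tid: str,
    gene_id: str | None = None,
    symbol: str = "",
    strand: Strand = Strand.PLUS,
) -> TranscriptModel:
    return TranscriptModel(
        GenomicInterval(chrom, start, end, strand),
        transcript_id=tid,
        gene_id=gene_id or tid,
        gene_symbol=symbol,
    )


def make_element(
    chrom: str, start: int, subfamily: str, length: int = 2000, raw_id: str = ""
) -> SvaElement:
    return SvaElement(GenomicInterval(chrom, start, start + length), subfamily, raw_id=raw_id)
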