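"""Genome description and fixed-width bin grids.

Copy-number profiles from shallow whole-genome sequencing are summarized on a
grid of fixed-width genomic bins (default 50 kb). All internal coordinates are
0-based half-open; SEG-file I/O converts from/to the 1-based inclusive dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BIN_SIZE = 50_000


@dataclass(frozen=True)
class GenomeSpec:
    """A genome as an ordered list of chromosomes with a bin size.

    Parameters
    ----------
    species_label:
        Free-text species tag carried through outputs (e.g. ``"mouse"``).
    chromosomes:
        Ordered ``(name, length_bp)`` pairs. Names must be unique and
        lengths positive.
    bin_size:
        Width of the tiling bins in bp (default 50 kb, the resolution used
        for shallow CNV-seq profiles).
    """

    species_label: str
    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class BinGrid:
    """Ordered, non-overlapping genomic bins shared by all samples.

    Bins tile each chromosome left to right at fixed width; the terminal bin
    of each chromosome is truncated to the chromosome length. ``chrom_slices``
    maps chromosome name to the slice of bin indices it occupies.
    """

    chroms: np.ndarray  # per-bin chromosome name
    starts: np.ndarray  # per-bin start, 0-based
    ends: np.ndarray  # per-bin end, half-open
    chrom_slices: dict[str, slice] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the bin containing position ``pos`` on ``chrom``."""
        sl = self.chrom_slices[chrom]
        idx = sl.start + int(np.searchsorted(self.ends[sl], pos, side="right"))
        if idx >= sl.stop:
            idx = sl.stop - 1
        return idx

    def overlapping_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of bins overlapping [start, end) on ``chrom`` by >= 1 bp."""
        if chrom not in self.chrom_slices:
            return np.array([], dtype=int)
        sl = self.chrom_slices[chrom]
        s, e = self.starts[sl], self.ends[sl]
        mask = (s < end) & (e > start)
        return np.nonzero(mask)[0] + sl.start


def make_bins(genome: GenomeSpec) -> BinGrid:
    """Tile a genome into a :class:`BinGrid` of ``genome.bin_size`` bins.

    Each chromosome of length L yields ceil(L / bin_size) bins; the last bin
    ends exactly at L.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    slices: dict[str, slice] = {}
    for name, length in genome.chromosomes:
        first = len(starts)
        edges = list(range(0, length, genome.bin_size)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
        slices[name] = slice(first, len(starts))
    return BinGrid(
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        chrom_slices=slices,
    )
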