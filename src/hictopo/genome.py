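"""Genomic bin frame shared by all matrices and tracks.

Every matrix, track and interval in this package lives on a single
:class:`GenomeBins` instance: an ordered set of chromosomes tiled by
fixed-width, 0-based half-open bins.  Bin ids are global (concatenated
across chromosomes in order), which is also how they appear in the
on-disk bins BED and bin-pair triplet files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeBins"]


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width bin tiling of a genome.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> chromosome length in bp, in genome order.
    bin_width
        Bin size in bp (default 10 kb).  The last bin of each chromosome may
        be shorter; bins tile each chromosome without gaps or overlap.
    """

    lengths: dict[str, int]
    bin_width: int = 10_000
    # derived, filled in __post_init__
    _n_bins: dict[str, int] = field(init=False, repr=False)
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_bins: dict[str, int] = {}
        offsets: dict[str, int] = {}
        off = 0
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            n = -(-length // self.bin_width)  # ceil
            n_bins[chrom] = n
            offsets[chrom] = off
            off += n
        object.__setattr__(self, "_n_bins", n_bins)
        object.__setattr__(self, "_offsets", offsets)

    # -- sizes ---------------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    @property
    def total_bins(self) -> int:
        return sum(self._n_bins.values())

    def offset(self, chrom: str) -> int:
        """Global bin id of this chromosome's first bin."""
        return self._offsets[chrom]

    # -- coordinate conversion ----------------------------------------
    def bin_of(self, chrom: str, pos: int) -> int:
        """Chromosome-local bin index containing position ``pos`` (0-based)."""
        if not 0 <= pos < self.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_width

    def bin_interval(self, chrom: str, i: int) -> tuple[int, int]:
        """Half-open [start, end) of local bin ``i``."""
        if not 0 <= i < self._n_bins[chrom]:
            raise ValueError(f"bin {i} outside {chrom}")
        start = i * self.bin_width
        return start, min(start + self.bin_width, self.lengths[chrom])

    def chrom_of_global(self, gid: int) -> tuple[str, int]:
        """(chromosome, local bin index) for a global bin id."""
        for chrom in self.lengths:
            off, n = self._offsets[chrom], self._n_bins[chrom]
            if off <= gid < off + n:
                return chrom, gid - off
        raise ValueError(f"global bin id {gid} out of range")

    def region_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Local bin indices overlapping half-open [start, end)."""
        if end <= start:
            raise ValueError("empty region")
        if start < 0 or end > self.lengths[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} exceeds chromosome")
        lo = start // self.bin_width
        hi = -(-end // self.bin_width)
        return np.arange(lo, min(hi, self._n_bins[chrom]))

    def same_frame(self, other: "GenomeBins") -> bool:
        return self.lengths == other.lengths and self.bin_width == other.bin_width
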