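"""Genome binning shared by contact maps and per-bin tracks.

Coordinates are 0-based half-open (BED convention); bin ``k`` of a chromosome
covers ``[k*bin_size, min((k+1)*bin_size, length))`` and the bin index of a
position is ``floor(pos / bin_size)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Binning:
    """Fixed-width tiling of a set of chromosomes.

    Parameters
    ----------
    chrom_names :
        Chromosome identifiers, in map order.
    chrom_lengths :
        Lengths in base pairs, parallel to ``chrom_names``.
    bin_size :
        Bin width in base pairs.
    """

    chrom_names: tuple
    chrom_lengths: tuple
    bin_size: int

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(l) for l in self.chrom_lengths))

    # -- derived quantities -------------------------------------------------
    def n_bins_of(self, chrom: str) -> int:
        length = self.chrom_lengths[self.chrom_names.index(chrom)]
        return -(-length // self.bin_size)  # ceil division

    @property
    def bins_per_chrom(self) -> tuple:
        return tuple(-(-l // self.bin_size) for l in self.chrom_lengths)

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom)

    @property
    def offsets(self) -> dict:
        """Global index of each chromosome's first bin."""
        out, acc = {}, 0
        for name, n in zip(self.chrom_names, self.bins_per_chrom):
            out[name] = acc
            acc += n
        return out

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + self.n_bins_of(chrom))

    def chrom_of_bins(self) -> np.ndarray:
        """Chromosome name for every global bin index."""
        return np.repeat(np.array(self.chrom_names, dtype=object), self.bins_per_chrom)

    def chrom_id_of_bins(self) -> np.ndarray:
        """Integer chromosome id for every global bin index."""
        return np.repeat(np.arange(len(self.chrom_names)), self.bins_per_chrom)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a genomic position."""
        length = self.chrom_lengths[self.chrom_names.index(chrom)]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (length {length})")
        return self.offsets[chrom] + pos // self.bin_size

    def bin_starts(self) -> np.ndarray:
        parts = [np.arange(n) * self.bin_size for n in self.bins_per_chrom]
        return np.concatenate(parts) if parts else np.array([], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Bin table with columns chrom, start, end."""
        chroms = self.chrom_of_bins()
        starts = self.bin_starts()
        lengths = np.repeat(np.array(self.chrom_lengths), self.bins_per_chrom)
        ends = np.minimum(starts + self.bin_size, lengths)
        return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})

    def same_grid(self, other: "Binning") -> bool:
        return (
            self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )
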