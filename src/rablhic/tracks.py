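"""Per-bin scalar tracks (cePC1, insulation, gene density, GC, TPM, ChIP)
on a shared binning, with bedGraph/BED round-tripping."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Binning


@dataclass
class GenomicTrack:
    """One scalar value per genomic bin; NaN marks missing bins."""

    binning: Binning
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.binning.n_bins,):
            raise ValueError(f"track needs {self.binning.n_bins} values, got {v.shape}")
        self.values = v

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.binning.chrom_slice(chrom)]

    def to_frame(self) -> pd.DataFrame:
        df = self.binning.to_frame()
        df["value"] = self.values
        return df

    def with_values(self, values: np.ndarray, name: str | None = None) -> "GenomicTrack":
        return GenomicTrack(self.binning, values, self.name if name is None else name)


def write_bedgraph(track: GenomicTrack, path: str) -> None:
    df = track.to_frame().dropna(subset=["value"])
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path: str, binning: Binning, name: str = "") -> GenomicTrack:
    """Read a bedGraph onto ``binning``; intervals must be bin-aligned."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#")
    values = np.full(binning.n_bins, np.nan)
    offsets = binning.offsets
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        idx = offsets[chrom] + (sub["start"].to_numpy() // binning.bin_size)
        values[idx] = sub["value"].to_numpy()
    return GenomicTrack(binning, values, name=name)


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name, score])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = cols[: df.shape[1]] + list(df.columns[6:])
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def regions_to_bin_mask(regions: pd.DataFrame, binning: Binning) -> np.ndarray:
    """Boolean mask of bins overlapping any region."""
    mask = np.zeros(binning.n_bins, dtype=bool)
    offsets = binning.offsets
    lengths = dict(zip(binning.chrom_names, binning.chrom_lengths))
    for _, row in regions.iterrows():
        chrom = row["chrom"]
        if chrom not in offsets:
            continue
        first = int(row["start"]) // binning.bin_size
        last = (min(int(row["end"]), lengths[chrom]) - 1) // binning.bin_size
        off = offsets[chrom]
        mask[off + first : off + last + 1] = True
    return mask
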