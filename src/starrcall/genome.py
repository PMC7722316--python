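"""Genome coordinate model, sliding-window binning, and interval file I/O.

All coordinates are 0-based half-open, matching BED. A genome is described
by a ``ChromSizes`` (ordered chromosome name -> length mapping); the unit of
counting and testing is a ``BinSet`` of fixed-length sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "BinSet",
    "make_bins",
    "nonoverlapping_subset",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome extents.

    Order is preserved as given (file order), never sorted, so that runs are
    reproducible regardless of chromosome naming scheme.
    """

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        items = dict(self.sizes)
        if len(items) != len(list(self.sizes)):
            raise ValueError("duplicate chromosome names")
        for name, length in items.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "sizes", items)

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __iter__(self):
        return iter(self.sizes)

    def items(self):
        return self.sizes.items()

    @property
    def names(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_length(self) -> int:
        return int(sum(self.sizes.values()))


@dataclass
class BinSet:
    """Sliding genomic windows of length ``l`` stepped by ``s``.

    ``frame`` holds one row per bin with columns ``chrom``, ``start``,
    ``end`` sorted by (chromosome order, start). Terminal windows truncated
    at the chromosome end are kept but flagged, so model training can
    exclude them while testing still covers the genome.
    """

    frame: pd.DataFrame
    l: int
    s: int
    chrom_sizes: ChromSizes = field(repr=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chrom(self) -> pd.Series:
        return self.frame["chrom"]

    @property
    def start(self) -> np.ndarray:
        return self.frame["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.frame["end"].to_numpy()

    @property
    def truncated(self) -> np.ndarray:
        """Boolean mask of bins shorter than the nominal window length."""
        return (self.end - self.start) < self.l

    def to_bed(self, path: str | Path) -> None:
        write_bed(self.frame, path)


def make_bins(chrom_sizes: ChromSizes, l: int = 500, s: int = 100) -> BinSet:
    """Tile each chromosome with sliding windows of length ``l``, step ``s``.

    Windows start at 0, s, 2s, ...; the first window whose end reaches the
    chromosome end is truncated there and closes the chromosome (further
    starts would only nest inside it).
    """
    if l <= 0 or s <= 0:
        raise ValueError(f"window length and step must be positive (got l={l}, s={s})")
    if s > l:
        raise ValueError(f"step larger than window (s={s} > l={l}) leaves gaps")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, length in chrom_sizes.items():
        start = 0
        while start < length:
            end = min(start + l, length)
            chroms.append(name)
            starts.append(start)
            ends.append(end)
            if end >= length:
                break
            start += s
    frame = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="object"),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
        }
    )
    return BinSet(frame=frame, l=l, s=s, chrom_sizes=chrom_sizes)


def nonoverlapping_subset(bins: BinSet) -> np.ndarray:
    """Mask selecting the disjoint tiling: bins whose start ≡ 0 (mod l).

    These are the bins used for model fitting, where each fragment center
    can land in exactly one window.
    """
    return (bins.start % bins.l) == 0


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    return ChromSizes(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_chrom_sizes(chrom_sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a frame with 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = _BED6_COLS[:ncol]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _BED6_COLS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)
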