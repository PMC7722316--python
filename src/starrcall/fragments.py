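"""Fragment-insert extraction from paired-end alignments and bin coverage.

The cloned insert, not the sequencing read, is the unit of signal in a
STARR-seq experiment: a properly paired read pair is reduced to its outer
span (leftmost start to rightmost end), and coverage is counted at the
insert *center*. Counting read 5' starts is kept as a comparison mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
import pysam

from .genome import BinSet, ChromSizes

__all__ = [
    "FragmentRecord",
    "ParseStats",
    "parse_fragments",
    "fragments_to_frame",
    "read_fragment_bed",
    "write_fragment_bed",
    "fragment_coverage",
    "read_start_coverage",
    "subsample_fragments",
    "span_depth",
    "center_depth",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_INSERT = 200
DEFAULT_MAX_INSERT = 1000


class FragmentRecord(NamedTuple):
    """A filtered paired-end insert.

    ``strand`` is the strand of the first-in-pair mate, i.e. the orientation
    of the insert as cloned. ``center`` is the floor of the midpoint.
    """

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def insert_size(self) -> int:
        return self.end - self.start


@dataclass
class ParseStats:
    """Counters for pairs dropped while parsing an alignment stream."""

    kept: int = 0
    unpaired_or_improper: int = 0
    secondary_or_supplementary: int = 0
    low_mapq: int = 0
    insert_out_of_range: int = 0
    orphans: int = 0
    duplicates_removed: int = 0


def parse_fragments(
    path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    l_min: int = DEFAULT_MIN_INSERT,
    l_max: int = DEFAULT_MAX_INSERT,
    dedup: bool = False,
    stats: ParseStats | None = None,
) -> Iterator[FragmentRecord]:
    """Stream filtered fragment inserts from a SAM/BAM file.

    Keeps only properly paired, primary, non-supplementary pairs with both
    mates' MAPQ >= ``min_mapq`` and insert size in [l_min, l_max]. Mates are
    matched by query name so the file may be coordinate- or name-sorted.
    The insert span is the outer span of the two mates; the template-length
    field is not trusted for the span itself.
    """
    if stats is None:
        stats = ParseStats()
    pending: dict[str, pysam.AlignedSegment] = {}
    seen: set[tuple] | None = set() if dedup else None
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.mate_is_unmapped or not read.is_paired:
                stats.unpaired_or_improper += 1
                continue
            if read.is_secondary or read.is_supplementary:
                stats.secondary_or_supplementary += 1
                continue
            if not read.is_proper_pair:
                stats.unpaired_or_improper += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            frag = _pair_to_fragment(read, mate, min_mapq, l_min, l_max, stats)
            if frag is None:
                continue
            if seen is not None:
                key = (frag.chrom, frag.start, frag.end, frag.strand)
                if key in seen:
                    stats.duplicates_removed += 1
                    continue
                seen.add(key)
            stats.kept += 1
            yield frag
    stats.orphans += len(pending)
    if stats.orphans:
        log.warning("%d reads had no mate in the stream and were skipped", stats.orphans)


def _pair_to_fragment(a, b, min_mapq, l_min, l_max, stats) -> FragmentRecord | None:
    if a.mapping_quality < min_mapq or b.mapping_quality < min_mapq:
        stats.low_mapq += 1
        return None
    if a.reference_name != b.reference_name:
        stats.unpaired_or_improper += 1
        return None
    start = min(a.reference_start, b.reference_start)
    end = max(a.reference_end, b.reference_end)
    insert = end - start
    if insert < l_min or insert > l_max:
        stats.insert_out_of_range += 1
        return None
    first = a if a.is_read1 else b
    strand = "-" if first.is_reverse else "+"
    return FragmentRecord(a.reference_name, int(start), int(end), strand)


def fragments_to_frame(fragments: Iterable[FragmentRecord]) -> pd.DataFrame:
    """Materialize a fragment stream as a frame with a ``center`` column."""
    rows = list(fragments)
    if not rows:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype="object"), "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64), "strand": pd.Series(dtype="object"),
             "center": pd.Series(dtype=np.int64)}
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def read_fragment_bed(path: str | Path) -> pd.DataFrame:
    """Load fragments from BED6 (chrom, start, end, name, score, strand).

    This bypasses alignment parsing entirely; useful for testing and for
    pre-extracted fragment sets.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, [0, 1, 2, 5] if df.shape[1] >= 6 else [0, 1, 2]]
    if df.shape[1] == 3:
        df["strand"] = "+"
    df.columns = ["chrom", "start", "end", "strand"]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def write_fragment_bed(frags: pd.DataFrame, path: str | Path) -> None:
    out = frags[["chrom", "start", "end"]].copy()
    out["name"] = "."
    out["score"] = (frags["end"] - frags["start"]).astype(int)
    out["strand"] = frags["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def _positions_by_chrom(frags: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in frags.groupby("chrom", sort=False):
        out[str(chrom)] = np.sort(grp[col].to_numpy(dtype=np.int64))
    return out


def _count_in_bins(positions: dict[str, np.ndarray], bins: BinSet) -> np.ndarray:
    """Count sorted positions falling in each half-open bin via searchsorted."""
    counts = np.zeros(len(bins), dtype=np.int64)
    frame = bins.frame
    for chrom, grp in frame.groupby("chrom", sort=False):
        pos = positions.get(str(chrom))
        if pos is None or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    return counts


def fragment_coverage(frags: pd.DataFrame, bins: BinSet) -> np.ndarray:
    """Per-bin count of fragments whose *center* lies in the bin.

    A center inside k overlapping sliding windows increments all k; a center
    exactly on a bin start belongs to that bin (half-open convention).
    Fragments on chromosomes absent from the bin set are silently skipped
    (they are counted in the returned vector's complement, not an error).
    """
    if len(frags) == 0:
        return np.zeros(len(bins), dtype=np.int64)
    return _count_in_bins(_positions_by_chrom(frags, "center"), bins)


def read_start_coverage(frags: pd.DataFrame, bins: BinSet) -> np.ndarray:
    """Comparison mode: count read 5' start positions instead of centers.

    Each pair contributes its two mates' 5' ends: the forward mate starts at
    the fragment start, the reverse mate's 5' end is the last base of the
    span. This reproduces the read-based counting used by conventional
    peak callers, which dilutes and shifts the insert signal.
    """
    if len(frags) == 0:
        return np.zeros(len(bins), dtype=np.int64)
    fwd = frags[["chrom", "start"]].rename(columns={"start": "pos"})
    rev = pd.DataFrame({"chrom": frags["chrom"], "pos": frags["end"] - 1})
    pos = pd.concat([fwd, rev], ignore_index=True)
    by_chrom = {str(c): np.sort(g["pos"].to_numpy(dtype=np.int64))
                for c, g in pos.groupby("chrom", sort=False)}
    return _count_in_bins(by_chrom, bins)


def subsample_fragments(frags: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Keep each fragment independently with probability ``rate``."""
    if not 0 < rate <= 1:
        raise ValueError(f"subsampling rate must be in (0, 1], got {rate}")
    if rate == 1.0:
        return frags.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frags)) < rate
    return frags.loc[keep].reset_index(drop=True)


def span_depth(frags: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base depth of fragment spans over [start, end) on one chromosome.

    This is the direct fragment coverage used for summit refinement: every
    base covered by the insert contributes, so signal piles up over the
    active element itself.
    """
    depth = np.zeros(end - start, dtype=np.int64)
    sel = frags[(frags["chrom"] == chrom) & (frags["end"] > start) & (frags["start"] < end)]
    if len(sel) == 0:
        return depth
    s = np.clip(sel["start"].to_numpy() - start, 0, end - start)
    e = np.clip(sel["end"].to_numpy() - start, 0, end - start)
    np.add.at(depth, s, 1)
    ends_in = e[e < end - start]
    np.add.at(depth, ends_in, -1)
    return np.cumsum(depth)


def center_depth(frags: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base count of fragment centers over [start, end)."""
    depth = np.zeros(end - start, dtype=np.int64)
    sel = frags[(frags["chrom"] == chrom) & (frags["center"] >= start) & (frags["center"] < end)]
    if len(sel):
        np.add.at(depth, sel["center"].to_numpy() - start, 1)
    return depth
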