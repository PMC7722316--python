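"""Per-bin covariate matrix: input coverage, GC, mappability, folding energy.

STARR-seq output coverage correlates strongly with library/sequencing
covariates (input DNA coverage, GC content, mappability) and with the
thermodynamic stability of the transcribed insert RNA. These enter the
background regression so that enrichment is tested against the *expected*
coverage of each bin rather than a flat genome-wide baseline. Folding
energy and mappability are consumed as precomputed per-base tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .genome import BinSet

__all__ = [
    "CovariateMatrix",
    "gc_content",
    "bin_average_track",
    "bin_track_means",
    "assemble_matrix",
    "select_training_bins",
    "covariate_correlations",
]

AMBIGUOUS_FRACTION_MASK = 0.5


def gc_content(reference: str | Path | Fasta, bins: BinSet) -> np.ndarray:
    """(G+C)/(A+C+G+T) per bin, case-insensitive; NaN where unusable.

    A bin is masked (NaN) when more than half of its bases are ambiguous
    (N etc.) or its chromosome is absent from the FASTA.
    """
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    out = np.full(len(bins), np.nan)
    frame = bins.frame
    for chrom, grp in frame.groupby("chrom", sort=False):
        if str(chrom) not in fasta:
            continue
        seq = str(fasta[str(chrom)][:]).upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
        cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
        cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])
        s = grp["start"].to_numpy()
        e = np.minimum(grp["end"].to_numpy(), len(arr))
        n_gc = cum_gc[e] - cum_gc[s]
        n_ok = cum_ok[e] - cum_ok[s]
        width = e - s
        vals = np.where(n_ok > 0, n_gc / np.maximum(n_ok, 1), np.nan)
        vals = np.where((width - n_ok) > AMBIGUOUS_FRACTION_MASK * width, np.nan, vals)
        out[grp.index.to_numpy()] = vals
    return out


def _bedgraph_frame(track: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(track, pd.DataFrame):
        df = track.copy()
        df.columns = ["chrom", "start", "end", "value"][: df.shape[1]]
    else:
        df = pd.read_csv(track, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def bin_average_track(track, bins: BinSet) -> np.ndarray:
    """Per-bin mean of a per-base track (bigWig path or bedGraph).

    The mean is over bases the track actually covers; a bin with no covered
    base is NaN. bedGraph intervals are treated as constant per-base values.
    """
    name = str(track) if isinstance(track, (str, Path)) else ""
    if name.endswith((".bw", ".bigwig", ".bigWig")):
        return _bin_average_bigwig(name, bins)
    return _bin_average_bedgraph(_bedgraph_frame(track), bins)


def _bin_average_bigwig(path: str, bins: BinSet) -> np.ndarray:
    import pyBigWig

    out = np.full(len(bins), np.nan)
    with pyBigWig.open(path) as bw:
        chrom_lens = bw.chroms()
        for chrom, grp in bins.frame.groupby("chrom", sort=False):
            if str(chrom) not in chrom_lens:
                continue
            for idx, start, end in zip(grp.index, grp["start"], grp["end"]):
                val = bw.stats(str(chrom), int(start), int(end), type="mean", exact=True)[0]
                if val is not None:
                    out[idx] = val
    return out


def _bin_average_bedgraph(df: pd.DataFrame, bins: BinSet) -> np.ndarray:
    # expand to per-base sums via cumulative arrays, one chromosome at a time
    out = np.full(len(bins), np.nan)
    for chrom, grp in bins.frame.groupby("chrom", sort=False):
        track = df[df["chrom"] == str(chrom)]
        if len(track) == 0:
            continue
        length = max(int(track["end"].max()), int(grp["end"].max()))
        value = np.zeros(length)
        covered = np.zeros(length, dtype=bool)
        for s, e, v in zip(track["start"].astype(int), track["end"].astype(int), track["value"]):
            e = min(e, length)
            value[s:e] = v
            covered[s:e] = True
        cum_v = np.concatenate([[0.0], np.cumsum(np.where(covered, value, 0.0))])
        cum_n = np.concatenate([[0], np.cumsum(covered.astype(np.int64))])
        s = grp["start"].to_numpy()
        e = np.minimum(grp["end"].to_numpy(), length)
        n = cum_n[e] - cum_n[s]
        with np.errstate(invalid="ignore"):
            vals = np.where(n > 0, (cum_v[e] - cum_v[s]) / np.maximum(n, 1), np.nan)
        out[grp.index.to_numpy()] = vals
    return out


def bin_track_means(values_by_chrom: dict, bins: BinSet) -> np.ndarray:
    """Per-bin means of in-memory per-base arrays (one array per chromosome)."""
    out = np.full(len(bins), np.nan)
    for chrom, grp in bins.frame.groupby("chrom", sort=False):
        arr = values_by_chrom.get(str(chrom))
        if arr is None:
            continue
        cum = np.concatenate([[0.0], np.cumsum(np.asarray(arr, dtype=float))])
        s = grp["start"].to_numpy()
        e = np.minimum(grp["end"].to_numpy(), len(arr))
        width = np.maximum(e - s, 1)
        out[grp.index.to_numpy()] = (cum[e] - cum[s]) / width
    return out


@dataclass
class CovariateMatrix:
    """Aligned per-bin covariate columns with a missing-row mask.

    In the default covariate model the input-coverage column enters the
    log-linear predictor as ln(1 + t); the remaining columns may be
    z-standardized using statistics from the training rows (recorded so the
    transform is invertible).
    """

    names: list[str]
    values: np.ndarray  # (n_bins, m)
    missing: np.ndarray  # (n_bins,) bool, True where any column is unusable
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def standardized(self, training_mask: np.ndarray) -> "CovariateMatrix":
        """Z-standardize every column except the input-coverage transform,
        using mean/sd over the given training rows."""
        vals = self.values.copy()
        means = np.zeros(vals.shape[1])
        sds = np.ones(vals.shape[1])
        for j, name in enumerate(self.names):
            if name == "log_input":
                continue
            col = vals[training_mask, j]
            m, sd = np.nanmean(col), np.nanstd(col)
            if sd == 0 or not np.isfinite(sd):
                sd = 1.0
            means[j], sds[j] = m, sd
            vals[:, j] = (vals[:, j] - m) / sd
        return CovariateMatrix(list(self.names), vals, self.missing.copy(), means, sds)

    def destandardized(self) -> "CovariateMatrix":
        if self.means is None:
            return self
        vals = self.values * self.sds + self.means
        return CovariateMatrix(list(self.names), vals, self.missing.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


def assemble_matrix(
    input_counts: np.ndarray,
    gc: np.ndarray | None = None,
    mappability: np.ndarray | None = None,
    folding: np.ndarray | None = None,
    standardize: bool = True,
    training_mask: np.ndarray | None = None,
) -> CovariateMatrix:
    """Build the covariate matrix from aligned per-bin vectors.

    Input coverage enters as ln(1 + t); optional covariates are appended in
    the order (gc, mappability, folding). The missing mask is the union of
    the column NaN masks.
    """
    t = np.asarray(input_counts, dtype=float)
    cols = [("log_input", np.log1p(t))]
    for name, arr in (("gc", gc), ("mappability", mappability), ("folding", folding)):
        if arr is not None:
            arr = np.asarray(arr, dtype=float)
            if len(arr) != len(t):
                raise ValueError(f"covariate {name!r} length {len(arr)} != {len(t)} bins")
            cols.append((name, arr))
    values = np.column_stack([c for _, c in cols])
    missing = ~np.all(np.isfinite(values), axis=1)
    mat = CovariateMatrix([n for n, _ in cols], values, missing)
    if standardize:
        mask = training_mask if training_mask is not None else ~missing
        mat = mat.standardized(mask)
    return mat


def select_training_bins(
    input_counts: np.ndarray,
    nonoverlap_mask: np.ndarray,
    missing: np.ndarray | None = None,
    truncated: np.ndarray | None = None,
    min_cov: int = 10,
    t_min_quantile: float = 0.0,
) -> np.ndarray:
    """Mask of bins eligible for model fitting.

    Training is restricted to the non-overlapping tiling; bins with no
    input coverage, input below ``min_cov``, input below the
    ``t_min_quantile`` quantile of nonzero input, missing covariates, or a
    truncated terminal window are excluded — such bins carry no power to
    detect enrichment or would distort the fit.
    """
    t = np.asarray(input_counts, dtype=float)
    mask = np.asarray(nonoverlap_mask, dtype=bool).copy()
    mask &= t > 0
    mask &= t >= min_cov
    if t_min_quantile > 0:
        nonzero = t[t > 0]
        if len(nonzero):
            mask &= t >= np.quantile(nonzero, t_min_quantile)
    if missing is not None:
        mask &= ~np.asarray(missing, dtype=bool)
    if truncated is not None:
        mask &= ~np.asarray(truncated, dtype=bool)
    if not mask.any():
        raise ValueError(
            "no bins left for model training after filtering "
            f"(n={len(t)}, nonzero input={int((t > 0).sum())}, min_cov={min_cov})"
        )
    return mask


def covariate_correlations(
    y: np.ndarray,
    matrix: CovariateMatrix,
    subsample: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlation of output coverage with each covariate column.

    Computed over a random subsample of usable bins (diagnostic mirror of
    the bias analysis one runs before trusting a flat background). Columns
    with zero variance get NaN.
    """
    usable = np.flatnonzero(~matrix.missing & np.isfinite(np.asarray(y, dtype=float)))
    if len(usable) < 3:
        raise ValueError("need at least 3 usable bins for correlation")
    rng = np.random.default_rng(seed)
    if len(usable) > subsample:
        usable = rng.choice(usable, size=subsample, replace=False)
    ys = np.asarray(y, dtype=float)[usable]
    rows = []
    for j, name in enumerate(matrix.names):
        col = matrix.values[usable, j]
        if np.std(col) == 0 or np.std(ys) == 0:
            rows.append((name, np.nan))
        else:
            rows.append((name, float(np.corrcoef(ys, col)[0, 1])))
    return pd.DataFrame(rows, columns=["covariate", "pcc"])
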