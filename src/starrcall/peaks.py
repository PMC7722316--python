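"""Peak calling from scored sliding bins, and downstream peak utilities.

Significant sliding bins (q below threshold, fold enrichment above a
floor) are merged into regions; each region is re-centered on the summit
of the direct per-base fragment coverage and reported as a fixed-width
peak with the statistics of its most significant constituent bin. Also
here: replicate consolidation, the strand orientation-bias binomial test,
and sensitivity/specificity evaluation against a spike-in truth set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import span_depth
from .genome import ChromSizes
from .nbmodel import bh_adjust

__all__ = [
    "fold_enrichment",
    "call_peaks",
    "consolidate_replicates",
    "orientation_bias_test",
    "flag_orientation_bias",
    "evaluate_against_truth",
    "write_narrowpeak",
]

PEAK_COLUMNS = [
    "chrom", "start", "end", "summit", "region_start", "region_end",
    "y", "t", "fold", "pvalue", "qvalue",
]


def fold_enrichment(y, t, y_total, t_total):
    """Depth-normalized output:input ratio, (y / Y_total) / (t / T_total).

    This is the quantitative activity measure of a region; a basal-rate
    region has fold 1. Undefined (NaN) where t = 0.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y_total <= 0 or t_total <= 0:
        raise ValueError("library totals must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = (y / y_total) / (t / t_total)
    return np.where(t > 0, fe, np.nan)


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame(columns=PEAK_COLUMNS)


def call_peaks(
    scored: pd.DataFrame,
    output_fragments: pd.DataFrame,
    chrom_sizes: ChromSizes,
    peak_length: int = 500,
    q_threshold: float = 0.05,
    min_fold: float = 1.0,
) -> pd.DataFrame:
    """Merge significant sliding bins into summit-centered fixed-width peaks.

    ``scored`` needs columns chrom/start/end/y/t/fold/pvalue/qvalue (one row
    per tested sliding bin). Steps: (1) select bins with q <= q_threshold
    and fold >= min_fold; (2) merge overlapping or book-ended selected bins
    into regions; (3) find each region's summit, the position of maximum
    per-base output fragment coverage (leftmost on ties); (4) report a
    ``peak_length`` window centered on the summit, clipped to the
    chromosome; (5) carry the statistics of the region's minimum-P bin.
    """
    sel = scored[(scored["qvalue"] <= q_threshold) & (scored["fold"] >= min_fold)]
    if len(sel) == 0:
        return _empty_peaks()
    rows = []
    for chrom, grp in sel.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        region_start, region_end = int(starts[0]), int(ends[0])
        members = [grp.index[0]]
        regions = []
        for idx, s, e in zip(grp.index[1:], starts[1:], ends[1:]):
            if s <= region_end:  # overlap or book-ended
                region_end = max(region_end, int(e))
                members.append(idx)
            else:
                regions.append((region_start, region_end, members))
                region_start, region_end, members = int(s), int(e), [idx]
        regions.append((region_start, region_end, members))
        chrom_len = chrom_sizes[str(chrom)]
        for rs, re, idxs in regions:
            depth = span_depth(output_fragments, str(chrom), rs, re)
            summit = rs + int(np.argmax(depth)) if depth.size else (rs + re) // 2
            half = peak_length // 2
            ps = max(0, min(summit - half, chrom_len - peak_length))
            ps = max(ps, 0)
            pe = min(ps + peak_length, chrom_len)
            best = scored.loc[idxs].sort_values(["pvalue", "start"]).iloc[0]
            rows.append({
                "chrom": str(chrom), "start": int(ps), "end": int(pe),
                "summit": int(summit - ps), "region_start": rs, "region_end": re,
                "y": int(best["y"]), "t": int(best["t"]), "fold": float(best["fold"]),
                "pvalue": float(best["pvalue"]), "qvalue": float(best["qvalue"]),
            })
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return peaks.reset_index(drop=True)


def _overlap_lengths(a_start, a_end, b_start, b_end):
    return np.maximum(0, np.minimum(a_end, b_end) - np.maximum(a_start, b_start))


def consolidate_replicates(
    peaks1: pd.DataFrame,
    peaks2: pd.DataFrame,
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Keep replicate-1 peaks reciprocally overlapping a replicate-2 peak.

    A pair matches when the overlap covers at least ``min_overlap_frac`` of
    *both* peaks. The rep-1 interval is reported with conservative merged
    statistics: the worse (max) P and q and the mean fold across the pair.
    """
    if len(peaks1) == 0 or len(peaks2) == 0:
        return _empty_peaks()
    rows = []
    for chrom, grp1 in peaks1.groupby("chrom", sort=False):
        grp2 = peaks2[peaks2["chrom"] == chrom]
        if len(grp2) == 0:
            continue
        s2 = grp2["start"].to_numpy()
        e2 = grp2["end"].to_numpy()
        for _, p1 in grp1.iterrows():
            ov = _overlap_lengths(p1["start"], p1["end"], s2, e2)
            frac1 = ov / (p1["end"] - p1["start"])
            frac2 = ov / (e2 - s2)
            hit = (frac1 >= min_overlap_frac) & (frac2 >= min_overlap_frac)
            if not hit.any():
                continue
            p2 = grp2.iloc[int(np.argmax(np.where(hit, ov, -1)))]
            row = p1.to_dict()
            row["pvalue"] = max(p1["pvalue"], p2["pvalue"])
            row["qvalue"] = max(p1["qvalue"], p2["qvalue"])
            row["fold"] = 0.5 * (p1["fold"] + p2["fold"])
            rows.append(row)
    if not rows:
        return _empty_peaks()
    return pd.DataFrame(rows).reset_index(drop=True)[list(peaks1.columns)]


def orientation_bias_test(fwd, total):
    """Two-sided binomial test of strand balance at p = 0.5.

    P = min(1, 2 * min(Pr(K <= k), Pr(K >= k))) — doubling the smaller
    tail, the conservative reading of "skewed on one strand". NaN where
    total = 0 (no supporting fragments, not testable).
    """
    fwd = np.asarray(fwd, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(fwd < 0) or np.any(fwd > total):
        raise ValueError("need 0 <= fwd <= total")
    with np.errstate(invalid="ignore"):
        lower = stats.binom.cdf(fwd, total, 0.5)
        upper = stats.binom.sf(fwd - 1, total, 0.5)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(total > 0, p, np.nan)


def flag_orientation_bias(
    fwd1, total1, fwd2, total2,
    input_balanced=None,
    alpha: float = 0.01,
):
    """Flag peaks with significant strand bias in *both* replicates.

    Each replicate's binomial P values are BH-adjusted over the tested
    peaks and thresholded at ``alpha``. A peak is only flagged when the
    input DNA library is strand-balanced there (``input_balanced`` mask,
    default all True): pre-existing input bias points to PCR artifacts
    rather than orientation-specific activity.
    """
    p1 = orientation_bias_test(fwd1, total1)
    p2 = orientation_bias_test(fwd2, total2)
    q1 = np.full_like(p1, np.nan)
    q2 = np.full_like(p2, np.nan)
    ok1, ok2 = np.isfinite(p1), np.isfinite(p2)
    if ok1.any():
        q1[ok1] = bh_adjust(p1[ok1])
    if ok2.any():
        q2[ok2] = bh_adjust(p2[ok2])
    flagged = ok1 & ok2 & (q1 <= alpha) & (q2 <= alpha)
    if input_balanced is not None:
        flagged &= np.asarray(input_balanced, dtype=bool)
    return pd.DataFrame({"p_rep1": p1, "q_rep1": q1, "p_rep2": p2, "q_rep2": q2,
                         "biased": flagged})


def evaluate_against_truth(
    peaks: pd.DataFrame,
    truth: pd.DataFrame,
    overlap_frac: float = 0.8,
    n_negatives: int = 1000,
) -> dict:
    """Sensitivity/specificity of peak calls against spike-in controls.

    A peak counts as a true positive when at least ``overlap_frac`` of the
    *peak's* length lies inside a control. Sensitivity is the fraction of
    controls hit; peaks hitting no control are false positives;
    specificity = (n_negatives - FP) / n_negatives under the assumption of
    ~``n_negatives`` true-negative regions.
    """
    if len(truth) == 0:
        raise ValueError("truth set is empty")
    controls_hit = np.zeros(len(truth), dtype=bool)
    peak_positive = np.zeros(len(peaks), dtype=bool)
    hits = []
    for i, (_, pk) in enumerate(peaks.iterrows()):
        same = truth[truth["chrom"] == pk["chrom"]]
        if len(same) == 0:
            continue
        ov = _overlap_lengths(pk["start"], pk["end"],
                              same["start"].to_numpy(), same["end"].to_numpy())
        frac = ov / (pk["end"] - pk["start"])
        match = frac >= overlap_frac
        if match.any():
            peak_positive[i] = True
            controls_hit[same.index.to_numpy()[match]] = True
            hits.append((i, same.index.to_numpy()[match]))
    fp = int((~peak_positive).sum())
    sensitivity = float(controls_hit.mean())
    specificity = float((n_negatives - fp) / n_negatives)
    table = truth.copy()
    table["hit"] = controls_hit
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "true_positives": int(peak_positive.sum()),
        "false_positives": fp,
        "controls_hit": int(controls_hit.sum()),
        "n_controls": len(truth),
        "table": table,
    }


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    """ENCODE narrowPeak (BED6+4): signalValue = fold enrichment,
    pValue/qValue as -log10, peak = summit offset from start."""
    with np.errstate(divide="ignore"):
        mlog_p = -np.log10(np.maximum(peaks["pvalue"].to_numpy(dtype=float), 1e-300))
        mlog_q = -np.log10(np.maximum(peaks["qvalue"].to_numpy(dtype=float), 1e-300))
    out = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"].astype(int),
        "end": peaks["end"].astype(int),
        "name": [f"peak_{i + 1}" for i in range(len(peaks))],
        "score": np.minimum(1000, (10 * mlog_q).round().astype(int)),
        "strand": ".",
        "signalValue": peaks["fold"].round(5),
        "pValue": np.round(mlog_p, 5),
        "qValue": np.round(mlog_q, 5),
        "peak": peaks["summit"].astype(int),
    })
    out.to_csv(path, sep="\t", header=False, index=False)
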