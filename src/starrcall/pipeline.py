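"""End-to-end orchestration: bin, count, fit, score, correct, call.

`score_experiment` is the programmatic core working on in-memory fragment
frames and per-bin covariate vectors; `run_pipeline` is the file-based
wrapper that reads alignments/BED fragments, FASTA, and covariate tracks,
and writes peak files, the model JSON, and diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import fragments as frg
from .genome import BinSet, ChromSizes, make_bins, nonoverlapping_subset, read_chrom_sizes
from .nbmodel import NBFit, bh_adjust, fit_nb2, fit_rate_mode, nb_pvalue
from .peaks import call_peaks, fold_enrichment, write_narrowpeak

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "score_experiment", "run_pipeline", "load_fragments"]


@dataclass
class PipelineResult:
    bins: BinSet
    y: np.ndarray
    t: np.ndarray
    matrix: "cov.CovariateMatrix"
    train_mask: np.ndarray
    tested_mask: np.ndarray
    scored: pd.DataFrame
    fit: NBFit
    estimator: object
    peaks: pd.DataFrame


def score_experiment(
    output_fragments: pd.DataFrame,
    input_fragments: pd.DataFrame,
    chrom_sizes: ChromSizes,
    gc: np.ndarray | None = None,
    mappability: np.ndarray | None = None,
    folding: np.ndarray | None = None,
    bins: BinSet | None = None,
    l: int = 500,
    s: int = 100,
    mode: str = "covariate",
    min_cov: int = 10,
    t_min_quantile: float = 0.0,
    q_threshold: float = 0.05,
    min_fold: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PipelineResult:
    """Run the full statistical pipeline on in-memory inputs.

    The NB2 background is fit on filtered bins of the non-overlapping
    tiling; P values are then assigned to every sliding bin that passes the
    input-coverage filters, BH-corrected over exactly that tested set, and
    significant bins are merged into summit-centered peaks of width ``l``.
    """
    if bins is None:
        bins = make_bins(chrom_sizes, l=l, s=s)
    y = frg.fragment_coverage(output_fragments, bins)
    t = frg.fragment_coverage(input_fragments, bins)

    raw = cov.assemble_matrix(t, gc, mappability, folding, standardize=False)
    nonov = nonoverlapping_subset(bins)
    train = cov.select_training_bins(
        t, nonov, missing=raw.missing, truncated=bins.truncated,
        min_cov=min_cov, t_min_quantile=t_min_quantile,
    )
    matrix = raw.standardized(train)

    if mode in ("covariate", "1", 1):
        fit, est = fit_nb2(y[train], _rows(matrix, train), mode="covariate",
                           tol=tol, max_iter=max_iter)
    elif mode in ("rate", "2", 2):
        fit, est = fit_rate_mode(y[train], t[train], _rows(matrix, train),
                                 tol=tol, max_iter=max_iter)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    tested = _tested_mask(t, raw.missing, min_cov, t_min_quantile)
    if fit.mode == "rate":
        keep = [j for j, n in enumerate(matrix.names) if n != "log_input"]
        mu = est.predict(matrix.values[np.ix_(tested, keep)], offset=np.log(t[tested]))
    else:
        mu = est.predict(matrix.values[tested])
    p = nb_pvalue(y[tested], mu, fit.theta)
    q = bh_adjust(p)

    # library totals over the disjoint tiling, so each fragment counts once
    y_total = max(int(y[nonov].sum()), 1)
    t_total = max(int(t[nonov].sum()), 1)
    fold = fold_enrichment(y[tested], t[tested], y_total, t_total)

    scored = bins.frame.loc[tested, ["chrom", "start", "end"]].copy()
    scored["y"] = y[tested]
    scored["t"] = t[tested]
    scored["mu"] = mu
    scored["fold"] = fold
    scored["pvalue"] = p
    scored["qvalue"] = q

    peaks = call_peaks(scored, output_fragments, chrom_sizes, peak_length=bins.l,
                       q_threshold=q_threshold, min_fold=min_fold)
    return PipelineResult(bins, y, t, matrix, train, tested, scored, fit, est, peaks)


def _rows(matrix: "cov.CovariateMatrix", mask: np.ndarray) -> "cov.CovariateMatrix":
    return cov.CovariateMatrix(list(matrix.names), matrix.values[mask],
                               matrix.missing[mask], matrix.means, matrix.sds)


def _tested_mask(t, missing, min_cov, t_min_quantile):
    t = np.asarray(t, dtype=float)
    mask = (t > 0) & (t >= min_cov) & ~missing
    if t_min_quantile > 0:
        nonzero = t[t > 0]
        if len(nonzero):
            mask &= t >= np.quantile(nonzero, t_min_quantile)
    if not mask.any():
        raise ValueError("no bins pass the input-coverage filters")
    return mask


def score_simulated(exp, l: int = 500, s: int = 100, **kwargs) -> PipelineResult:
    """Run the full pipeline on an in-memory simulated experiment."""
    from .simulate import experiment_covariates

    bins = make_bins(exp.config.chrom_sizes, l=l, s=s)
    return score_experiment(
        exp.output_fragments, exp.input_fragments, exp.config.chrom_sizes,
        bins=bins, l=l, s=s, **experiment_covariates(exp, bins), **kwargs,
    )


@dataclass
class RunConfig:
    """File-based run configuration with the recommended defaults."""

    output_path: str
    input_path: str
    chrom_sizes: str
    prefix: str
    fasta: str | None = None
    mappability: str | None = None
    folding: str | None = None
    l: int = 500
    s: int = 100
    l_min: int = 200
    l_max: int = 1000
    min_mapq: int = 30
    min_cov: int = 10
    t_min_quantile: float = 0.0
    q_threshold: float = 0.05
    min_fold: float = 1.0
    mode: str = "covariate"
    dedup: bool = False
    seed: int = 0


def load_fragments(path: str | Path, min_mapq: int = 30, l_min: int = 200,
                   l_max: int = 1000, dedup: bool = False) -> pd.DataFrame:
    """Load fragments from SAM/BAM (parsed and filtered) or fragment BED6."""
    name = str(path)
    if name.endswith((".bed", ".bed.gz", ".bed6")):
        df = frg.read_fragment_bed(name)
        size = df["end"] - df["start"]
        return df[(size >= l_min) & (size <= l_max)].reset_index(drop=True)
    return frg.fragments_to_frame(
        frg.parse_fragments(name, min_mapq=min_mapq, l_min=l_min, l_max=l_max, dedup=dedup)
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the pipeline from files and write all outputs.

    Writes <prefix>.peaks.narrowPeak, <prefix>.peaks.tsv, <prefix>.bins.tsv,
    <prefix>.model.json, and <prefix>.run.json (the exact configuration).
    """
    stage = "load"
    try:
        chrom_sizes = read_chrom_sizes(config.chrom_sizes)
        out_frags = load_fragments(config.output_path, config.min_mapq,
                                   config.l_min, config.l_max, config.dedup)
        in_frags = load_fragments(config.input_path, config.min_mapq,
                                  config.l_min, config.l_max, config.dedup)
        log.info("loaded %d output and %d input fragments", len(out_frags), len(in_frags))

        stage = "covariates"
        bins = make_bins(chrom_sizes, l=config.l, s=config.s)
        gc = cov.gc_content(config.fasta, bins) if config.fasta else None
        mapp = cov.bin_average_track(config.mappability, bins) if config.mappability else None
        fold = cov.bin_average_track(config.folding, bins) if config.folding else None

        stage = "model"
        result = score_experiment(
            out_frags, in_frags, chrom_sizes, gc=gc, mappability=mapp, folding=fold,
            bins=bins, mode=config.mode, min_cov=config.min_cov,
            t_min_quantile=config.t_min_quantile, q_threshold=config.q_threshold,
            min_fold=config.min_fold,
        )

        stage = "write"
        prefix = Path(config.prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_narrowpeak(result.peaks, f"{prefix}.peaks.narrowPeak")
        result.peaks.to_csv(f"{prefix}.peaks.tsv", sep="\t", index=False)
        result.scored.to_csv(f"{prefix}.bins.tsv", sep="\t", index=False,
                             float_format="%.6g")
        result.fit.to_json(f"{prefix}.model.json")
        with open(f"{prefix}.run.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2)
        log.info("called %d peaks (theta=%.3f)", len(result.peaks), result.fit.theta)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
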