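"""Fully generative synthetic STARR-seq experiments with known ground truth.

The simulator emits everything the pipeline consumes — reference FASTA,
chromosome sizes, per-base covariate tracks, paired-end input (DNA) and
output (RNA) fragment sets, and a truth BED of spike-in controls — with the
statistical structure the background model assumes: per-bin output counts
are NB2 around a mean proportional to input intensity, modulated by smooth
covariate effects, with a basal transcription rate of 1 outside controls
and an elevated rate inside the spiked control regions.

Control fragments are placed so that each insert *contains* the control
midpoint (an insert only reports on an element it carries), which makes the
per-base fragment depth pile up over the element — the signal summit
refinement relies on. Background fragment centers are uniform within their
generative bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.ndimage import gaussian_filter1d

from .genome import ChromSizes, write_chrom_sizes, write_bed

__all__ = [
    "SimConfig",
    "Tracks",
    "SimulatedExperiment",
    "simulate_covariate_tracks",
    "simulate_experiment",
    "simulate_replicate",
    "experiment_covariates",
    "write_simulated_alignments",
    "write_bedgraph",
]

# Midpoints of four in vivo enhancers of a well-characterized oncogene
# locus, as fractions of the ~2.6-Mb region they sit in; used only by the
# optional pinned layout (synthetic stand-in, no biological claim).
_PINNED_FRACTIONS = (0.2960, 0.3196, 0.9425, 0.9838)


@dataclass
class SimConfig:
    """Study conditions for a synthetic spike-in experiment.

    Defaults mirror the benchmark design: a ~2.6-Mb chromosome carrying 28
    non-overlapping 500-bp control regions at a strongly elevated
    transcription rate over a basal rate of 1, insert sizes 200-1000 bp
    around a 500-bp library, and NB2 dispersion at the whole-genome scale
    estimated from real data (theta ~ 8.9).
    """

    chrom: str = "chrS"
    genome_length: int = 2_600_000
    bin_size: int = 500
    n_controls: int = 28
    control_size: int = 500
    background_rate: float = 1.0
    control_multiplier: float = 30.0
    input_depth: float = 20.0  # mean input fragments per generative bin
    output_depth_factor: float = 1.0  # output:input sequencing-depth ratio
    insert_mean: float = 500.0
    insert_sd: float = 100.0
    insert_min: int = 200
    insert_max: int = 1000
    theta: float = 8.9
    gc_effect: float = 0.3
    mappability_effect: float = 0.2
    folding_effect: float = -0.2
    input_gc_effect: float = 0.3
    input_mappability_effect: float = 0.2
    strand_prob: float = 0.5
    control_strand_prob: dict = field(default_factory=dict)  # control idx -> fwd prob
    # minimum distance between control midpoints: inserts reach at most
    # insert_max/2 from the element they carry, so 2 kb plus a window keeps
    # the merged significant regions of distinct controls disjoint
    min_control_gap: int = 2000
    pinned_controls: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.control_size > self.bin_size:
            raise ValueError("control_size must not exceed the generative bin size")
        if self.background_rate <= 0 or self.control_multiplier <= 0:
            raise ValueError("rates must be positive")
        if self.theta <= 0:
            raise ValueError("dispersion theta must be positive")

    @property
    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes({self.chrom: self.genome_length})


@dataclass
class Tracks:
    """Per-base covariate tracks plus a sequence consistent with the GC track."""

    chrom: str
    gc: np.ndarray
    mappability: np.ndarray
    folding: np.ndarray
    sequence: str


def _smooth_track(rng, n_bases, knot_spacing=200, sigma_knots=5):
    n_knots = n_bases // knot_spacing + 2
    x = gaussian_filter1d(rng.normal(size=n_knots), sigma_knots)
    sd = x.std()
    if sd > 0:
        x = x / sd
    knots = np.arange(n_knots) * knot_spacing
    return np.interp(np.arange(n_bases), knots, x)


def simulate_covariate_tracks(config: SimConfig, rng=None) -> Tracks:
    """Smooth, spatially autocorrelated covariate tracks and a matching FASTA.

    GC in [0.2, 0.8]; mappability in [0, 1] (mostly near 1); folding free
    energy negative. The sequence is built by error diffusion against the
    GC track, so the GC fraction of any window of >= 50 bp matches the
    track's window mean to within 0.02.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.genome_length
    gc = np.clip(0.5 + 0.10 * _smooth_track(rng, n), 0.2, 0.8)
    mappability = np.clip(0.88 + 0.12 * _smooth_track(rng, n), 0.0, 1.0)
    folding = np.minimum(-1.0, -30.0 + 8.0 * _smooth_track(rng, n))
    # error diffusion: GC count of any window tracks the cumulative target
    cum = np.floor(np.cumsum(gc)).astype(np.int64)
    is_gc = np.diff(np.concatenate([[0], cum])) > 0
    strong = rng.random(n) < 0.5
    bases = np.where(is_gc, np.where(strong, ord("G"), ord("C")),
                     np.where(strong, ord("A"), ord("T"))).astype(np.uint8)
    sequence = bases.tobytes().decode("ascii")
    return Tracks(config.chrom, gc, mappability, folding, sequence)


def _place_controls(config: SimConfig, rng, intensity=None) -> np.ndarray:
    """Indices of generative bins hosting controls.

    Controls are spiked into loci the input library represents at least at
    its nominal depth (spike-in loci are *selected*, not random, and a
    control in an input-depleted region would be untestable by design),
    with midpoints at least ``min_control_gap`` apart so distinct controls
    yield distinct merged regions.
    """
    n_bins = config.genome_length // config.bin_size
    margin = 2
    min_sep = max(2, -(-config.min_control_gap // config.bin_size))
    if config.n_controls == 0:
        return np.array([], dtype=np.int64)
    if config.pinned_controls:
        pinned = sorted(int(f * n_bins) for f in _PINNED_FRACTIONS)
        rest = np.linspace(margin, n_bins - margin - 1,
                           config.n_controls - len(pinned)).astype(int)
        chosen: list[int] = []
        for b in sorted(set(pinned) | set(rest.tolist())):
            if all(abs(b - c) >= min_sep for c in chosen):
                chosen.append(int(b))
        return np.asarray(chosen[: config.n_controls])
    eligible = np.arange(margin, n_bins - margin)
    if intensity is not None:
        eligible = eligible[intensity[eligible] >= config.input_depth]
    candidates = rng.permutation(eligible)
    chosen = []
    for b in candidates:
        if all(abs(int(b) - c) >= min_sep for c in chosen):
            chosen.append(int(b))
            if len(chosen) == config.n_controls:
                break
    if len(chosen) < config.n_controls:
        raise ValueError("genome too small for the requested number of controls")
    return np.sort(np.asarray(chosen))


def _draw_inserts(rng, size, config: SimConfig):
    ins = rng.normal(config.insert_mean, config.insert_sd, size)
    lo, hi = config.insert_min, config.insert_max
    bad = (ins < lo) | (ins > hi)
    while bad.any():  # redraw outside the truncation bounds
        ins[bad] = rng.normal(config.insert_mean, config.insert_sd, int(bad.sum()))
        bad = (ins < lo) | (ins > hi)
    return ins.astype(np.int64)


def _clip_to_genome(start, end, length):
    shift = np.maximum(0, -start)
    start = start + shift
    end = end + shift
    over = np.maximum(0, end - length)
    start = np.maximum(0, start - over)
    end = end - over
    return start, end


@dataclass
class SimulatedExperiment:
    config: SimConfig
    tracks: Tracks
    input_fragments: pd.DataFrame
    output_fragments: pd.DataFrame
    truth: pd.DataFrame  # chrom, start, end, rate
    bin_input_counts: np.ndarray
    bin_output_counts: np.ndarray


def simulate_experiment(config: SimConfig | None = None) -> SimulatedExperiment:
    """Generate input/output fragment sets and the spike-in truth.

    Per generative bin j with z-scored covariates z_j: input intensity
    I_j ∝ depth * exp(input effects · z_j); input count t_j ~ Poisson(I_j);
    output mean mu_j = rate_j * I_j * exp(output effects · z_j) with the
    covariate modulation normalized to mean 1 (so the genome-wide ratio
    stays at the background rate); output count y_j ~ NB2(mu_j, theta).
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    tracks = simulate_covariate_tracks(config, rng)
    L, B = config.genome_length, config.bin_size
    n_bins = L // B
    edges = np.arange(n_bins + 1) * B

    def binmean(track):
        c = np.concatenate([[0.0], np.cumsum(track)])
        return (c[edges[1:]] - c[edges[:-1]]) / B

    def zscore(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    z_gc = zscore(binmean(tracks.gc))
    z_map = zscore(binmean(tracks.mappability))
    z_fold = zscore(binmean(tracks.folding))

    in_mod = np.exp(config.input_gc_effect * z_gc + config.input_mappability_effect * z_map)
    intensity = config.input_depth * in_mod / in_mod.mean()
    t_counts = rng.poisson(intensity)

    out_mod = np.exp(config.gc_effect * z_gc + config.mappability_effect * z_map
                     + config.folding_effect * z_fold)
    out_mod = out_mod / out_mod.mean()

    control_bins = _place_controls(config, rng, intensity)
    rate = np.full(n_bins, config.background_rate)
    rate[control_bins] = config.background_rate * config.control_multiplier
    mu = rate * config.output_depth_factor * intensity * out_mod
    lam = rng.gamma(config.theta, mu / config.theta)
    y_counts = rng.poisson(lam)

    is_control = np.zeros(n_bins, dtype=bool)
    is_control[control_bins] = True

    input_frags = _scatter_uniform(rng, t_counts, edges, config)
    bg_counts = np.where(is_control, 0, y_counts)
    output_bg = _scatter_uniform(rng, bg_counts, edges, config)
    output_ctrl = _scatter_controls(rng, y_counts, control_bins, edges, config)
    output_frags = pd.concat([output_bg, output_ctrl], ignore_index=True)
    output_frags = output_frags.sort_values(["start", "end"]).reset_index(drop=True)

    offset = (B - config.control_size) // 2
    truth = pd.DataFrame({
        "chrom": config.chrom,
        "start": edges[control_bins] + offset,
        "end": edges[control_bins] + offset + config.control_size,
        "rate": rate[control_bins],
    })
    return SimulatedExperiment(config, tracks, input_frags, output_frags, truth,
                               t_counts, y_counts)


def simulate_replicate(exp: SimulatedExperiment, seed: int) -> SimulatedExperiment:
    """Re-draw both libraries with independent noise over the same truth.

    Tracks, control placement, and programmed rates are reused from ``exp``;
    only the stochastic layers (input/output counts and fragment placement)
    are regenerated, emulating a biological replicate of the same sample.
    """
    config = exp.config
    rng = np.random.default_rng(seed)
    L, B = config.genome_length, config.bin_size
    n_bins = L // B
    edges = np.arange(n_bins + 1) * B

    def binmean(track):
        c = np.concatenate([[0.0], np.cumsum(track)])
        return (c[edges[1:]] - c[edges[:-1]]) / B

    def zscore(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    z_gc = zscore(binmean(exp.tracks.gc))
    z_map = zscore(binmean(exp.tracks.mappability))
    z_fold = zscore(binmean(exp.tracks.folding))
    in_mod = np.exp(config.input_gc_effect * z_gc + config.input_mappability_effect * z_map)
    intensity = config.input_depth * in_mod / in_mod.mean()
    out_mod = np.exp(config.gc_effect * z_gc + config.mappability_effect * z_map
                     + config.folding_effect * z_fold)
    out_mod = out_mod / out_mod.mean()

    control_bins = (exp.truth["start"].to_numpy()
                    - (B - config.control_size) // 2) // B
    rate = np.full(n_bins, config.background_rate)
    rate[control_bins] = exp.truth["rate"].to_numpy()

    t_counts = rng.poisson(intensity)
    mu = rate * config.output_depth_factor * intensity * out_mod
    y_counts = rng.poisson(rng.gamma(config.theta, mu / config.theta))
    is_control = np.zeros(n_bins, dtype=bool)
    is_control[control_bins] = True

    input_frags = _scatter_uniform(rng, t_counts, edges, config)
    output_bg = _scatter_uniform(rng, np.where(is_control, 0, y_counts), edges, config)
    output_ctrl = _scatter_controls(rng, y_counts, control_bins, edges, config)
    output_frags = pd.concat([output_bg, output_ctrl], ignore_index=True)
    output_frags = output_frags.sort_values(["start", "end"]).reset_index(drop=True)
    return SimulatedExperiment(config, exp.tracks, input_frags, output_frags,
                               exp.truth.copy(), t_counts, y_counts)


def experiment_covariates(exp: SimulatedExperiment, bins) -> dict:
    """Per-bin covariate vectors for a simulated experiment's tracks."""
    from .covariates import bin_track_means

    chrom = exp.config.chrom
    return {
        "gc": bin_track_means({chrom: exp.tracks.gc}, bins),
        "mappability": bin_track_means({chrom: exp.tracks.mappability}, bins),
        "folding": bin_track_means({chrom: exp.tracks.folding}, bins),
    }


def _scatter_uniform(rng, counts, edges, config: SimConfig) -> pd.DataFrame:
    total = int(counts.sum())
    bin_starts = np.repeat(edges[:-1], counts)
    centers = bin_starts + rng.integers(0, config.bin_size, total)
    inserts = _draw_inserts(rng, total, config)
    start = centers - inserts // 2
    end = start + inserts
    start, end = _clip_to_genome(start, end, config.genome_length)
    strand = np.where(rng.random(total) < config.strand_prob, "+", "-")
    return _frag_frame(config.chrom, start, end, strand)


def _scatter_controls(rng, y_counts, control_bins, edges, config: SimConfig) -> pd.DataFrame:
    frames = []
    for k, b in enumerate(control_bins):
        n = int(y_counts[b])
        core = int(edges[b]) + config.bin_size // 2
        inserts = _draw_inserts(rng, n, config)
        start = core - rng.integers(0, inserts)  # insert always contains the core
        end = start + inserts
        start, end = _clip_to_genome(start, end, config.genome_length)
        p_fwd = config.control_strand_prob.get(k, config.strand_prob)
        strand = np.where(rng.random(n) < p_fwd, "+", "-")
        frames.append(_frag_frame(config.chrom, start, end, strand))
    if not frames:
        return _frag_frame(config.chrom, np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64), np.array([], dtype="object"))
    return pd.concat(frames, ignore_index=True)


def _frag_frame(chrom, start, end, strand) -> pd.DataFrame:
    df = pd.DataFrame({
        "chrom": chrom, "start": start.astype(np.int64), "end": end.astype(np.int64),
        "strand": strand,
    })
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def write_fasta(tracks: Tracks, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{tracks.chrom}\n")
        seq = tracks.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_bedgraph(values: np.ndarray, chrom: str, path: str | Path,
                   resolution: int = 50) -> None:
    """Write a per-base track as a step-wise bedGraph averaged over
    ``resolution``-bp windows."""
    n = len(values)
    starts = np.arange(0, n, resolution)
    ends = np.minimum(starts + resolution, n)
    cum = np.concatenate([[0.0], np.cumsum(values)])
    means = (cum[ends] - cum[starts]) / (ends - starts)
    pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                  "value": np.round(means, 6)}).to_csv(
        path, sep="\t", header=False, index=False)


def write_simulated_alignments(frags: pd.DataFrame, chrom_sizes: ChromSizes,
                               path: str | Path, read_length: int = 100) -> None:
    """Emit one properly paired read pair per fragment as SAM.

    The pair's outer span reproduces the fragment exactly, MAPQ is 60, and
    the first-in-pair mate sits on the fragment's strand, so parsing the
    file back recovers the fragment set.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(chrom_sizes.names)}
        for i, row in enumerate(frags.itertuples(index=False)):
            rl = min(read_length, row.end - row.start)
            left = _segment(f"frag{i}", tid[row.chrom], row.start, rl, reverse=False)
            right = _segment(f"frag{i}", tid[row.chrom], row.end - rl, rl, reverse=True)
            insert = row.end - row.start
            if row.strand == "+":
                first, second = left, right
            else:
                first, second = right, left
            first.is_read1, second.is_read2 = True, True
            for seg, mate, sign in ((left, right, insert), (right, left, -insert)):
                seg.next_reference_id = mate.reference_id
                seg.next_reference_start = mate.reference_start
                seg.template_length = sign
                seg.mate_is_reverse = mate.is_reverse
            out.write(left)
            out.write(right)


def _segment(name, tid, pos, rl, reverse):
    seg = pysam.AlignedSegment()
    seg.query_name = name
    seg.reference_id = tid
    seg.reference_start = int(pos)
    seg.mapping_quality = 60
    seg.cigarstring = f"{rl}M"
    seg.query_sequence = "A" * rl
    seg.is_paired = True
    seg.is_proper_pair = True
    seg.is_reverse = reverse
    return seg


def write_experiment(exp: SimulatedExperiment, outdir: str | Path,
                     sam: bool = False) -> dict[str, Path]:
    """Write every artifact of a simulated experiment to a directory."""
    from .fragments import write_fragment_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "gc": outdir / "gc.bedgraph",
        "mappability": outdir / "mappability.bedgraph",
        "folding": outdir / "folding.bedgraph",
        "input_bed": outdir / "input.fragments.bed",
        "output_bed": outdir / "output.fragments.bed",
        "truth": outdir / "truth.bed",
    }
    write_fasta(exp.tracks, paths["fasta"])
    write_chrom_sizes(exp.config.chrom_sizes, paths["chrom_sizes"])
    write_bedgraph(exp.tracks.gc, exp.config.chrom, paths["gc"])
    write_bedgraph(exp.tracks.mappability, exp.config.chrom, paths["mappability"])
    write_bedgraph(exp.tracks.folding, exp.config.chrom, paths["folding"])
    write_fragment_bed(exp.input_fragments, paths["input_bed"])
    write_fragment_bed(exp.output_fragments, paths["output_bed"])
    truth = exp.truth.copy()
    truth["name"] = [f"control_{i + 1}" for i in range(len(truth))]
    truth["score"] = truth.pop("rate")
    write_bed(truth, paths["truth"])
    if sam:
        paths["input_sam"] = outdir / "input.sam"
        paths["output_sam"] = outdir / "output.sam"
        write_simulated_alignments(exp.input_fragments, exp.config.chrom_sizes,
                                   paths["input_sam"])
        write_simulated_alignments(exp.output_fragments, exp.config.chrom_sizes,
                                   paths["output_sam"])
    return paths
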