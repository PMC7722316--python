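# Methods

## Fragment-insert coverage

The unit of signal is the cloned insert, not the sequencing read. From a
paired-end alignment stream we keep properly paired, primary,
non-supplementary pairs with both mates' MAPQ ≥ 30 (default), take the
insert span as the outer coordinates of the two mates (the template-length
field is not trusted for the span), and drop inserts shorter than 200 bp
or longer than 1000 bp — the size-selection window of a typical 500-bp
STARR-seq library; shorter templates are PCR-bias-prone. Coverage is
counted at the insert **center** (floor of the midpoint; a center on a bin
start belongs to that bin, half-open convention). Because read-start
counting spreads one insert's evidence over ± insert/2, center counting
concentrates signal, sharpens summits, and raises fold enrichment; a
read-start mode is retained for exactly this comparison. The fragment
strand is the strand of the first-in-pair mate, i.e., the orientation of
the insert as cloned — needed only by the orientation-bias test.
Deduplication by identical (chrom, start, end, strand) is available but
off by default, as index-multiplexed libraries are typically deduplicated
per sub-library upstream.

Coordinates are 0-based half-open throughout; BED stays BED. Chromosome
order follows the chrom.sizes file, never a lexicographic sort.

## Binning

The genome is tiled with sliding windows of length *l* = 500 bp and step
*s* = 100 bp (matching the library's insert size; a smaller step raises
resolution at proportional cost). On each chromosome windows start at
0, s, 2s, …; the first window whose end reaches the chromosome end is
truncated there and closes the chromosome — later starts would only nest
inside it. Truncated terminal windows are emitted but flagged: they are
excluded from model training yet still tested, so chromosome ends are not
silently dropped. The *non-overlapping subset* (starts ≡ 0 mod l) is the
disjoint tiling on which the count model is fit, since only there can a
fragment center land in exactly one window (the i.i.d. assumption).

## Background model

Output counts y over the disjoint tiling are modeled as NB2 (Gamma–Poisson
mixture): f(y; μ, θ) = Γ(y+θ)/(Γ(y+1)Γ(θ)) · (θ/(θ+μ))^θ · (μ/(θ+μ))^y,
with variance μ + μ²/θ. Overdispersion is essential: genome-wide
STARR-seq output at fixed input coverage is far from Poisson, and the
`fit_candidate_distributions` diagnostic (MLE fits of Poisson, binomial,
and NB to output counts at the median input coverage, with Q-Q tables at
integer percentiles) reproduces that comparison on any dataset.

The mean is log-linear in the covariates. We include an explicit
intercept; the input column enters as ln(1 + t) (the predictor must be
finite at t = 0 and a log-linear model wants input on the log scale), and
the remaining columns (GC fraction of the window, mean mappability, mean
folding free energy) are z-standardized using training-row statistics —
purely a conditioning transform, recorded in the model JSON and
invertible, so fitted means are unchanged. GC is computed from an indexed
FASTA ((G+C)/(A+C+G+T), case-insensitive; windows more than half
ambiguous are masked). Mappability and folding energy are consumed as
precomputed per-base tracks (bigWig or bedGraph); computing folding
thermodynamics is out of scope. No automatic covariate selection is done:
nested covariate sets can be compared by AIC/BIC (`aic_`/`bic_` on the
estimator, k = |β| + 1 counting the dispersion).

**Training-bin filter.** Fitting uses disjoint, untruncated bins with
t > 0, t ≥ 10 (the default minimum coverage for a deep whole-genome
library — bins below it carry no power to detect enrichment), t at or
above an optional quantile of nonzero input (default quantile 0), and no
missing covariates.

**Estimation.** `NegativeBinomialRegressor` (sklearn-style estimator)
alternates (a) a Fisher-scoring/IRLS step for β at fixed θ, safeguarded by
step halving so the log-likelihood never decreases, and (b) a bounded 1-D
profile-likelihood maximization of θ at fixed β over θ ∈ [1e−3, 1e6]
(floor and cap for stability; a Poisson-like fit drives θ to the cap).
β is warm-started from log-linear least squares on ln(y + 0.5), θ from a
method-of-moments estimate on the warm-start residuals. Iteration stops
when the max coefficient update and the log-θ update both fall below
tol = 1e−8 (default; max 100 rounds); non-convergence is flagged and
warned, never silently returned. The linear predictor is clipped at ±30
before exponentiation. Rank-deficient designs fail with the offending
column names. The per-iteration log-likelihood path is kept on the fitted
object, and the implementation is pinned in tests against an independent
GLM implementation and against a dense θ-grid profile search.

**Rate mode (mode 2).** ln t enters as a fixed offset (coefficient 1, not
estimated), so the model describes the transcription rate π = y/t; with no
covariates the intercept is the log basal rate (≈ 0 when output and input
depths match and the basal rate is 1). Useful when the library contains
discrete elements or covariates are unavailable. Rate mode requires t > 0
on all fitted/scored rows, which the filters guarantee.

## Scoring, correction, peak calling

Every sliding bin passing the input filters (t ≥ min coverage, covariates
present — truncated terminal bins included) is scored with
P = Pr(Y ≥ y) = 1 − CDF(y − 1) under the fitted null, evaluated through
the regularized incomplete-beta identity Pr(Y ≥ y) = I_{μ/(θ+μ)}(y, θ)
(y ≥ 1; P(0) = 1), clipped to [0, 1]; direct pmf summation is retained as
a test oracle at 1e−10. Bins failing the filters get *no* P value — they
were never tested. BH correction is applied genome-wide over exactly the
tested set; the dependence between overlapping windows is acknowledged,
not modeled (see Calibration below).

Bins with q ≤ 0.05 and fold enrichment ≥ 1 are merged (overlapping or
book-ended) into regions. Each region's **summit** is the position of
maximum per-base *fragment-span* depth (leftmost on ties): an insert
reports on the element it carries, so span depth piles up over the active
element itself, whereas insert centers scatter ± insert/2 around it and
cannot localize a point-like element. The reported peak is a fixed
l-length window centered on the summit, clipped to the chromosome —
uniform-width, ENCODE-style; the raw merged region is kept as extra
columns. Peak statistics (y, t, P, q, fold) come from the region's
minimum-P constituent bin, a conservative conventional choice. Fold
enrichment is (y/Y_total)/(t/T_total) with totals summed over the disjoint
tiling, so each fragment counts once.

**Replicates.** Consolidation keeps replicate-1 peaks with ≥ 50%
reciprocal overlap against a replicate-2 peak (our construction; the
reported interval is rep-1-anchored with the worse P/q and the mean fold).

**Orientation bias.** Per peak, supporting fragments (centers inside the
peak) are tested against Binomial(n, 0.5) two-sided by doubling the
smaller tail, capped at 1 — the conservative reading of "skewed on one
strand". A peak is flagged only when significant at BH q ≤ 0.01 in *both*
replicates and the input library is strand-balanced there; pre-existing
input imbalance points to PCR artifacts, not orientation-specific
activity.

**Truth evaluation.** A peak is a true positive when ≥ 80% of its length
lies inside a control; sensitivity is the fraction of controls hit, and
specificity assumes ~1000 true-negative regions: (1000 − FP)/1000.

## The simulator

`simulate_experiment` is fully generative — no external data. It emits
smooth spatially autocorrelated covariate tracks (GC in [0.2, 0.8],
mappability in [0, 1], folding energy negative; Gaussian-filtered noise
interpolated from 200-bp knots), a FASTA built by error diffusion against
the GC track (windowed GC matches the track within 0.02 for ≥ 50-bp
windows), and both libraries at the level of 500-bp generative bins: input
intensity I_j ∝ depth · exp(input effects · z_j) with t_j ~ Poisson(I_j),
and output y_j ~ NB2(rate_j · depth-factor · I_j · exp(output effects ·
z_j), θ), with the covariate modulation normalized to mean 1 so the
genome-wide output:input ratio stays at the basal rate.

Defaults are anchored to the scale of a deep whole-genome experiment:
input depth 20 fragments per 500-bp bin (a realistic median
input coverage), θ = 8.9, insert sizes truncated-normal(500, 100) within
[200, 1000], basal rate 1 with matched output/input depth
(`output_depth_factor = 1`; set it to 41.6/20 to put raw output counts at
the deep-experiment scale, mean ≈ 41.6 at median input).

**Spike-ins.** 28 controls of 500 bp (defaults) are placed on distinct
generative bins, restricted to bins whose input intensity is at least the
nominal depth — spike-in loci are *selected*, and a control in an
input-depleted bin would sit below the caller's own minimum-coverage
testing floor by construction — and with midpoints ≥ 2 kb apart: inserts
reach at most insert_max/2 = 500 bp from the element they carry, so closer
controls would fuse into a single merged region and are arguably one
element. Their rate is the basal rate times a multiplier, default 30:
with NB2 dispersion θ = 8.9 the count distribution has a heavy lower
tail, and 30 is the level at which a worst-case control (covariate
modulation ~0.6) still exceeds the detection threshold (~80 fragments)
except with probability ~3e−4 — i.e., controls are unambiguous, which is
the point of a spike-in truth set. Control fragments are drawn to
*contain* the control midpoint (the insert is placed uniformly over
positions covering it), the generative reading of "reads that support the
control region"; background fragment centers are uniform within their
bin. Strand is Bernoulli(0.5) unless a per-control bias is configured.
An optional pinned layout places four controls at the relative positions
of well-characterized in vivo enhancers of a famous oncogene locus
rescaled into the synthetic chromosome (a synthetic stand-in for
documentation; no biological claim), the rest evenly spaced.

`write_simulated_alignments` converts any fragment set into proper read
pairs (MAPQ 60, outer span equal to the fragment) so the full parser path
can be exercised; `simulate_replicate` redraws both libraries with
independent noise over the same truth and tracks.

**What the simulator does not emulate** — and hence what passing tests do
*not* demonstrate about real data: base-call errors and quality scores,
PCR-duplicate families, alignment ambiguity (every simulated pair maps
uniquely and properly), chromatin- or sequence-driven fragmentation
beyond the smooth GC/mappability surrogates, enhancers of varying width
or strength mixtures, silencers/negative enrichment, and real folding
thermodynamics (the folding track is a smooth stand-in). Covariate effects
are exactly log-linear by construction, so the regression is correctly
specified in simulation; on real data residual confounding will remain.

## Calibration and its limits

On background-only simulations the upper-tail P values over the
**disjoint tiling** track Uniform(0, 1) (KS distance ~0.02 at 1e4 bins;
the residual deviation is count discreteness, since Pr(P ≤ p) ≤ p with
steps of the order of the maximum pmf). Overlapping sliding bins are
*not* NB(μ, θ) with the genome-wide θ: a window straddling two generative
bins sums two thinned draws and is less dispersed, so its P values deviate
modestly (KS ~0.035 under the same conditions). This is the known cost of
testing overlapping windows and is left unmodeled, consistently with
applying BH over the tested set without dependence correction; FDR
control at q ≤ 0.05 empirically holds in both regimes (zero discoveries
on null data). Calibration checks should therefore be run on the tiling
(l = s), as `tests/test_acceptance.py` does.

## Degenerate inputs and numerical conventions

Empty chrom.sizes → empty bin set; empty fragment streams → zero
coverage; no bin surviving the training filter → a fatal, diagnostic
error; all-constant counts in distribution fitting → degenerate flag with
θ at the cap; zero-variance columns in correlation diagnostics → NaN;
orientation test at zero supporting fragments → NaN (untestable); peaks
with t = 0 → fold undefined, never scored. Summit ties break leftmost;
subsampling is an independent Bernoulli thinning, deterministic under a
fixed seed; every stochastic component takes a single integer seed and
fixed seeds reproduce every artifact byte-for-byte.

## Problem sizes used in the shipped checks

The benchmark and test suite run at the scale the method targets but on a
single synthetic chromosome: the spike-in benchmark on ~2.6 Mb with 28
controls (~100k fragments per library), parameter recovery at n = 50,000
bins, and null calibration on a ~5.2-Mb tiling (~1e4 independent bins).
These sizes give Monte-Carlo error comfortably below the assertion
tolerances while keeping a full run in tens of seconds.
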