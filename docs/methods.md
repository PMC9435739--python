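# Methods

## Overview

`lnctime` analyses dense stimulation time courses of bulk RNA-seq to compare
the activation timing of lncRNAs and protein-coding genes. The chain is:
region-restricted quantification of nascent (intronic) and mature (exonic)
signal → median-of-ratios normalization → Ljung–Box activation screen →
impulse-model summaries, kinetic (half-life) fits and elongation-rate
estimation → distance-binned coexpression with block-bootstrap envelopes →
lagged cross-correlation. A synthetic-data generator provides ground-truthed
inputs with the same statistical structure, so every stage is tested by
parameter recovery rather than by fixtures of unknown provenance.

## Quantification conventions

Intron-mapping reads proxy pre-mRNA and hence nascent transcription. Two
windows matter:

* **intron5p** — the first 10 kb of *concatenated intronic sequence* in
  transcription order (not genomic span), excluding exonic bases. Mean
  elongation delay for this window is ≤ ~4 min at 2.5 kb/min, so it times
  activation for genes of any length.
* **intron3p** — the last 10 kb of intronic sequence. The polymerase flux
  here is what is spliced into mature mRNA, so this window drives the
  kinetic model.

Genes whose introns total under 10 kb keep all their introns (short
windows are flagged by length, not dropped — dropping would bias against
short lncRNAs). Intronless genes are excluded from pre-mRNA analyses.
Coordinates are 0-based half-open internally; GTF (1-based inclusive) and
BED conversions happen only at file boundaries.

Normalization is median-of-ratios: each time point's size factor is the
median across all-positive genes of the count over that gene's geometric
mean. The median is taken on the natural scale, exactly as the formula
reads. This estimator assumes most genes are unchanged across the course;
the generator's default fixtures keep activated genes a minority for the
same reason real transcriptomes do.

## The synthetic generator

`SimConfig` defaults encode the human study design: 41 samples, 0–400 min
at 10-min spacing; coding gene lengths log-normal with mean 51.8 kb,
lncRNAs 16.6 kb (σ = 1.0 on the log scale — a heavy right tail whose sample
mean is still stable at a few thousand genes; a σ matching the full
1 kb–1 Mb population range would make the configured mean practically
unrecoverable from finite samples); elongation 2.5 kb/min; one lncRNA per
coding gene at a TSS distance uniform in (0, 50 kb]; 2–10 exons per gene
with ≥ 80% intronic content.

Dynamics: each activated coding gene gets an impulse (product of two
logistics) at its TSS; onset times follow an AR(1) walk along each
chromosome (autocorrelation 0.7), which is what gives profiles their
within-class spatial autocorrelation. A paired lncRNA re-uses its partner's
impulse, amplitude-scaled and shifted by `lnc_lag_min` (default 0:
synchronous). The pre-mRNA signal at genomic offset `d` from the TSS is the
TSS impulse delayed by `d / rate`, evaluated on a 1-min internal grid to
avoid aliasing sub-step delays; window signals average that wave over
500-bp sample points of the window. Mature mRNA solves
`dM/dt = βP − αM` driven by the intron3p signal (production happens when
the polymerase completes the 3′ end), started at its baseline steady state.
Coding half-lives are log-uniform on 5–600 min — immediate-early mRNAs sit
near 10 min and stable messages at many hours — and lncRNAs on 5–60 min
(rapid exosomal turnover). Counts are negative-binomial,
`var = μ + φμ²` with φ = `nb_dispersion` (default 0.05), scaled by
per-time-point depth factors (log-normal, σ = 0.1). `shuffle_profiles=True`
permutes dynamics across genes within each class, producing a null fixture
in which expression is independent of position.

What the generator does **not** emulate: read-level sampling (no FASTQ/BAM,
no mappability or GC structure), alternative isoforms, overlapping or
nested genes, time-correlated biological noise, and chromatin state. Tests
passing on this generator therefore validate the statistical machinery and
its calibration, not robustness to alignment or annotation artifacts.

## Screen

Each profile is tested for serial autocorrelation with the Ljung–Box
statistic. The lag count defaults to `min(10, max(2, n//8))` — 5 on the
41-point grid — because the χ² reference degrades when the lag count is
large relative to the series (empirical size 0.069 at h = 10 versus 0.052
at h = 5, nominal 0.05, n = 41). A gene's regions are combined by
Bonferroni (min p × number of tested regions) and BH adjustment runs across
genes; activated means adjusted p < 0.01. Constant profiles are reported as
degenerate, not dropped silently.

## Kinetics

The ODE is integrated exactly per interval for linearly interpolated
`P(t)` (integrating factor), so integration error is zero for the
interpolant and results are bit-reproducible. `M₀` anchors to the first
observed mRNA value (a serum-starved culture is near steady state), leaving
two free parameters searched on an 8×8 log grid over
α ∈ [ln2/1000, ln2/5] min⁻¹ and β ∈ [10⁻³, 10²], refined by Nelder–Mead in
log space. Flat pre-mRNA with dynamic mRNA raises an unidentifiable error
rather than returning an arbitrary α.

**Identifiability.** A 10-min/400-min design measures half-lives well in
roughly the 30–200 min band. Below ~2 sampling steps the system is
quasi-steady (`M ≈ (β/α)P`, only the ratio identified); above ~half the
window there is almost no decay to observe. With count noise at CV
√0.05 ≈ 22%, the median relative half-life error across genes drawn from
the full 5–600 min range is ~0.19, and ~0.11 inside the identifiable band —
consistent with a Fisher-information estimate of the attainable floor.
Benchmarks in the test suite therefore carry two kinds of bounds: a
≤ 0.15 median bound on an identifiable-band fixture, and looser regression
guards (0.25 / 0.75 at dispersion 0.05 / 0.5) for the full range.
Noise-free recovery is exact to < 0.5%.

Elongation: per gene, the delay between impulse-fit peak times of the
intron5p and intron3p profiles is paired with the distance between the
windows' centres of mass; the rate is the inverted slope of the
through-origin regression of delay on distance. Delay (the fitted, noisy
quantity) sits on the left of the regression so its error does not
attenuate the slope; genes with non-positive delay are excluded and
counted.

## Impulse fitting

Least squares with deterministic data-driven starts (boundary means for
h₀/h₂, extremum for h₁, half-crossing times for t₁/t₂, slopes from
{0.05, 0.2, 1} min⁻¹), bounds t ∈ [−50, window+50] min and
λ ∈ [10⁻³, 10] min⁻¹ to exclude degenerate step fits, and a flat start so
the fit never does worse than the constant model. The contract is the
fitted *curve*: the seven parameters trade off at 10-min sampling, so
recovery is asserted on pointwise curve error (≤ 1% of amplitude
noise-free), not parameter identity. Peak time is the argmax on a 1-min
grid; monotone or plateauing curves (sustained induction) are flagged
no-peak instead of returning a window edge.

## Clustering

Best-of-25 k-means with k-means++ seeding on z-scored profiles, fixed RNG
stream per k. The WSS curve is reported for k selection; the automatic
elbow (max second difference) is available but the pipeline default is
k = 6, the repertoire size that describes this kind of stimulation response.
Centroid agreement between classes is a plain Pearson matrix with NaN for
degenerate centroids.

## Distance trend, block size and envelopes

The trend of pair correlation over TSS distance is a penalized cubic
B-spline: basis dimension 10 (knots at distance quantiles),
second-difference coefficient penalty, smoothing parameter by GCV over a
log grid with ties resolved to the smoothest fit; reported `edf` is
`tr(H) − 1`. statsmodels' GLMGam is the independent cross-check in the
test suite; the in-package smoother exists because envelopes need thousands
of refits (bootstrap refits reuse the observed fit's knots and smoothing
parameter, turning each iteration into one 10×10 solve).

Block size: pair distances are shuffled (≥ 100 permutations, default 1000)
and the pointwise 99th quantile of null trends computed; the observed
trend's contiguous exceedance run starting at the shortest evaluation
distance marks how far spatial dependence reaches, and its upper edge is
the block size. If the observed trend does not exceed the null at the
shortest distance, the configured minimum (25 kb) is returned with a
fallback flag.

Envelope: each chromosome is split into contiguous blocks of the chosen
size; blocks are resampled with replacement *independently for the coding
and lncRNA classes*, genes travelling with their blocks. Independent
per-class resampling is what makes the envelope a null for the cross-class
relationship while preserving each class's own spatial autocorrelation —
same-class genes sharing a block keep their exact relative positions, while
cross-class adjacency is scrambled beyond the block scale. Pairs and the
trend (or the binned mean cross-correlation) are recomputed per iteration;
the envelope is the pointwise 1st/99th percentile over iterations
(default 1000; calibration tests use 200, where the suite verifies the
quantiles have stabilized on the interior of the distance grid).

## Cross-correlation

At lag ℓ the lncRNA profile advanced by ℓ is correlated with the fixed
coding profile on the truncated overlap (no padding); lags are multiples of
the sampling step within ±200 min (±90 min suits shorter murine designs).
The sign convention — negative peak lag ⇔ lncRNA precedes — is pinned by a
constructed-shift regression test. Binned means use
{0–50, 50–150, 150–500} kb by default; peak-lag ties resolve to the
smallest |lag| and then to the negative lag, encoding the synchrony null.
Pairing is restricted to screen-activated genes with non-degenerate
profiles, mirroring the analysis population.

## Problem sizes

Recovery and calibration suites run at sizes chosen to make the statistics
stable while keeping the full test run a few minutes on one core: 200
coding/lncRNA pairs plus 600 background genes for the synchrony and
envelope fixtures, 100–200 genes for kinetic and elongation recovery, 200
permutations / 200 bootstrap iterations for calibration checks (the
production default remains 1000), and six seeds for the null-coverage
medians.

## Known limitations

* Rates are time-invariant: no modelling of changing splicing or
  degradation along the course, and no nuclear-export compartment.
* Half-life accuracy is bounded by the sampling design (see above); values
  far outside 30–200 min should be read as order-of-magnitude.
* The enhancer/promoter labelling of lncRNAs is a plain ±300 bp TSS
  interval query against a user-supplied element BED; no chromatin signal
  is analysed.
* The pseudochromosome bootstrap anchors genes by TSS; a pair whose members
  straddle a block boundary changes or vanishes in resampled genomes, which
  is intended (cross-class structure beyond the block scale is the null's
  target) but means envelopes are conservative exactly at the block scale.
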