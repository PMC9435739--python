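# lnctime

Activation-timing analysis of long noncoding RNAs (lncRNAs) and
protein-coding genes in dense RNA-seq time courses.

## The problem

When cells are stimulated, mature mRNA levels are a lagged, smoothed readout
of gene activation: RNA polymerase II needs `L / v` minutes to traverse a
gene of length `L` at elongation rate `v` (~2.5 kb/min), and the mRNA pool
integrates production with a gene-specific half-life. Comparing lncRNA and
coding-gene activation on mature-RNA profiles therefore produces spurious
"lncRNA first" orderings, because lncRNAs are short and unstable while
coding genes are long and often stable. The fix is to time activation from
*nascent* transcription — intron-mapping reads in total RNA-seq — restricted
to the first 10 kb of intron sequence downstream of the TSS, where the
elongation delay is negligible for every gene.

`lnctime` implements that analysis end to end for sampled time courses
(41 points at 10-min spacing by default), together with a synthetic-data
generator that reproduces the statistical structure of such an experiment so
every stage is testable without downloads.

## Models and statistics

* **Transcription kinetics** — mature mRNA follows
  `dM/dt = β·P(t) − α·M(t)`, with `P` the pre-mRNA signal from the *last*
  10 kb of introns (the production flux at the gene's 3′ end), `β` the
  splicing/production coefficient and `α` the degradation rate;
  `T½ = ln 2 / α`. The ODE is solved exactly for piecewise-linear `P` by an
  integrating factor; `(α, β)` come from least squares over a multi-start
  log-grid with Nelder–Mead refinement.
* **Impulse model** — profiles are summarized by the product-of-logistics
  curve `f(t) = (1/h₁)·(h₀+(h₁−h₀)σ(λ₁(t−t₁)))·(h₂+(h₁−h₂)σ(−λ₂(t−t₂)))`,
  with asymptotes `f(−∞)=h₀`, `f(+∞)=h₂`; its analytic peak time feeds the
  elongation-rate regression (delay vs distance through the origin).
* **Activation screen** — Ljung–Box portmanteau test per gene,
  Benjamini–Hochberg adjustment, activated at adjusted p < 0.01.
* **Distance–coexpression** — Pearson correlation of z-scored intron
  profiles for all intra-chromosomal coding/lncRNA pairs within 500 kb,
  smoothed over TSS distance by a penalized B-spline (GAM); significance via
  a block bootstrap that resamples chromosome blocks independently per
  transcript class (pseudochromosomes) and takes pointwise 1st/99th
  percentiles over 1000 iterations.
* **Lead/lag** — lagged cross-correlation (±200 min) with the lncRNA
  shifted and the coding profile fixed; a *negative* peak lag means the
  lncRNA precedes.

## Worked example

`examples/07_lagged_crosscorrelation.py` simulates 200 synchronously
activated coding/lncRNA pairs inside a background-dominated transcriptome,
screens for activated genes and computes distance-binned mean
cross-correlations:

```
bin   0-50  kb:  207 pairs, peak lag +0 min
bin  50-150 kb:  126 pairs, peak lag -10 min
bin 150-500 kb:  593 pairs, peak lag +0 min
nearest bin with mature-mRNA coding profiles: peak lag -40 min
```

Nearby pairs peak at lag 0 — activation is synchronous when both classes
are timed from their first-10-kb intron signal. Replacing the coding side
with mature mRNA moves the peak to −40 min: an apparent lncRNA lead
manufactured entirely by gene length and transcript stability. The other
examples cover fixture generation, screening, half-life inference
(`03_fit_halflives.py`), elongation-rate estimation (`04_elongation_rate.py`
prints 2.55 kb/min against a generating 2.5), profile clustering and the
distance-correlation envelope.

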