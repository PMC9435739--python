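"""Order lncRNA vs coding activation in time with lagged cross-correlation.

The lncRNA profile is shifted across lags of -200..+200 min while the coding
profile stays fixed; a NEGATIVE peak lag means the lncRNA precedes. Using
first-10-kb intron signal for both sides removes gene-length and stability
delays; substituting mature mRNA for the coding side re-introduces them.
"""

from lnctime import crosscorr, quantify, screen, simdata, spatial

cfg = simdata.SimConfig(n_coding=200, n_lnc_per_coding=1, n_background=600,
                        lnc_lag_min=0.0, seed=8)
genes, truth = simdata.make_genome(cfg)
profiles = quantify.normalize_table(simdata.simulate_counts(genes, truth, cfg))
res = screen.screen_genes(profiles, threshold=0.01)
active = res.loc[res["activated"], "gene_id"]
pairs = spatial.make_pairs(genes, profiles, 500_000, gene_ids=active)

ccf = crosscorr.binned_mean_ccf(pairs, profiles, max_lag=200, step=10)
for (lo, hi), lag, n in zip(ccf.bins, ccf.peak_lag, ccf.n_pairs):
    print(f"bin {lo // 1000:>3}-{hi // 1000:<3} kb: {n:>4} pairs, "
          f"peak lag {lag:+.0f} min")

exon = crosscorr.binned_mean_ccf(pairs, profiles, max_lag=200, step=10,
                                 coding_region="exon")
print(f"nearest bin with mature-mRNA coding profiles: peak lag "
      f"{exon.peak_lag[0]:+.0f} min")
# Pre-mRNA vs pre-mRNA peaks at lag 0: activation is synchronous. The
# mature-mRNA substitution shifts the peak negative - an apparent lncRNA
# lead created purely by elongation and degradation delays, not regulation.
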