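"""Group activated genes into prototypical response classes with k-means.

Z-scored profiles are clustered on Euclidean distance; the WSS (within-
cluster sum of squares) curve guides the choice of k, and centroids of the
coding and lncRNA classes are compared by Pearson correlation.
"""

import numpy as np

from lnctime import clustering, quantify, screen, simdata, spatial

cfg = simdata.SimConfig(n_coding=120, n_lnc_per_coding=1, n_background=400,
                        seed=6)
genes, truth = simdata.make_genome(cfg)
profiles = quantify.normalize_table(simdata.simulate_counts(genes, truth, cfg))
res = screen.screen_genes(profiles, threshold=0.01)
active = set(res.loc[res["activated"], "gene_id"])

biotype = {g.gene_id: g.biotype for g in genes}
ids, Z = spatial.profile_matrix(profiles, region="intron5p", gene_ids=active)
coding = np.array([biotype[g] == "protein_coding" for g in ids])

curve = clustering.wss_curve(Z[coding], range(1, 9), seed=0)
print("WSS curve (k, wss):", [(k, round(w)) for k, w in curve])

k = 6  # the pipeline default for this kind of response repertoire
cod = clustering.kmeans_profiles(Z[coding], k=k, seed=0)
lnc = clustering.kmeans_profiles(Z[~coding], k=k, seed=0)
M = clustering.centroid_correlation(cod.centroids, lnc.centroids)
print(f"k={k}: coding cluster sizes",
      [int((cod.labels == c + 1).sum()) for c in range(k)])
best = np.nanmax(M, axis=1)
print("best lncRNA-centroid correlation per coding centroid:",
      np.round(best, 2))
# High off-diagonal maxima mean every coding response class has a matching
# lncRNA class: the two transcript classes share the same temporal repertoire.
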