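"""Generate a small synthetic time-course fixture and write it to disk.

Builds a genome of paired coding genes and lncRNAs plus flat background
genes, simulates the 41-point count table for the three region classes, and
writes GTF/BED annotation, counts, ground truth and a manifest.
"""

from lnctime import simdata

cfg = simdata.SimConfig(n_coding=20, n_lnc_per_coding=1, n_background=40,
                        seed=1)
genes, truth = simdata.make_genome(cfg)
counts = simdata.simulate_counts(genes, truth, cfg)
paths = simdata.write_fixture(genes, counts, truth, "scratch/fixture",
                              cfg, force=True)

n_lnc = sum(g.biotype == "lncRNA" for g in genes)
n_cod = sum(g.biotype == "protein_coding" for g in genes)
print(f"genes: {n_cod} protein-coding + {n_lnc} lncRNA on "
      f"{len({g.chrom for g in genes})} chromosomes")
print(f"count table: {counts.shape[0]} rows (gene x region) x "
      f"{counts.shape[1] - 2} time points")
for name, path in paths.items():
    print(f"  {name}: {path}")
# Each paired lncRNA shares its partner's activation impulse; the truth
# table records the impulse parameters, kinetic rates and TSS distances
# that every downstream recovery test measures against.
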