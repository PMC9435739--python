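import numpy as np
import pytest

from lnctime import quantify, screen, simdata

normalized = quantify.normalize_table


def activated_ids(profiles):
    res = screen.screen_genes(profiles, threshold=0.01)
    return list(res.loc[res["activated"], "gene_id"])


@pytest.fixture(scope="session")
def sync_fixture():
    """200 synchronous coding/lncRNA pairs embedded in a majority of flat
    background genes (as in a real transcriptome, where activated genes are
    the minority the median-of-ratios normalization assumes), moderate
    negative-binomial noise; returns normalized profiles and the activated
    gene set from the Ljung-Box screen (the pairing population)."""
    cfg = simdata.SimConfig(n_coding=200, n_lnc_per_coding=1, n_background=600,
                            seed=17)
    genes, truth = simdata.make_genome(cfg)
    counts = simdata.simulate_counts(genes, truth, cfg)
    prof = normalized(counts)
    return cfg, genes, truth, prof, activated_ids(prof)


@pytest.fixture(scope="session")
def null_fixtures():
    """Position-shuffled (null) fixtures over several seeds, screened."""
    out = []
    for seed in range(6):
        cfg = simdata.SimConfig(n_coding=100, n_lnc_per_coding=1,
                                n_background=500, shuffle_profiles=True,
                                seed=100 + seed)
        genes, truth = simdata.make_genome(cfg)
        counts = simdata.simulate_counts(genes, truth, cfg)
        prof = normalized(counts)
        out.append((cfg, genes, truth, prof, activated_ids(prof)))
    return out


@pytest.fixture(scope="session")
def toy_gene():
    return quantify.GeneModel(
        gene_id="toy", chrom="chr1", strand="+", gene_start=0, gene_end=21000,
        biotype="protein_coding",
        exons=((0, 1000), (6000, 8000), (20000, 21000)))
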