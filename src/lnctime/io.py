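"""File-format boundary: GTF, BED12, count/truth TSVs and the run manifest.

All coordinates are 0-based half-open in memory; GTF lines are written
1-based inclusive and BED 0-based half-open, so the two files for the same
gene differ by exactly 1 in the start coordinate.
"""

from __future__ import annotations

import hashlib
import os

import gffutils
import numpy as np
import pandas as pd
import yaml

from .quantify import REGIONS, GeneModel


def write_gtf(genes: list[GeneModel], path: str) -> None:
    """Write gene and exon features as GTF (1-based, inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write("\t".join([g.chrom, "lnctime", "gene", str(g.gene_start + 1),
                                str(g.gene_end), ".", g.strand, ".", attrs]) + "\n")
            tx = f'{attrs} transcript_id "{g.gene_id}.t1";'
            for a, b in g.exons:
                fh.write("\t".join([g.chrom, "lnctime", "exon", str(a + 1), str(b),
                                    ".", g.strand, ".", tx]) + "\n")


def read_gtf(path: str) -> list[GeneModel]:
    """Parse a GTF of gene/exon features back into :class:`GeneModel` objects."""
    db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                            disable_infer_genes=True, disable_infer_transcripts=True)
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        exons = []
        for ex in db.region(seqid=feat.seqid, start=feat.start, end=feat.end,
                            featuretype="exon"):
            if ex.attributes.get("gene_id", [None])[0] == feat.attributes["gene_id"][0]:
                exons.append((ex.start - 1, ex.end))
        genes.append(GeneModel(
            gene_id=feat.attributes["gene_id"][0],
            chrom=feat.seqid,
            strand=feat.strand,
            gene_start=feat.start - 1,
            gene_end=feat.end,
            biotype=feat.attributes["gene_biotype"][0],
            exons=tuple(sorted(exons)),
        ))
    genes.sort(key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    return genes


def write_bed12(genes: list[GeneModel], path: str) -> None:
    """Write genes as BED12 (0-based, half-open); blocks are the exons."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(b - a) for a, b in g.exons) + ","
            starts = ",".join(str(a - g.gene_start) for a, b in g.exons) + ","
            fh.write("\t".join([
                g.chrom, str(g.gene_start), str(g.gene_end), g.gene_id, "0",
                g.strand, str(g.gene_start), str(g.gene_end), "0",
                str(len(g.exons)), sizes, starts]) + "\n")


def write_counts(counts: pd.DataFrame, path: str) -> None:
    """Write the long count table (gene_id, region, one column per minute)."""
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "region"]:
        raise ValueError("count table must start with gene_id and region columns")
    bad = set(df["region"]) - set(REGIONS)
    if bad:
        raise ValueError(f"unknown region labels: {sorted(bad)}")
    return df


def count_times(counts: pd.DataFrame) -> np.ndarray:
    """Time grid (minutes) from the count-table header."""
    return np.array([float(c) for c in counts.columns[2:]])


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(config_dict: dict, path: str, force: bool = False) -> None:
    """Record the generating configuration; refuses to clobber unless forced."""
    if os.path.exists(path) and not force:
        raise FileExistsError(f"manifest exists at {path}; pass force=True to overwrite")
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def read_manifest(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
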