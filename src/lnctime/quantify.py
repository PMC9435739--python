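"""Region-restricted expression quantification and normalization.

Intronic read signal in total RNA-seq proxies nascent transcription
(pre-mRNA), while exonic signal tracks mature mRNA.  Because RNA polymerase II
takes tens of minutes to traverse long genes, the *position* of the intronic
window matters: the first 10 kb of intron sequence downstream of the TSS
times gene activation with minimal elongation delay, while the last 10 kb
reports the production flux that feeds the mature mRNA pool.  This module
provides those window computations, the median-of-ratios normalization used
to put time points on a common scale, and z-scoring of profiles.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based inclusive GTF happens only at file boundaries (see
:mod:`lnctime.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("intron5p", "intron3p", "exon")


class NoIntronError(ValueError):
    """Raised for intronless genes, which are excluded from pre-mRNA analysis."""


class DegenerateProfileError(ValueError):
    """Raised when a constant profile reaches an operation requiring variance."""


class UnnormalizableError(ValueError):
    """Raised when no gene has all-positive counts across time points."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: coordinates, strand, biotype and exon structure.

    ``exons`` are disjoint, sorted, 0-based half-open intervals covering the
    transcribed portions; introns are everything else inside
    ``[gene_start, gene_end)``.  The TSS is ``gene_start`` on the + strand and
    ``gene_end - 1`` on the − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    biotype: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.gene_end > self.gene_start:
            raise ValueError("gene_end must exceed gene_start")
        ex = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        if not ex:
            raise ValueError("gene must have at least one exon")
        if ex[0][0] != self.gene_start or ex[-1][1] != self.gene_end:
            raise ValueError("first/last exon must abut the gene boundaries")
        for (a, b), (c, d) in zip(ex, ex[1:]):
            if c < b:
                raise ValueError("exons overlap")
        object.__setattr__(self, "exons", ex)

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    @property
    def length(self) -> int:
        return self.gene_end - self.gene_start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c > b:
                out.append((b, c))
        return tuple(out)

    @property
    def intron_length(self) -> int:
        return sum(b - a for a, b in self.introns)


@dataclass
class ExpressionProfile:
    """One gene's values over the time grid for one region class."""

    gene_id: str
    region: str
    times: np.ndarray
    values: np.ndarray
    state: str = "raw"  # raw | normalized | zscore

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.times.size != self.values.size:
            raise ValueError("times/values length mismatch")
        if self.times.size >= 2:
            d = np.diff(self.times)
            if not (d > 0).all() or not np.allclose(d, d[0]):
                raise ValueError("times must be strictly increasing and evenly spaced")

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.values) == 0.0)


def region_windows(gene: GeneModel, window_kb: float = 10.0,
                   end: str = "five_prime") -> list[tuple[int, int]]:
    """Genomic intervals covering the first/last ``window_kb`` of intron sequence.

    Introns are walked in transcription order (strand-aware) and concatenated;
    the window covers the first (``end='five_prime'``) or last
    (``end='three_prime'``) ``window_kb`` kilobases of that concatenated
    intronic sequence, excluding all exonic bases.  If the gene's total intron
    length is shorter than the window, all introns are returned (the caller
    can detect the shortfall by summing interval lengths).

    Returns intervals sorted by genomic coordinate.
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    introns = list(gene.introns)
    if not introns:
        raise NoIntronError(f"gene {gene.gene_id} has no introns")
    # forward genomic walk consumes intron left edges, backward walk right edges
    forward = (gene.strand == "+") == (end == "five_prime")
    walk = introns if forward else introns[::-1]
    budget = int(round(window_kb * 1000))
    taken: list[tuple[int, int]] = []
    for a, b in walk:
        if budget <= 0:
            break
        size = b - a
        if size <= budget:
            taken.append((a, b))
            budget -= size
        else:
            taken.append((a, a + budget) if forward else (b - budget, b))
            budget = 0
    return sorted(taken)


def size_factors(count_matrix: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors, one per column (time point).

    Each column's factor is the median, over genes with all-positive counts,
    of the ratio of that gene's count to its geometric mean across columns.
    Dividing each column by its factor normalizes the matrix.  Genes with any
    zero count are excluded from the geometric-mean reference (log of zero is
    undefined), mirroring the standard DESeq-style estimator.
    """
    X = np.asarray(count_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a genes x time-points matrix with >= 2 columns")
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise UnnormalizableError("no gene has all-positive counts")
    ref = X[positive]
    geomean = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    return np.median(ref / geomean, axis=0)


def normalize_counts(count_matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each time-point column by its median-of-ratios size factor."""
    f = size_factors(count_matrix)
    return count_matrix / f


def normalize_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize a long count table (gene_id, region, time columns) in place
    of its value columns, using median-of-ratios size factors computed over
    all rows."""
    return pd.concat([counts.iloc[:, :2].copy(),
                      normalize_counts(counts.iloc[:, 2:])], axis=1)


def zscore(profile: ExpressionProfile) -> ExpressionProfile:
    """Z-score a profile using the population standard deviation."""
    if profile.is_constant:
        raise DegenerateProfileError(
            f"constant profile {profile.gene_id}/{profile.region} cannot be z-scored")
    v = profile.values
    z = (v - v.mean()) / v.std()
    return ExpressionProfile(gene_id=profile.gene_id, region=profile.region,
                             times=profile.times.copy(), values=z, state="zscore")
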