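"""Distance-coexpression trends and block-bootstrap simulation envelopes.

Neighbouring genes share regulatory environment, so a lncRNA's expression
profile tends to correlate with that of nearby protein-coding genes, with
the correlation decaying over genomic distance.  Because profiles of genes
of the *same* class are themselves spatially autocorrelated, a naive
permutation null is too narrow; instead, pseudochromosomes are built by
splitting each chromosome into fixed-size blocks and resampling the blocks
with replacement, independently for the coding and lncRNA classes.  Pair
correlations and the distance trend are recomputed on each pseudochromosome
and the pointwise 1st/99th percentiles over iterations form the simulation
envelope: an observed trend escaping the envelope at short distances
indicates genuine cross-class coupling beyond shared spatial structure.

The trend smoother is a penalized cubic B-spline (basis dimension 10,
second-difference penalty, smoothness chosen by generalized cross
validation), the standard GAM smooth for a scatter of correlations against
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .quantify import GeneModel


class TooFewPairsError(ValueError):
    """Trend fitting needs >= 50 pairs spanning >= 3 distance bins."""


# ---------------------------------------------------------------------------
# penalized-spline smoother


class PenalizedSpline:
    """Cubic B-spline smooth with a second-difference coefficient penalty.

    Minimizes ``||y - B c||^2 + lam * ||D2 c||^2`` where ``B`` is a cubic
    B-spline basis of dimension ``df`` (knots at quantiles of x) and ``D2``
    the second-difference operator.  When ``lam`` is not given it is chosen
    by generalized cross validation over a log-spaced grid; GCV ties resolve
    to the smoothest candidate.  ``edf`` reports ``tr(H) - 1``, the
    effective degrees of freedom of the smooth beyond a constant level.
    """

    def __init__(self, df: int = 10, degree: int = 3,
                 lambdas=None) -> None:
        self.df = df
        self.degree = degree
        self.lambdas = (np.geomspace(1e-4, 1e8, 25) if lambdas is None
                        else np.asarray(lambdas, dtype=float))
        self.knots_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None
        self.lam_: float | None = None
        self.edf_: float | None = None

    def _make_knots(self, x: np.ndarray) -> np.ndarray:
        k = self.degree
        n_interior = self.df - k - 1
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs) if n_interior > 0 else np.array([])
        interior = np.unique(interior)
        lo, hi = float(x.min()), float(x.max())
        # collapse duplicated quantiles toward an even grid if x is very tied
        if interior.size < n_interior:
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])

    def _basis(self, x: np.ndarray) -> np.ndarray:
        k = self.degree
        t = self.knots_
        xc = np.clip(x, t[k], t[-k - 1])
        return BSpline.design_matrix(xc, t, k).toarray()

    def fit(self, x, y, lam: float | None = None,
            knots: np.ndarray | None = None) -> "PenalizedSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        self.knots_ = self._make_knots(x) if knots is None else knots
        B = self._basis(x)
        D2 = np.diff(np.eye(B.shape[1]), n=2, axis=0)
        S = D2.T @ D2
        BtB, Bty = B.T @ B, B.T @ y
        n = y.size

        def solve(l):
            c = np.linalg.solve(BtB + l * S, Bty)
            # tr(H) = tr((B'B + lS)^-1 B'B)
            tr = np.trace(np.linalg.solve(BtB + l * S, BtB))
            return c, tr

        if lam is None:
            best = None
            for l in self.lambdas:
                c, tr = solve(l)
                rss = float(np.sum((y - B @ c) ** 2))
                denom = max(n - tr, 1e-9)
                gcv = n * rss / denom ** 2
                if best is None or gcv <= best[0] + 1e-12:
                    best = (gcv, l, c, tr)
            _, lam, c, tr = best
        else:
            c, tr = solve(lam)
        self.lam_, self.coef_, self.edf_ = float(lam), c, float(tr - 1.0)
        return self

    def refit(self, x, y) -> "PenalizedSpline":
        """New data, same knots and smoothing parameter (bootstrap refits)."""
        out = PenalizedSpline(self.df, self.degree)
        return out.fit(x, y, lam=self.lam_, knots=self.knots_)

    def predict(self, x) -> np.ndarray:
        return self._basis(np.asarray(x, dtype=float)) @ self.coef_


# ---------------------------------------------------------------------------
# pair construction


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (values - mu) / sd


def profile_matrix(profiles: pd.DataFrame, region: str = "intron5p",
                   gene_ids=None) -> tuple[list[str], np.ndarray]:
    """Extract one region's profiles as (gene ids, z-scored value matrix).

    Constant (degenerate) profiles are dropped.
    """
    df = profiles[profiles["region"] == region]
    if gene_ids is not None:
        keep = set(gene_ids)
        df = df[df["gene_id"].isin(keep)]
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    ok = np.ptp(values, axis=1) > 0
    Z = _zscore_rows(values[ok])
    return list(df["gene_id"][ok]), Z


def make_pairs(genes: list[GeneModel], profiles: pd.DataFrame,
               max_distance_bp: int = 500_000, region: str = "intron5p",
               gene_ids=None, bin_bp: int = 25_000,
               classes: tuple[str, str] = ("protein_coding", "lncRNA"),
               ) -> pd.DataFrame:
    """All intra-chromosomal cross-class gene pairs within a TSS distance.

    Pairing is many-to-many and strand-agnostic: every (coding, lncRNA) pair
    on the same chromosome with |TSS_a - TSS_b| <= ``max_distance_bp`` is
    reported, with the Pearson correlation of their z-scored ``region``
    profiles and a distance-bin label (``bin_bp``-wide bins, display only).
    """
    ids, Z = profile_matrix(profiles, region=region, gene_ids=gene_ids)
    index = {gid: i for i, gid in enumerate(ids)}
    T = Z.shape[1] if Z.size else 0
    by_class: dict[str, list[GeneModel]] = {c: [] for c in classes}
    for g in genes:
        if g.biotype in by_class and g.gene_id in index:
            by_class[g.biotype].append(g)
    rows = []
    for a in by_class[classes[0]]:
        za = Z[index[a.gene_id]]
        for b in by_class[classes[1]]:
            if b.chrom != a.chrom or (classes[0] == classes[1] and
                                      b.gene_id <= a.gene_id):
                continue
            d = abs(a.tss - b.tss)
            if d > max_distance_bp:
                continue
            zb = Z[index[b.gene_id]]
            r = float(za @ zb) / T
            rows.append({"coding_id": a.gene_id, "lnc_id": b.gene_id,
                         "chrom": a.chrom, "tss_distance": d, "pearson_r": r,
                         "distance_bin": f"{d // bin_bp * bin_bp // 1000}-"
                                         f"{(d // bin_bp + 1) * bin_bp // 1000}kb"})
    return pd.DataFrame(rows, columns=["coding_id", "lnc_id", "chrom",
                                       "tss_distance", "pearson_r",
                                       "distance_bin"])


# ---------------------------------------------------------------------------
# trend + envelopes


@dataclass(frozen=True)
class GamTrendResult:
    smoother: PenalizedSpline
    edf: float

    def __call__(self, distances) -> np.ndarray:
        return self.smoother.predict(distances)


def gam_trend(pairs: pd.DataFrame, df: int = 10,
              min_pairs: int = 50) -> GamTrendResult:
    """Penalized-spline smooth of pair correlation against TSS distance."""
    if len(pairs) < min_pairs or pairs["distance_bin"].nunique() < 3:
        raise TooFewPairsError(
            f"need >= {min_pairs} pairs over >= 3 distance bins, got "
            f"{len(pairs)} pairs / {pairs['distance_bin'].nunique()} bins")
    sm = PenalizedSpline(df=df).fit(pairs["tss_distance"], pairs["pearson_r"])
    return GamTrendResult(smoother=sm, edf=sm.edf_)


@dataclass(frozen=True)
class EnvelopeResult:
    eval_distances: np.ndarray
    trend: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_boot: int
    block_size: int

    @property
    def exceeds_envelope(self) -> np.ndarray:
        return (self.trend > self.hi) | (self.trend < self.lo)


def _eval_grid(pairs: pd.DataFrame, n_eval: int) -> np.ndarray:
    return np.linspace(pairs["tss_distance"].min(),
                       pairs["tss_distance"].max(), n_eval)


def choose_block_size(pairs: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
                      min_block_bp: int = 25_000, n_eval: int = 50,
                      ) -> tuple[int, bool]:
    """Block size from the reach of the observed distance-correlation trend.

    Pair separation distances are shuffled ``n_perm`` times; a trend is fit
    to each shuffle with the observed fit's knots and smoothing parameter,
    giving a pointwise 99th-quantile null curve.  The observed trend's
    contiguous exceedance run starting at the shortest evaluation distance
    marks how far spatial dependence reaches; its upper edge is returned as
    the block size.  If the trend does not exceed the null at the shortest
    distance, dependence is undetectable and (``min_block_bp``, True) is
    returned, the flag marking the fallback.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable 99th quantile")
    rng = np.random.default_rng(seed)
    obs = gam_trend(pairs)
    grid = _eval_grid(pairs, n_eval)
    observed = obs(grid)
    d = pairs["tss_distance"].to_numpy()
    r = pairs["pearson_r"].to_numpy()
    null = np.empty((n_perm, grid.size))
    for i in range(n_perm):
        null[i] = obs.smoother.refit(rng.permutation(d), r).predict(grid)
    q99 = np.quantile(null, 0.99, axis=0)
    exceeds = observed > q99
    if not exceeds[0]:
        return min_block_bp, True
    edge = int(np.argmin(exceeds)) if not exceeds.all() else grid.size - 1
    block = int(round(grid[edge]))
    return max(block, min_block_bp), False


def pseudochromosome_positions(genes: list[GeneModel], block_size: int,
                               rng: np.random.Generator,
                               classes: tuple[str, str] = ("protein_coding",
                                                           "lncRNA"),
                               ) -> dict[str, list[tuple[str, str, int]]]:
    """One block-bootstrap draw of gene TSS positions.

    Each chromosome is split into contiguous ``block_size``-bp blocks which
    are resampled with replacement, independently for each transcript class;
    genes travel with their block (TSS re-anchored to the block offset) and
    may appear zero or several times.  Returns, per class, a list of
    (gene_id, chrom, new_tss) instances.
    """
    chrom_len: dict[str, int] = {}
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.gene_end)
    out: dict[str, list[tuple[str, str, int]]] = {c: [] for c in classes}
    for cls in classes:
        members = [g for g in genes if g.biotype == cls]
        for chrom in sorted(chrom_len):
            n_blocks = max(1, -(-chrom_len[chrom] // block_size))
            here = [g for g in members if g.chrom == chrom]
            by_block: dict[int, list[GeneModel]] = {}
            for g in here:
                by_block.setdefault(g.tss // block_size, []).append(g)
            draw = rng.integers(0, n_blocks, size=n_blocks)
            for slot, src in enumerate(draw):
                for g in by_block.get(int(src), []):
                    new_tss = slot * block_size + (g.tss - int(src) * block_size)
                    out[cls].append((g.gene_id, chrom, new_tss))
    return out


def _pairs_from_positions(pos_a, pos_b, corr: np.ndarray,
                          index_a: dict, index_b: dict,
                          max_distance_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and correlations for all cross-class instance pairs."""
    dist, r = [], []
    by_chrom: dict[str, list] = {}
    for gid, chrom, tss in pos_b:
        if gid in index_b:
            by_chrom.setdefault(chrom, []).append((tss, index_b[gid]))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for gid, chrom, tss in pos_a:
        ia = index_a.get(gid)
        if ia is None or chrom not in by_chrom:
            continue
        arr = by_chrom[chrom]
        tss_arr = np.array([t for t, _ in arr])
        lo = np.searchsorted(tss_arr, tss - max_distance_bp, "left")
        hi = np.searchsorted(tss_arr, tss + max_distance_bp, "right")
        for t, ib in arr[lo:hi]:
            dist.append(abs(t - tss))
            r.append(corr[ia, ib])
    return np.asarray(dist, dtype=float), np.asarray(r, dtype=float)


def _class_profiles(genes, profiles, region, gene_ids, classes):
    ids, Z = profile_matrix(profiles, region=region, gene_ids=gene_ids)
    index = {gid: i for i, gid in enumerate(ids)}
    biotype = {g.gene_id: g.biotype for g in genes}
    idx_a = {gid: i for gid, i in index.items() if biotype.get(gid) == classes[0]}
    idx_b = {gid: i for gid, i in index.items() if biotype.get(gid) == classes[1]}
    T = Z.shape[1]
    corr = (Z @ Z.T) / T
    return idx_a, idx_b, corr


def block_bootstrap_envelope(genes: list[GeneModel], profiles: pd.DataFrame,
                             block_size: int, n_boot: int = 1000, seed: int = 0,
                             max_distance_bp: int = 500_000,
                             region: str = "intron5p", gene_ids=None,
                             n_eval: int = 50,
                             classes: tuple[str, str] = ("protein_coding",
                                                         "lncRNA"),
                             ) -> EnvelopeResult:
    """Simulation envelope for the distance-correlation trend.

    The observed trend (GCV-smoothed) is compared against the pointwise
    1st/99th percentiles of trends refit on ``n_boot`` pseudochromosome
    draws (same knots and smoothing parameter).  Deterministic per seed.
    """
    pairs = make_pairs(genes, profiles, max_distance_bp, region=region,
                       gene_ids=gene_ids, classes=classes)
    obs = gam_trend(pairs)
    grid = _eval_grid(pairs, n_eval)
    observed = obs(grid)
    idx_a, idx_b, corr = _class_profiles(genes, profiles, region, gene_ids,
                                         classes)
    rng = np.random.default_rng(seed)
    curves = np.full((n_boot, grid.size), np.nan)
    for i in range(n_boot):
        pos = pseudochromosome_positions(genes, block_size, rng, classes)
        d, r = _pairs_from_positions(pos[classes[0]], pos[classes[1]], corr,
                                     idx_a, idx_b, max_distance_bp)
        if d.size < 10:
            continue
        curves[i] = obs.smoother.refit(d, r).predict(grid)
    ok = ~np.isnan(curves).any(axis=1)
    lo = np.quantile(curves[ok], 0.01, axis=0)
    hi = np.quantile(curves[ok], 0.99, axis=0)
    return EnvelopeResult(eval_distances=grid, trend=observed, lo=lo, hi=hi,
                          n_boot=n_boot, block_size=block_size)


def classify_tss_elements(genes: list[GeneModel], elements: pd.DataFrame,
                          window_bp: int = 300) -> pd.DataFrame:
    """Label genes by candidate cis-regulatory elements near their TSS.

    ``elements`` needs columns chrom/start/end/label (e.g. promoter-like,
    enhancer-like).  A gene receives every label of elements lying within
    ``window_bp`` of its TSS (strand-agnostic interval query); genes with no
    nearby element get an empty label string.
    """
    rows = []
    by_chrom = {c: sub.sort_values("start") for c, sub in elements.groupby("chrom")}
    for g in genes:
        labels = []
        sub = by_chrom.get(g.chrom)
        if sub is not None:
            near = sub[(sub["end"] + window_bp > g.tss) &
                       (sub["start"] - window_bp <= g.tss)]
            labels = sorted(set(near["label"]))
        rows.append({"gene_id": g.gene_id, "biotype": g.biotype,
                     "labels": ",".join(labels)})
    return pd.DataFrame(rows)
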