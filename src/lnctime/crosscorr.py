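"""Lagged cross-correlation of lncRNA and coding-gene expression profiles.

To order lncRNA and protein-coding activation in time, the lncRNA profile is
shifted across a symmetric range of lags while the coding profile stays
fixed, and the Pearson correlation is computed on the truncated overlap at
each lag (no padding).  Sign convention, pinned by a regression test: a
NEGATIVE peak lag means the lncRNA precedes the coding gene (the lncRNA has
to be shifted later in time to align).  Distance-binned means over many
pairs give the population-level lead/lag picture, and pseudochromosome
resampling (see :mod:`lnctime.spatial`) yields per-bin 1st/99th-percentile
envelopes under the null of no distance relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import GeneModel
from .spatial import (_class_profiles, _pairs_from_positions, make_pairs,
                      profile_matrix, pseudochromosome_positions)

DEFAULT_BINS_BP = ((0, 50_000), (50_000, 150_000), (150_000, 500_000))


def _row_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape matrices (NaN where
    either row is constant)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A ** 2).sum(axis=1) * (B ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def _lag_matrix(L: np.ndarray, C: np.ndarray, lag_steps: np.ndarray) -> np.ndarray:
    """Mean-preserving matrix of r(pair, lag): cor(L[i+m], C[i]) on overlap."""
    n = L.shape[1]
    out = np.empty((L.shape[0], lag_steps.size))
    for j, m in enumerate(lag_steps):
        if m >= 0:
            a, b = L[:, m:], C[:, :n - m] if m else C
        else:
            a, b = L[:, :n + m], C[:, -m:]
        out[:, j] = _row_pearson(a, b)
    return out


def ccf_pair(lnc_values, coding_values, max_lag: float, step: float,
             min_overlap: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlation series for one pair.

    Returns (lags in minutes, Pearson r at each lag).  At lag ``l = m*step``
    the correlation is between the lncRNA profile advanced by ``m`` samples
    and the fixed coding profile, over the truncated overlap; a constant
    overlap yields NaN at that lag.
    """
    L = np.asarray(lnc_values, dtype=float)[None, :]
    C = np.asarray(coding_values, dtype=float)[None, :]
    if L.shape != C.shape:
        raise ValueError("profiles must share the time grid")
    K = int(round(max_lag / step))
    if L.shape[1] - K < min_overlap:
        raise ValueError(f"need >= {min_overlap} overlapping points at max lag")
    lag_steps = np.arange(-K, K + 1)
    r = _lag_matrix(L, C, lag_steps)[0]
    return lag_steps * step, r


def _peak_lag(lags: np.ndarray, mean_r: np.ndarray) -> float:
    """Argmax lag; ties go to the smallest |lag|, then to the negative one."""
    finite = np.isfinite(mean_r)
    best = np.max(mean_r[finite])
    cand = lags[finite][mean_r[finite] >= best - 1e-12]
    order = sorted(cand, key=lambda l: (abs(l), l))
    return float(order[0])


@dataclass(frozen=True)
class CrossCorrResult:
    lags: np.ndarray                    # minutes, symmetric about 0
    bins: tuple[tuple[int, int], ...]   # bp intervals
    mean_ccf: np.ndarray                # n_bins x n_lags (NaN for empty bins)
    n_pairs: np.ndarray                 # pairs per bin
    peak_lag: np.ndarray                # minutes per bin (NaN for empty bins)
    lo: np.ndarray | None = None        # envelope bounds, same shape as mean_ccf
    hi: np.ndarray | None = None


def binned_mean_ccf(pairs: pd.DataFrame, profiles: pd.DataFrame,
                    max_lag: float = 200.0, step: float = 10.0,
                    bins=DEFAULT_BINS_BP, region: str = "intron5p",
                    coding_region: str | None = None) -> CrossCorrResult:
    """Mean cross-correlation per distance bin over all pairs.

    The lncRNA side always uses ``region`` (first-10-kb intron signal);
    ``coding_region`` defaults to the same but can be set to ``"exon"`` to
    reproduce the mature-mRNA comparison, where elongation and degradation
    delays drag the coding profile later and the apparent peak lag moves in
    the lncRNA-precedes direction.
    """
    coding_region = coding_region or region
    lnc_ids, Zl = profile_matrix(profiles, region=region)
    cod_ids, Zc = profile_matrix(profiles, region=coding_region)
    li = {g: i for i, g in enumerate(lnc_ids)}
    ci = {g: i for i, g in enumerate(cod_ids)}
    usable = pairs[pairs["lnc_id"].isin(li) & pairs["coding_id"].isin(ci)]
    L = Zl[[li[g] for g in usable["lnc_id"]]]
    C = Zc[[ci[g] for g in usable["coding_id"]]]
    K = int(round(max_lag / step))
    lag_steps = np.arange(-K, K + 1)
    R = _lag_matrix(L, C, lag_steps)
    dist = usable["tss_distance"].to_numpy()
    lags = lag_steps * step
    mean_ccf = np.full((len(bins), lags.size), np.nan)
    n_pairs = np.zeros(len(bins), dtype=int)
    peak = np.full(len(bins), np.nan)
    for b, (lo_bp, hi_bp) in enumerate(bins):
        mask = (dist >= lo_bp) & (dist < hi_bp)
        n_pairs[b] = int(mask.sum())
        if n_pairs[b] == 0:
            continue
        mean_ccf[b] = np.nanmean(R[mask], axis=0)
        peak[b] = _peak_lag(lags, mean_ccf[b])
    return CrossCorrResult(lags=lags, bins=tuple(tuple(b) for b in bins),
                           mean_ccf=mean_ccf, n_pairs=n_pairs, peak_lag=peak)


def ccf_envelope(genes: list[GeneModel], profiles: pd.DataFrame,
                 block_size: int, n_boot: int = 1000, seed: int = 0,
                 max_lag: float = 200.0, step: float = 10.0,
                 bins=DEFAULT_BINS_BP, max_distance_bp: int = 500_000,
                 region: str = "intron5p", gene_ids=None,
                 classes: tuple[str, str] = ("protein_coding", "lncRNA"),
                 ) -> CrossCorrResult:
    """Per-bin, per-lag 1st/99th-percentile envelopes from pseudochromosomes.

    Reuses the block-bootstrap machinery: each iteration resamples
    chromosome blocks independently per transcript class, rebuilds the pair
    set and recomputes the binned mean cross-correlation.  The returned
    result carries the observed mean CCF plus the envelope bounds.
    """
    pairs = make_pairs(genes, profiles, max_distance_bp, region=region,
                       gene_ids=gene_ids, classes=classes)
    observed = binned_mean_ccf(pairs, profiles, max_lag=max_lag, step=step,
                               bins=bins, region=region)
    lnc_ids, Zl = profile_matrix(profiles, region=region, gene_ids=gene_ids)
    li = {g: i for i, g in enumerate(lnc_ids)}
    biotype = {g.gene_id: g.biotype for g in genes}
    idx_cod = {g: i for g, i in li.items() if biotype.get(g) == classes[0]}
    idx_lnc = {g: i for g, i in li.items() if biotype.get(g) == classes[1]}
    K = int(round(max_lag / step))
    lag_steps = np.arange(-K, K + 1)
    rng = np.random.default_rng(seed)
    acc = np.full((n_boot, len(bins), lag_steps.size), np.nan)
    for it in range(n_boot):
        pos = pseudochromosome_positions(genes, block_size, rng, classes)
        # collect instance pairs with their profile indices
        dist, ic, il = [], [], []
        by_chrom: dict[str, list] = {}
        for gid, chrom, tss in pos[classes[1]]:
            if gid in idx_lnc:
                by_chrom.setdefault(chrom, []).append((tss, idx_lnc[gid]))
        for chrom in by_chrom:
            by_chrom[chrom].sort()
        for gid, chrom, tss in pos[classes[0]]:
            if gid not in idx_cod or chrom not in by_chrom:
                continue
            arr = by_chrom[chrom]
            tarr = np.array([t for t, _ in arr])
            lo = np.searchsorted(tarr, tss - max_distance_bp, "left")
            hi = np.searchsorted(tarr, tss + max_distance_bp, "right")
            for t, j in arr[lo:hi]:
                dist.append(abs(t - tss))
                ic.append(idx_cod[gid])
                il.append(j)
        if not dist:
            continue
        dist = np.asarray(dist)
        R = _lag_matrix(Zl[np.asarray(il)], Zl[np.asarray(ic)], lag_steps)
        for b, (lo_bp, hi_bp) in enumerate(bins):
            mask = (dist >= lo_bp) & (dist < hi_bp)
            if mask.any():
                acc[it, b] = np.nanmean(R[mask], axis=0)
    lo = np.nanquantile(acc, 0.01, axis=0)
    hi = np.nanquantile(acc, 0.99, axis=0)
    return CrossCorrResult(lags=observed.lags, bins=observed.bins,
                           mean_ccf=observed.mean_ccf, n_pairs=observed.n_pairs,
                           peak_lag=observed.peak_lag, lo=lo, hi=hi)
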