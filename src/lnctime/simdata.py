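"""Synthetic genomes and RNA-seq time-course count tables.

The generator emulates the statistical structure of a dense stimulation
time course (41 samples at 10-min intervals by default):

* protein-coding genes with log-normal lengths (mean 51.8 kb) and shorter
  lncRNAs (mean 16.6 kb) placed without overlap on several synthetic
  chromosomes, each lncRNA paired with a nearby coding gene (TSS distance
  uniform up to a configurable maximum);
* impulse-shaped pre-mRNA activation at each activated TSS, with lncRNA
  activation an amplitude-scaled, optionally time-lagged copy of its
  partner's impulse;
* a transcription wave: the pre-mRNA signal at genomic offset ``d`` from
  the TSS is the TSS impulse delayed by ``d / elongation_rate``;
* mature mRNA obeying ``dM/dt = beta * P(t) - alpha * M(t)``, where the
  production term follows the polymerase flux at the 3' end of the gene
  (the last-10-kb intron signal), with half-lives ``ln 2 / alpha`` drawn
  from minutes to hours;
* onset times that drift along each chromosome (AR(1) over gene order),
  giving within-class spatial autocorrelation of profiles;
* negative-binomial count noise around depth-scaled expectations.

Everything is a pure function of (:class:`SimConfig`, seed): identical
configurations reproduce byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import os

import numpy as np
import pandas as pd

from . import io as lio
from .impulse import ImpulseParams, impulse_eval
from .kinetics import integrate_model
from .quantify import REGIONS, GeneModel, region_windows


class PlacementInfeasibleError(RuntimeError):
    """Genes could not be placed without overlap after bounded retries."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic study.

    Defaults reproduce the human time-course design: 41 samples at 10-min
    spacing (0-400 min), coding genes averaging 51.8 kb and lncRNAs 16.6 kb,
    elongation at 2.5 kb/min, and synchronous lncRNA activation
    (``lnc_lag_min = 0``).  ``halflife_range_min`` bounds the log-uniform
    draw of coding mRNA half-lives; lncRNAs use the shorter
    ``lnc_halflife_range_min`` (they are rapidly turned over).  Count noise
    is negative binomial with variance ``mu + nb_dispersion * mu**2``;
    per-time-point depth factors default to log-normal(0, 0.1) draws.
    """

    n_coding: int = 50
    n_lnc_per_coding: int = 1
    n_background: int = 50
    coding_length_mean_kb: float = 51.8
    lnc_length_mean_kb: float = 16.6
    length_sigma: float = 1.0
    elongation_rate_kb_per_min: float = 2.5
    time_start: float = 0.0
    time_stop: float = 400.0
    time_step: float = 10.0
    lnc_lag_min: float = 0.0
    halflife_range_min: tuple[float, float] = (5.0, 600.0)
    lnc_halflife_range_min: tuple[float, float] = (5.0, 60.0)
    nb_dispersion: float = 0.05
    depth_factors: tuple[float, ...] | None = None
    depth_sigma: float = 0.1
    max_pair_distance_bp: int = 50_000
    n_chromosomes: int = 4
    gap_bp_range: tuple[int, int] = (20_000, 200_000)
    onset_range_min: tuple[float, float] = (30.0, 240.0)
    onset_autocorr: float = 0.7
    fine_step_min: float = 1.0
    shuffle_profiles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coding <= 0:
            raise ValueError("n_coding must be positive")
        if self.n_lnc_per_coding < 0 or self.n_background < 0:
            raise ValueError("gene counts must be non-negative")
        if min(self.coding_length_mean_kb, self.lnc_length_mean_kb) <= 0:
            raise ValueError("gene lengths must be positive")
        if self.time_stop <= self.time_start:
            raise ValueError("time_stop must exceed time_start")
        n_steps = (self.time_stop - self.time_start) / self.time_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("time_step must divide the time span")
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes")
        if self.elongation_rate_kb_per_min <= 0:
            raise ValueError("elongation rate must be positive")

    def times(self) -> np.ndarray:
        """The measurement grid in minutes."""
        n = int(round((self.time_stop - self.time_start) / self.time_step))
        return self.time_start + self.time_step * np.arange(n + 1)

    def fine_times(self) -> np.ndarray:
        n = int(round((self.time_stop - self.time_start) / self.fine_step_min))
        return self.time_start + self.fine_step_min * np.arange(n + 1)


_TRUTH_COLS = ["gene_id", "biotype", "is_background", "partner_id",
               "tss_distance_bp", "onset_min", "h0", "h1", "h2", "t1", "t2",
               "lambda1", "lambda2", "alpha", "beta", "base_expr"]


def _draw_length(rng: np.random.Generator, mean_kb: float, sigma: float,
                 min_bp: int = 2000) -> int:
    mu = np.log(mean_kb * 1000.0) - sigma ** 2 / 2.0
    return max(min_bp, int(round(rng.lognormal(mu, sigma))))


def _exon_structure(rng: np.random.Generator, length: int) -> tuple[tuple[int, int], ...]:
    """Random 2-10 exon layout; intronic fraction at least 80% of the gene."""
    n_exons = int(rng.integers(2, 11))
    exon_sizes = rng.integers(100, 301, size=n_exons).astype(float)
    max_exonic = 0.2 * length
    if exon_sizes.sum() > max_exonic:
        exon_sizes *= max_exonic / exon_sizes.sum()
    exon_sizes = np.maximum(2, np.round(exon_sizes).astype(int))
    n_introns = n_exons - 1
    intron_total = length - int(exon_sizes.sum())
    w = rng.dirichlet(np.ones(n_introns))
    intron_sizes = np.maximum(1, np.floor(w * intron_total).astype(int))
    intron_sizes[-1] += intron_total - int(intron_sizes.sum())
    exons, pos = [], 0
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_sizes[i])))
        pos += int(exon_sizes[i])
        if i < n_introns:
            pos += int(intron_sizes[i])
    # force exact gene span by stretching the final exon if rounding drifted
    a, _ = exons[-1]
    exons[-1] = (a, length)
    return tuple(exons)


def _shift_exons(exons, offset):
    return tuple((a + offset, b + offset) for a, b in exons)


def make_genome(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes on synthetic chromosomes and draw ground-truth dynamics.

    Returns the gene models (sorted by chromosome and start) and a truth
    table with one row per gene: pairing, TSS distance, the TSS impulse
    parameters of pre-mRNA activation, and the kinetic rates ``alpha`` and
    ``beta`` used to produce mature mRNA.
    """
    rng = np.random.default_rng(config.seed)
    units: list[list[dict]] = []

    for i in range(config.n_coding):
        coding_len = _draw_length(rng, config.coding_length_mean_kb, config.length_sigma)
        strand = "+" if rng.random() < 0.5 else "-"
        unit = [{"gene_id": f"pc{i:05d}", "biotype": "protein_coding",
                 "background": False, "length": coding_len, "strand": strand,
                 "rel_start": 0, "partner": None, "tss_distance": 0}]
        coding_tss = 0 if strand == "+" else coding_len - 1
        placed: list[tuple[int, int]] = [(0, coding_len)]
        for j in range(config.n_lnc_per_coding):
            lnc_len = _draw_length(rng, config.lnc_length_mean_kb,
                                   config.length_sigma, min_bp=1000)
            for attempt in range(200):
                u = int(rng.integers(1, config.max_pair_distance_bp + 1))
                if strand == "+":
                    # lncRNA upstream (leftward), transcribed away from the gene
                    lnc_strand, start = "-", coding_tss - u + 1 - lnc_len
                    iv = (start, start + lnc_len)
                else:
                    lnc_strand, start = "+", coding_tss + u
                    iv = (start, start + lnc_len)
                if all(iv[1] <= a or iv[0] >= b for a, b in placed):
                    placed.append(iv)
                    unit.append({"gene_id": f"lnc{i:05d}_{j}", "biotype": "lncRNA",
                                 "background": False, "length": lnc_len,
                                 "strand": lnc_strand, "rel_start": iv[0],
                                 "partner": f"pc{i:05d}", "tss_distance": u})
                    break
            else:
                raise PlacementInfeasibleError(
                    f"could not place lncRNA {j} near pc{i:05d} within "
                    f"{config.max_pair_distance_bp} bp without overlap")
        units.append(unit)

    for i in range(config.n_background):
        biotype = "protein_coding" if i % 2 == 0 else "lncRNA"
        mean_kb = (config.coding_length_mean_kb if biotype == "protein_coding"
                   else config.lnc_length_mean_kb)
        L = _draw_length(rng, mean_kb, config.length_sigma)
        units.append([{"gene_id": f"bg{i:05d}", "biotype": biotype,
                       "background": True, "length": L,
                       "strand": "+" if rng.random() < 0.5 else "-",
                       "rel_start": 0, "partner": None, "tss_distance": 0}])

    order = rng.permutation(len(units))
    chrom_of = rng.integers(0, config.n_chromosomes, size=len(units))
    cursors = {c: 0 for c in range(config.n_chromosomes)}
    genes: list[GeneModel] = []
    rows: list[dict] = []
    for k in order:
        unit, c = units[k], int(chrom_of[k])
        lo = min(g["rel_start"] for g in unit)
        cursors[c] += int(rng.integers(*config.gap_bp_range))
        origin = cursors[c] - lo
        for g in unit:
            start = origin + g["rel_start"]
            exons = _shift_exons(_exon_structure(rng, g["length"]), start)
            genes.append(GeneModel(gene_id=g["gene_id"], chrom=f"chr{c + 1}",
                                   strand=g["strand"], gene_start=start,
                                   gene_end=start + g["length"],
                                   biotype=g["biotype"], exons=exons))
            rows.append({"gene_id": g["gene_id"], "biotype": g["biotype"],
                         "is_background": g["background"],
                         "partner_id": g["partner"] or "",
                         "tss_distance_bp": g["tss_distance"]})
        cursors[c] = max(cursors[c], max(origin + g["rel_start"] + g["length"]
                                         for g in unit))

    genes.sort(key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    truth = pd.DataFrame(rows).set_index("gene_id")
    truth = truth.loc[[g.gene_id for g in genes]]

    _draw_dynamics(genes, truth, config, rng)
    if config.shuffle_profiles:
        _shuffle_dynamics(truth, rng)
    return genes, truth.reset_index()[_TRUTH_COLS]


_DYN_COLS = ["onset_min", "h0", "h1", "h2", "t1", "t2", "lambda1", "lambda2",
             "alpha", "beta", "base_expr"]


def _draw_dynamics(genes: list[GeneModel], truth: pd.DataFrame,
                   config: SimConfig, rng: np.random.Generator) -> None:
    for col in _DYN_COLS:
        truth[col] = np.nan

    # coding onsets drift along each chromosome: AR(1) over gene order
    lo, hi = config.onset_range_min
    mid, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    phi = config.onset_autocorr
    prev_chrom, prev = None, None
    for g in genes:
        if truth.at[g.gene_id, "is_background"] or g.biotype != "protein_coding":
            continue
        if g.chrom != prev_chrom or prev is None:
            onset = mid + sd * rng.standard_normal()
        else:
            onset = mid + phi * (prev - mid) + sd * np.sqrt(1 - phi ** 2) * rng.standard_normal()
        prev_chrom, prev = g.chrom, onset
        onset = float(np.clip(onset, lo, hi))
        dur = float(rng.uniform(40.0, 120.0))
        params = {"onset_min": onset,
                  "h0": float(rng.uniform(0.05, 0.15)),
                  "h1": float(rng.uniform(1.5, 4.0)),
                  "h2": 0.0, "t1": onset, "t2": onset + dur,
                  "lambda1": float(rng.uniform(0.1, 0.3)),
                  "lambda2": float(rng.uniform(0.1, 0.3))}
        params["h2"] = params["h1"] * float(rng.uniform(0.1, 0.5))
        hl = float(np.exp(rng.uniform(*np.log(config.halflife_range_min))))
        params["alpha"] = np.log(2.0) / hl
        params["beta"] = float(rng.uniform(0.5, 2.0))
        params["base_expr"] = float(rng.lognormal(np.log(200.0), 0.4))
        for k, v in params.items():
            truth.at[g.gene_id, k] = v

    # lncRNA dynamics: partner's impulse, amplitude-scaled and lagged
    for g in genes:
        row = truth.loc[g.gene_id]
        if row["is_background"]:
            _flat_row(truth, g.gene_id, rng)
            continue
        if g.biotype != "lncRNA":
            continue
        p = truth.loc[row["partner_id"]]
        amp = float(rng.uniform(0.5, 1.5))
        hl = float(np.exp(rng.uniform(*np.log(config.lnc_halflife_range_min))))
        vals = {"onset_min": p["onset_min"] + config.lnc_lag_min,
                "h0": amp * p["h0"], "h1": amp * p["h1"], "h2": amp * p["h2"],
                "t1": p["t1"] + config.lnc_lag_min,
                "t2": p["t2"] + config.lnc_lag_min,
                "lambda1": p["lambda1"], "lambda2": p["lambda2"],
                "alpha": np.log(2.0) / hl, "beta": float(rng.uniform(0.5, 2.0)),
                "base_expr": float(rng.lognormal(np.log(100.0), 0.4))}
        for k, v in vals.items():
            truth.at[g.gene_id, k] = v


def _flat_row(truth: pd.DataFrame, gene_id: str, rng: np.random.Generator) -> None:
    level = float(rng.uniform(0.3, 1.5))
    hl = float(np.exp(rng.uniform(np.log(30.0), np.log(300.0))))
    vals = {"onset_min": np.nan, "h0": level, "h1": level, "h2": level,
            "t1": 0.0, "t2": 400.0, "lambda1": 0.2, "lambda2": 0.2,
            "alpha": np.log(2.0) / hl, "beta": 1.0,
            "base_expr": float(rng.lognormal(np.log(150.0), 0.4))}
    for k, v in vals.items():
        truth.at[gene_id, k] = v


def _shuffle_dynamics(truth: pd.DataFrame, rng: np.random.Generator) -> None:
    """Permute dynamics across genes within each biotype, breaking any link
    between genomic position and expression profile (null fixture)."""
    for biotype in ("protein_coding", "lncRNA"):
        mask = (truth["biotype"] == biotype) & (~truth["is_background"])
        idx = truth.index[mask]
        perm = rng.permutation(len(idx))
        block = truth.loc[idx, _DYN_COLS].to_numpy()
        truth.loc[idx, _DYN_COLS] = block[perm]
    truth.loc[:, "partner_id"] = ""  # pairing no longer meaningful


def _impulse_of(row) -> ImpulseParams:
    return ImpulseParams(h0=float(row["h0"]), h1=float(row["h1"]),
                         h2=float(row["h2"]), t1=float(row["t1"]),
                         t2=float(row["t2"]), lambda1=float(row["lambda1"]),
                         lambda2=float(row["lambda2"]))


def _window_offsets(gene: GeneModel, intervals, step_bp: int = 500) -> np.ndarray:
    """Genomic distances from the TSS of sample points tiling the intervals."""
    pts = []
    for a, b in intervals:
        p = np.arange(a + step_bp / 2, b, step_bp)
        pts.append(p if p.size else np.array([(a + b) / 2.0]))
    pos = np.concatenate(pts)
    return np.abs(pos - gene.tss)


def _region_signal(params: ImpulseParams, offsets_bp: np.ndarray,
                   rate_kb_min: float, t: np.ndarray) -> np.ndarray:
    """Mean delayed impulse over the window: the transcription wave."""
    delays = offsets_bp / (rate_kb_min * 1000.0)  # minutes
    return impulse_eval(params, t[None, :] - delays[:, None]).mean(axis=0)


def expected_signals(genes: list[GeneModel], truth: pd.DataFrame,
                     config: SimConfig) -> pd.DataFrame:
    """Noise-free expectation surface (before depth scaling and NB noise).

    One row per (gene, region), measurement-grid columns in minutes.  The
    exon row is the ODE solution ``dM/dt = beta*P - alpha*M`` driven by the
    last-10-kb intron signal, started at its baseline steady state and
    rescaled to the gene's base expression level.
    """
    tinfo = truth.set_index("gene_id")
    t_fine = config.fine_times()
    times = config.times()
    sel = np.isin(np.round(t_fine, 9), np.round(times, 9))
    rate = config.elongation_rate_kb_per_min
    rows, data = [], []
    for g in genes:
        row = tinfo.loc[g.gene_id]
        params = _impulse_of(row)
        base = float(row["base_expr"])
        sig = {}
        for region, end in (("intron5p", "five_prime"), ("intron3p", "three_prime")):
            iv = region_windows(g, 10.0, end)
            offsets = _window_offsets(g, iv)
            sig[region] = _region_signal(params, offsets, rate, t_fine)
        alpha, beta = float(row["alpha"]), float(row["beta"])
        P = sig["intron3p"]
        M = integrate_model(t_fine, P, alpha, beta, m0=beta * P[0] / alpha)
        m_scale = base / max(M.mean(), 1e-12)
        for region in REGIONS:
            vals = M * m_scale if region == "exon" else base * sig[region]
            rows.append((g.gene_id, region))
            data.append(vals[sel])
    out = pd.DataFrame(data, columns=[f"{t:g}" for t in times])
    out.insert(0, "region", [r for _, r in rows])
    out.insert(0, "gene_id", [gid for gid, _ in rows])
    return out


def simulate_counts(genes: list[GeneModel], truth: pd.DataFrame,
                    config: SimConfig) -> pd.DataFrame:
    """Draw the count table: negative-binomial noise around depth-scaled
    expectations (Poisson when ``nb_dispersion == 0``).

    Layout: one row per (gene_id, region), one column per time point
    labelled in minutes.
    """
    lag_steps = config.lnc_lag_min / config.fine_step_min
    if abs(lag_steps - round(lag_steps)) > 1e-9:
        raise ValueError("lnc_lag_min must be a multiple of the internal fine grid "
                         f"({config.fine_step_min} min)")
    expect = expected_signals(genes, truth, config)
    times = config.times()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.depth_factors is not None:
        depth = np.asarray(config.depth_factors, dtype=float)
        if depth.size != times.size:
            raise ValueError("depth_factors length must match the time grid")
    else:
        depth = rng.lognormal(0.0, config.depth_sigma, size=times.size)
    mu = expect.iloc[:, 2:].to_numpy() * depth[None, :]
    mu = np.maximum(mu, 1e-9)
    if config.nb_dispersion > 0:
        n = 1.0 / config.nb_dispersion
        p = n / (n + mu)
        counts = rng.negative_binomial(n, p)
    else:
        counts = rng.poisson(mu)
    out = expect.iloc[:, :2].copy()
    for j, col in enumerate(expect.columns[2:]):
        out[col] = counts[:, j].astype(np.int64)
    return out


def write_fixture(genes: list[GeneModel], counts: pd.DataFrame,
                  truth: pd.DataFrame, out_dir: str, config: SimConfig,
                  force: bool = False) -> dict[str, str]:
    """Write GTF, BED12, counts TSV, truth TSV and a YAML manifest.

    Refuses to overwrite an existing manifest unless ``force`` is given.
    Returns the mapping of artifact names to paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, fname) for name, fname in
             [("gtf", "genes.gtf"), ("bed", "genes.bed"),
              ("counts", "counts.tsv"), ("truth", "truth.tsv"),
              ("manifest", "manifest.yaml")]}
    cfg = asdict(config)
    for key in ("halflife_range_min", "lnc_halflife_range_min", "gap_bp_range",
                "onset_range_min"):
        cfg[key] = list(cfg[key])
    if cfg["depth_factors"] is not None:
        cfg["depth_factors"] = list(cfg["depth_factors"])
    lio.write_manifest({"config": cfg, "seed": config.seed}, paths["manifest"],
                       force=force)
    lio.write_gtf(genes, paths["gtf"])
    lio.write_bed12(genes, paths["bed"])
    lio.write_counts(counts, paths["counts"])
    lio.write_truth(truth, paths["truth"])
    return paths
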