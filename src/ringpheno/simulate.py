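"""Synthetic common-garden datasets with known ground truth.

Emulates the study system the pipeline targets: ~38 provenances of a
temperate conifer spanning a mean-annual-temperature (MAT_p) gradient, grown
together in one garden (two blocks), cored once so each tree contributes one
ring-width series; one climate record at the garden; a ~128-SNP array with
cluster-structured allele frequencies and a few causal SNPs whose additive
effects shift climate sensitivity.

The generative growth model is multiplicative on the log scale,

    log BAI_t = Hugershoff(age_t) + sum_ch s_ch * z_ch(t) + event_t + eps_t,

where z_ch(t) is the detrended, unit-variance anomaly of one (variable,
month-label) climate channel and the per-tree sensitivity

    s_ch = base_ch + slope_ch * (MAT_p - mid) + sum_causal effect * dosage + noise

varies linearly with provenance temperature, so the chronology pipeline is
exactly well-specified under the null and clinal/causal signals are planted
with known sign and size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as clim
from .clinal import ProvenanceRecord
from .genetics import GenotypeMatrix
from .ringchron import RingSeries

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "simulate_climate",
    "simulate_provenances",
    "simulate_genotypes",
    "simulate_growth",
    "simulate_dataset",
]

EVENT_YEAR = 2003


@dataclass
class ChannelSpec:
    """One planted climate-sensitivity channel."""

    variable: str       # temp | prec | dc | freeze
    month_label: str    # e.g. "JUL(t)"
    base: float         # sensitivity at mid-gradient (log-BAI per SD anomaly)
    slope: float        # change in sensitivity per degC of MAT_p
    causal: bool = False  # do the causal SNPs act on this channel?


@dataclass
class SimConfig:
    seed: int
    n_populations: int = 38
    trees_per_population_mean: float = 6.13
    trees_per_population_sd: float = 1.51
    trees_per_population_range: tuple[int, int] = (2, 10)
    first_ring_year: int = 1989
    analysis_start: int = 1993
    analysis_end: int = 2014
    mat_p_range: tuple[float, float] = (1.0, 11.0)
    # climate at the garden
    site_mat: float = 4.5
    seasonal_amplitude: float = 15.5
    daily_ar: float = 0.75
    daily_sd: float = 3.2
    warming_per_year: float = 0.03
    # growth
    hugershoff: tuple[float, float, float, float] = (0.6, 0.7, 0.04, 4.5)
    growth_noise_sd: float = 0.25
    sensitivity_noise_sd: float = 0.01
    channels: tuple[ChannelSpec, ...] = (
        ChannelSpec("temp", "JUL(t)", base=-0.02, slope=-0.018, causal=True),
        ChannelSpec("freeze", "oct(t-1)", base=-0.02, slope=-0.006),
    )
    event_year: int = EVENT_YEAR
    event_base: float = -0.15
    event_slope_per_degc: float = -0.015
    # optional mean-growth cline (log-BAI per degC of MAT_p) and causal
    # mean-growth effect (log-BAI per minor allele) for type-A trait studies
    mean_growth_slope_per_degc: float = 0.0
    mean_growth_causal_effect: float = 0.0
    # genetics
    n_snps: int = 128
    n_causal_snps: int = 3
    causal_effect: float = 0.04  # on channel sensitivity per minor allele
    # (~0.5 SD of the realized tree-level CS trait at the defaults above)
    divergence: float = 0.10     # Balding-Nichols F among clusters
    n_clusters: int = 3
    missing_rate: float = 0.01
    causal_cline: float = 0.3    # allele-frequency shift across the MAT_p range

    @property
    def n_years(self) -> int:
        return self.analysis_end - self.analysis_start + 1


@dataclass
class SimTruth:
    channels: list[dict]
    causal_snps: list[str]
    causal_effect: float
    cluster_of_population: dict[str, int]
    sensitivity: dict[str, dict[str, float]]  # tree -> channel label -> s
    age_trend: dict[str, list[float]]         # tree -> (a, b, c, d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimBundle:
    config: SimConfig
    daily: pd.DataFrame
    monthly: pd.DataFrame
    provenances: list[ProvenanceRecord]
    tree_table: pd.DataFrame   # tree_id, population_id, block
    rings: list[RingSeries]
    genotypes: GenotypeMatrix
    truth: SimTruth


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_climate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily site climate (seasonal sinusoid + AR(1) anomalies + warming
    trend; gamma rainfall) and the derived monthly table."""
    if config.n_years < 10:
        raise ValueError("need >= 10 analysis years")
    rng = _rng(config.seed, 1)
    start = config.first_ring_year - 1
    dates = pd.date_range(f"{start}-01-01", f"{config.analysis_end}-12-31", freq="D")
    doy = dates.day_of_year.to_numpy()
    yrs = dates.year.to_numpy()
    n = len(dates)
    seasonal = config.site_mat - config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - 15) / 365.25
    )
    anom = np.empty(n)
    anom[0] = rng.normal(0, config.daily_sd)
    innov = rng.normal(0, config.daily_sd, size=n)
    for i in range(1, n):
        anom[i] = config.daily_ar * anom[i - 1] + innov[i]
    trend = config.warming_per_year * (yrs - yrs[0])
    tmean = seasonal + anom + trend
    dtr = np.maximum(rng.normal(8.0, 2.0, size=n), 2.0)
    tmin = tmean - dtr / 2.0
    wet = rng.random(n) < 0.45
    scale = 4.5 - 1.5 * np.cos(2 * np.pi * (doy - 15) / 365.25)  # wetter summer
    prec = np.where(wet, rng.gamma(0.7, scale, size=n), 0.0)
    daily = pd.DataFrame(
        {"date": dates, "tmean_C": tmean, "tmin_C": tmin, "prec_mm": prec}
    )
    dc = clim.daily_drought_code(daily)
    monthly = clim.monthly_aggregate(daily, dc_daily=dc)
    return daily, monthly


def simulate_provenances(config: SimConfig) -> list[ProvenanceRecord]:
    """Provenances laid on a south-north gradient so that MAT_p differences
    track geographic distance; MAP_p positively (but loosely) tied to MAT_p."""
    if config.n_populations < 4:
        raise ValueError("need >= 4 populations")
    rng = _rng(config.seed, 2)
    lo, hi = config.mat_p_range
    mat = np.linspace(lo, hi, config.n_populations)
    # warm provenances sit south: lat decreasing in MAT_p, plus scatter
    lat = 49.0 - 1.05 * (mat - lo) + rng.normal(0, 0.35, config.n_populations)
    lon = -72.0 + rng.normal(0, 3.0, config.n_populations)
    map_p = 900.0 + 35.0 * (mat - mat.mean()) + rng.normal(0, 220.0, config.n_populations)
    recs = []
    for i in range(config.n_populations):
        recs.append(
            ProvenanceRecord(f"P{i+1:02d}", float(lat[i]), float(lon[i]),
                             float(mat[i]), float(map_p[i]))
        )
    return recs


def _population_clusters(config: SimConfig, provenances) -> dict[str, int]:
    """Southern cluster = warmest two provenances; the rest split west/east."""
    mats = {p.population_id: p.mat_p for p in provenances}
    by_mat = sorted(mats, key=mats.get)
    south = set(by_mat[-2:]) if config.n_clusters >= 2 else set()
    lons = {p.population_id: p.lon for p in provenances}
    rest = [pid for pid in by_mat if pid not in south]
    med_lon = float(np.median([lons[p] for p in rest]))
    out = {}
    for p in provenances:
        pid = p.population_id
        if pid in south:
            out[pid] = 0
        elif config.n_clusters >= 3 and lons[pid] < med_lon:
            out[pid] = 1
        else:
            out[pid] = min(2, config.n_clusters - 1)
    return out


def _tree_table(config: SimConfig, provenances) -> pd.DataFrame:
    rng = _rng(config.seed, 3)
    lo, hi = config.trees_per_population_range
    rows = []
    for p in provenances:
        k = int(np.clip(round(rng.normal(config.trees_per_population_mean,
                                         config.trees_per_population_sd)), lo, hi))
        for j in range(k):
            rows.append(
                {
                    "tree_id": f"{p.population_id}T{j+1:02d}",
                    "population_id": p.population_id,
                    "block": 1 + (j % 2),
                }
            )
    return pd.DataFrame(rows)


def simulate_genotypes(
    config: SimConfig, provenances, tree_table: pd.DataFrame
) -> tuple[GenotypeMatrix, dict]:
    """Balding-Nichols cluster-structured SNPs plus clinal causal SNPs.

    Ancestral frequencies ~ U(0.10, 0.90); per-cluster frequencies drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes binomial within population.
    Causal SNP frequencies additionally shift linearly along MAT_p. A
    `missing_rate` fraction of calls is blanked at random.
    """
    if config.n_snps < config.n_causal_snps:
        raise ValueError("n_snps must be >= n_causal_snps")
    rng = _rng(config.seed, 4)
    clusters = _population_clusters(config, provenances)
    mats = {p.population_id: p.mat_p for p in provenances}
    lo, hi = config.mat_p_range
    mid = (lo + hi) / 2.0
    snp_ids = [f"S{j+1:03d}" for j in range(config.n_snps)]
    causal = list(rng.choice(snp_ids, size=config.n_causal_snps, replace=False))
    p_anc = rng.uniform(0.10, 0.90, config.n_snps)
    F = config.divergence
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_clust = rng.beta(
            np.tile(a, (config.n_clusters, 1)), np.tile(b, (config.n_clusters, 1))
        )
    else:
        p_clust = np.tile(p_anc, (config.n_clusters, 1))
    pops = tree_table["population_id"].to_numpy()
    n_trees = len(tree_table)
    codes = np.empty((n_trees, config.n_snps))
    causal_idx = [snp_ids.index(s) for s in causal]
    for i in range(n_trees):
        pid = pops[i]
        pc = p_clust[clusters[pid]].copy()
        for ci in causal_idx:
            shift = config.causal_cline * (mats[pid] - mid) / (hi - lo)
            pc[ci] = np.clip(p_anc[ci] + shift, 0.05, 0.95)
        codes[i] = rng.binomial(2, pc)
    # redraw columns whose realized MAF falls under the downstream filter so
    # the configured n_snps is the post-filter count
    for _ in range(20):
        p_real = codes.mean(axis=0) / 2.0
        maf = np.minimum(p_real, 1 - p_real)
        low = np.where(maf < 0.035)[0]
        if low.size == 0:
            break
        for ci in low:
            if ci in causal_idx:
                for i in range(n_trees):
                    pid = pops[i]
                    shift = config.causal_cline * (mats[pid] - mid) / (hi - lo)
                    codes[i, ci] = rng.binomial(2, np.clip(p_anc[ci] + shift, 0.05, 0.95))
            else:
                p_anc[ci] = rng.uniform(0.10, 0.90)
                if F > 0:
                    a_ci = p_anc[ci] * (1 - F) / F
                    b_ci = (1 - p_anc[ci]) * (1 - F) / F
                    p_clust[:, ci] = rng.beta(a_ci, b_ci, size=config.n_clusters)
                else:
                    p_clust[:, ci] = p_anc[ci]
                for i in range(n_trees):
                    codes[i, ci] = rng.binomial(2, p_clust[clusters[pops[i]], ci])
    miss = rng.random(codes.shape) < config.missing_rate
    codes[miss] = np.nan
    g = GenotypeMatrix(tree_table["tree_id"].tolist(), snp_ids, codes)
    return g, {"causal": causal, "clusters": clusters}


def _channel_anomalies(config: SimConfig, monthly: pd.DataFrame) -> dict[str, pd.Series]:
    """Unit-variance detrended anomalies per planted channel, by ring year."""
    det = clim.detrend_climate(monthly)
    years = np.arange(config.first_ring_year, config.analysis_end + 1)
    out = {}
    for ch in config.channels:
        wm = clim.build_window_matrix(det, ch.variable, years)
        col = wm[ch.month_label]
        sd = col.std(ddof=1)
        out[_chlabel(ch)] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return out


def _chlabel(ch: ChannelSpec) -> str:
    return f"{ch.variable}.{ch.month_label}"


def simulate_growth(
    config: SimConfig,
    monthly: pd.DataFrame,
    provenances,
    tree_table: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    causal_snps: list[str] | None = None,
) -> tuple[list[RingSeries], dict]:
    """Ring series whose interannual log-BAI anomalies respond to the planted
    climate channels, with population sensitivities varying along MAT_p and
    causal-SNP dosages shifting the causal channel. Widths are recovered from
    cumulative BAI. The event year adds a MAT_p-dependent negative shock."""
    rng = _rng(config.seed, 5)
    anoms = _channel_anomalies(config, monthly)
    years = np.arange(config.first_ring_year, config.analysis_end + 1)
    for lab, col in anoms.items():
        missing = np.setdiff1d(years, col.index.to_numpy())
        if missing.size:
            raise ValueError(f"climate does not cover ring years: {missing.tolist()}")
    mats = {p.population_id: p.mat_p for p in provenances}
    mid = sum(config.mat_p_range) / 2.0
    a0, b0, c0, d0 = config.hugershoff
    dose = None
    if genotypes is not None and causal_snps:
        idx = [genotypes.snp_ids.index(s) for s in causal_snps]
        dose_mat = genotypes.codes[:, idx]
        col_mean = np.nanmean(dose_mat, axis=0)
        dose_mat = np.where(np.isfinite(dose_mat), dose_mat, col_mean)
        # centered allele-substitution effects: the sample-average genetic
        # background is part of the baseline, not a shift on top of it
        dose_mat = dose_mat - col_mean
        dose = dict(zip(genotypes.tree_ids, dose_mat.sum(axis=1)))
    out = []
    sens_truth: dict[str, dict[str, float]] = {}
    age_truth: dict[str, list[float]] = {}
    age = np.arange(1, years.size + 1, dtype=float)
    for rec in tree_table.itertuples():
        tid, pid = rec.tree_id, rec.population_id
        a = a0 * np.exp(rng.normal(0, 0.2))
        d = d0 + rng.normal(0, 0.3)
        d += config.mean_growth_slope_per_degc * (mats[pid] - mid)
        if config.mean_growth_causal_effect and dose is not None:
            d += config.mean_growth_causal_effect * dose.get(tid, 0.0)
        logbai = a * age**b0 * np.exp(-c0 * age) + d
        sens_truth[tid] = {}
        for ch in config.channels:
            s = ch.base + ch.slope * (mats[pid] - mid)
            if ch.causal and dose is not None:
                s += config.causal_effect * dose.get(tid, 0.0)
            s += rng.normal(0, config.sensitivity_noise_sd)
            sens_truth[tid][_chlabel(ch)] = float(s)
            logbai = logbai + s * anoms[_chlabel(ch)].loc[years].to_numpy()
        if config.event_year in years:
            shock = config.event_base + config.event_slope_per_degc * (mats[pid] - mid)
            logbai[years == config.event_year] += shock
        logbai = logbai + rng.normal(0, config.growth_noise_sd, size=years.size)
        bai = np.exp(logbai)
        radius = np.sqrt(np.cumsum(bai) / np.pi)
        widths = np.diff(radius, prepend=0.0)
        out.append(RingSeries(tid, pid, int(rec.block), years.copy(), widths))
        age_truth[tid] = [float(a), b0, c0, float(d)]
    return out, {"sensitivity": sens_truth, "age_trend": age_truth}


def simulate_dataset(config: SimConfig, outdir=None, overwrite: bool = False) -> SimBundle:
    """Full bundle; optionally written to `outdir` in the formats the other
    modules consume (ring rwl + long CSV, daily/monthly climate CSV,
    provenance CSV, genotype CSV, truth JSON). Same seed => same bytes."""
    daily, monthly = simulate_climate(config)
    provenances = simulate_provenances(config)
    tree_table = _tree_table(config, provenances)
    genotypes, gmeta = simulate_genotypes(config, provenances, tree_table)
    rings, rmeta = simulate_growth(
        config, monthly, provenances, tree_table, genotypes, gmeta["causal"]
    )
    truth = SimTruth(
        channels=[asdict(ch) for ch in config.channels],
        causal_snps=gmeta["causal"],
        causal_effect=config.causal_effect,
        cluster_of_population=gmeta["clusters"],
        sensitivity=rmeta["sensitivity"],
        age_trend=rmeta["age_trend"],
    )
    bundle = SimBundle(config, daily, monthly, provenances, tree_table, rings,
                       genotypes, truth)
    if outdir is not None:
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()) and not overwrite:
            raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
        outdir.mkdir(parents=True, exist_ok=True)
        from .ringchron import write_long_csv, write_rwl

        write_rwl(rings, outdir / "rings.rwl")
        write_long_csv(rings, outdir / "rings.csv")
        daily.to_csv(outdir / "climate_daily.csv", index=False)
        monthly.to_csv(outdir / "climate_monthly.csv", index=False)
        pd.DataFrame([asdict(p) for p in provenances]).to_csv(
            outdir / "provenances.csv", index=False
        )
        tree_table.to_csv(outdir / "trees.csv", index=False)
        genotypes.to_csv(outdir / "genotypes.csv")
        truth.to_json(outdir / "truth.json")
    return bundle
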