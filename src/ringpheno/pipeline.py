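"""End-to-end orchestration: rings -> chronologies -> CS traits -> clinal
screen -> structure/kinship -> associations, under one config and one seed.

`run_pipeline` executes every stage on a dataset bundle (files or an
in-memory :class:`~ringpheno.simulate.SimBundle`) and returns a
:class:`RunReport` plus the stage outputs. `recovery_run` is the lighter
harness used to measure planted-signal recovery on synthetic data: it
computes only the phenotypes the planted signals live in, then runs the full
three-model association scan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import climate as clim
from .clinal import ClinalFit, fit_clinal_model, select_traits_for_gpa
from .dendroclim import cs_point_estimates, cs_profile, screen_cs_traits, type_a_traits
from .genetics import GenotypeMatrix, dapc, filter_genotypes, ritland_kinship
from .gpa import run_gpa_suite
from .ringchron import (
    Chronology,
    build_population_chronology,
    interseries_rbar,
    ringwidth_to_bai,
    standardize_series,
)
from .simulate import SimBundle, SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report", "recovery_run"]


@dataclass
class PipelineConfig:
    seed: int
    analysis_start: int = 1993
    analysis_end: int = 2014
    n_boot: int = 1000
    min_sig_populations: int = 5
    clinal_p: float = 0.01
    maf_min: float = 0.03
    alpha: float = 0.05
    dapc_k: int = 3
    event_year: int = 2003


@dataclass
class RunReport:
    n_populations: int = 0
    n_trees: int = 0
    n_years: int = 0
    rbar: float = float("nan")
    rbar_sd: float = float("nan")
    eps: float = float("nan")
    snps_before_filter: int = 0
    snps_after_filter: int = 0
    cs_traits_screened: int = 0
    traits_selected: list = field(default_factory=list)
    association_counts: dict = field(default_factory=dict)
    filters: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def build_chronologies(
    rings, start: int, end: int
) -> tuple[dict[str, Chronology], dict[str, Chronology], dict[str, list[str]]]:
    """Standardize every ring series and average within populations.

    Returns (tree-level, population-level, population membership), with the
    tree-level chronologies truncated to the analysis window.
    """
    tree_chron: dict[str, Chronology] = {}
    members: dict[str, list[str]] = {}
    for s in rings:
        bai = ringwidth_to_bai(s)
        c = standardize_series(bai, population_id=s.population_id, block=s.block)
        tree_chron[s.tree_id] = c.window(start, end)
        members.setdefault(s.population_id, []).append(s.tree_id)
    pop_chron = {
        pid: build_population_chronology([tree_chron[t] for t in tids], pid)
        for pid, tids in members.items()
    }
    return tree_chron, pop_chron, members


def run_pipeline(
    bundle: SimBundle,
    config: PipelineConfig,
    dendrometric: pd.DataFrame | None = None,
) -> tuple[RunReport, dict]:
    """Execute all stages on a dataset bundle; deterministic under the seed."""
    report = RunReport()
    out: dict = {}

    # --- chronologies -----------------------------------------------------
    ring_trees = {s.tree_id for s in bundle.rings}
    geno_trees = set(bundle.genotypes.tree_ids)
    missing = sorted(ring_trees - geno_trees)
    if missing:
        raise ValueError(f"trees absent from genotype data: {missing}")
    tree_chron, pop_chron, members = build_chronologies(
        bundle.rings, config.analysis_start, config.analysis_end
    )
    report.n_populations = len(pop_chron)
    report.n_trees = len(tree_chron)
    report.n_years = config.analysis_end - config.analysis_start + 1
    stats = interseries_rbar(list(tree_chron.values()))
    report.rbar, report.rbar_sd, report.eps = stats.rbar, stats.rbar_sd, stats.eps
    out["tree_chronologies"], out["population_chronologies"] = tree_chron, pop_chron

    # --- climate ----------------------------------------------------------
    monthly = clim.detrend_climate(bundle.monthly)
    years = np.arange(config.analysis_start, config.analysis_end + 1)
    windows = {
        v: clim.build_window_matrix(monthly, v, years) for v in clim.VARIABLES
    }
    out["windows"] = windows

    # --- CS traits at population level + screen ---------------------------
    cs_pop = []
    for i, (pid, chron) in enumerate(sorted(pop_chron.items())):
        cs_pop.extend(
            cs_profile(chron, windows, n_boot=config.n_boot, seed=config.seed + i)
        )
    eligible = screen_cs_traits(cs_pop, config.min_sig_populations)
    report.cs_traits_screened = len(eligible)
    report.filters.append(
        {"stage": "cs_screen", "before": len({(t.variable, t.month_label) for t in cs_pop}),
         "after": len(eligible)}
    )
    out["cs_population"] = cs_pop
    out["cs_eligible"] = eligible

    # --- clinal screen ----------------------------------------------------
    prov = {p.population_id: p for p in bundle.provenances}
    pids = sorted(pop_chron)
    mat_p = np.array([prov[p].mat_p for p in pids])
    blocks = bundle.tree_table.groupby("population_id")["block"].agg(
        lambda b: (b == 1).sum() / max((b == 2).sum(), 1)
    )
    block_ratio = blocks.loc[pids].to_numpy()

    fits: list[ClinalFit] = []
    pop_traits: dict[str, pd.Series] = {}

    bai_raw = {
        s.tree_id: ringwidth_to_bai(s) for s in bundle.rings
    }
    mean_bai_tree = type_a_traits(bai_raw, (config.analysis_start, config.analysis_end))
    mean_bai_pop = pd.Series(
        {pid: mean_bai_tree[members[pid]].mean() for pid in pids}
    )
    pop_traits["meanBAI"] = mean_bai_pop

    event = pd.Series({pid: pop_chron[pid].at(config.event_year) for pid in pids})
    pop_traits[f"BAI{config.event_year}"] = event

    cs_by_label: dict[tuple[str, str], dict[str, float]] = {}
    for t in cs_pop:
        cs_by_label.setdefault((t.variable, t.month_label), {})[t.unit_id] = t.r
    for key in eligible:
        var, lab = key
        pop_traits[f"CS_BAI-{var}.{lab}"] = pd.Series(cs_by_label[key])

    for name, series in pop_traits.items():
        is_cs = name.startswith("CS_")
        fits.append(
            fit_clinal_model(
                series.loc[pids].to_numpy(), mat_p, block_ratio,
                trait_name=name, allow_quadratic=not is_cs,
            )
        )
    out["clinal_fits"] = fits
    dendro_names = list(dendrometric.columns) if dendrometric is not None else []
    selected = select_traits_for_gpa(fits, config.clinal_p, dendro_names)
    report.traits_selected = selected
    report.filters.append(
        {"stage": "clinal_screen", "before": len(fits), "after": len(selected)}
    )

    # --- genetics ----------------------------------------------------------
    report.snps_before_filter = len(bundle.genotypes.snp_ids)
    g = filter_genotypes(bundle.genotypes, maf_min=config.maf_min)
    report.snps_after_filter = len(g.snp_ids)
    report.filters.append(
        {"stage": "snp_filter", "before": report.snps_before_filter,
         "after": report.snps_after_filter}
    )
    K = ritland_kinship(g)
    structure = dapc(g, k=config.dapc_k, seed=config.seed)
    out["kinship"], out["structure"] = K, structure

    # --- tree-level traits for GPA -----------------------------------------
    tree_ids = sorted(tree_chron)
    trait_tbl = pd.DataFrame(index=pd.Index(tree_ids, name="tree_id"))
    score_years = np.array(
        sorted(set.intersection(*(set(tree_chron[t].years.tolist()) for t in tree_ids)))
    )
    scores = np.vstack(
        [
            tree_chron[t].score[np.isin(tree_chron[t].years, score_years)]
            for t in tree_ids
        ]
    )
    for name in selected:
        if name == "meanBAI":
            trait_tbl[name] = mean_bai_tree.loc[tree_ids]
        elif name.startswith("BAI"):
            yr = int(name[3:])
            trait_tbl[name] = [tree_chron[t].at(yr) for t in tree_ids]
        elif name.startswith("CS_BAI-"):
            var, lab = name[len("CS_BAI-"):].split(".", 1)
            wm = windows[var]
            yrs = np.intersect1d(score_years, wm.index.to_numpy())
            sub = scores[:, np.isin(score_years, yrs)]
            trait_tbl[name] = cs_point_estimates(sub, wm[[lab]], yrs)[:, 0]
        elif dendrometric is not None and name in dendrometric.columns:
            trait_tbl[name] = dendrometric.loc[tree_ids, name]
    out["tree_traits"] = trait_tbl

    # --- associations -------------------------------------------------------
    blk = bundle.tree_table.set_index("tree_id")["block"]
    results = run_gpa_suite(
        trait_tbl, g, structure.covariates, K, block=blk, alpha=config.alpha
    )
    out["associations"] = results
    report.association_counts = (
        results["label"].value_counts().to_dict() if len(results) else {}
    )
    return report, out


def write_report(report: RunReport, path_prefix) -> None:
    """Human-readable text + machine-readable JSON run report."""
    report.to_json(f"{path_prefix}.json")
    lines = [
        "ringpheno run report",
        "====================",
        f"populations: {report.n_populations}; trees: {report.n_trees}; "
        f"years: {report.n_years}",
        f"chronology quality: rbar = {report.rbar:.2f} (SD {report.rbar_sd:.2f}), "
        f"EPS = {report.eps:.2f}",
        f"SNPs: {report.snps_before_filter} -> {report.snps_after_filter} after filtering",
        f"CS traits passing the population screen: {report.cs_traits_screened}",
        f"traits selected for association: {', '.join(report.traits_selected) or 'none'}",
        "association labels: "
        + ", ".join(f"{k}: {v}" for k, v in sorted(report.association_counts.items())),
        "filters:",
    ]
    for f in report.filters:
        lines.append(f"  {f['stage']}: {f['before']} -> {f['after']}")
    with open(f"{path_prefix}.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Planted-signal recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    clinal_p: float
    clinal_sign: int
    true_sign: int
    causal_labels: dict[str, str]
    null_very_likely_rate: float
    n_trees: int
    n_snps: int


def recovery_run(seed: int, config: SimConfig | None = None) -> RecoveryResult:
    """Simulate a default dataset and measure end-to-end signal recovery.

    Checks (1) the clinal regression of the causal-channel population CS
    trait on MAT_p (sign + p-value) and (2) the association labels of the
    planted causal SNPs vs the null SNPs on the tree-level CS trait.
    """
    cfg = config or SimConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = SimConfig(**{**asdict(config), "seed": seed})  # type: ignore[arg-type]
    bundle = simulate_dataset(cfg)
    tree_chron, pop_chron, members = build_chronologies(
        bundle.rings, cfg.analysis_start, cfg.analysis_end
    )
    monthly = clim.detrend_climate(bundle.monthly)
    years = np.arange(cfg.analysis_start, cfg.analysis_end + 1)
    causal_ch = next(ch for ch in cfg.channels if ch.causal)
    wm = clim.build_window_matrix(monthly, causal_ch.variable, years)

    pids = sorted(pop_chron)
    pop_scores = np.vstack([
        pop_chron[p].score[np.isin(pop_chron[p].years, years)] for p in pids
    ])
    pop_cs = cs_point_estimates(pop_scores, wm[[causal_ch.month_label]], years)[:, 0]
    prov = {p.population_id: p for p in bundle.provenances}
    mat_p = np.array([prov[p].mat_p for p in pids])
    fit = fit_clinal_model(pop_cs, mat_p, trait_name="CS_causal", allow_quadratic=False)

    tree_ids = sorted(tree_chron)
    tree_scores = np.vstack([
        tree_chron[t].score[np.isin(tree_chron[t].years, years)] for t in tree_ids
    ])
    tree_cs = cs_point_estimates(tree_scores, wm[[causal_ch.month_label]], years)[:, 0]
    traits = pd.DataFrame({"CS_causal": tree_cs}, index=pd.Index(tree_ids, name="tree_id"))

    g = filter_genotypes(bundle.genotypes)
    K = ritland_kinship(g)
    structure = dapc(g, k=cfg.n_clusters, seed=seed)
    blk = bundle.tree_table.set_index("tree_id")["block"]
    res = run_gpa_suite(traits, g, structure.covariates, K, block=blk)

    causal = set(bundle.truth.causal_snps)
    causal_labels = {
        r.snp: r.label for r in res.itertuples() if r.snp in causal
    }
    null = res[~res["snp"].isin(causal)]
    null_vl = float((null["label"] == "very likely").mean()) if len(null) else 0.0
    return RecoveryResult(
        clinal_p=fit.p_value,
        clinal_sign=fit.slope_sign,
        true_sign=int(np.sign(causal_ch.slope)),
        causal_labels=causal_labels,
        null_very_likely_rate=null_vl,
        n_trees=len(tree_ids),
        n_snps=len(g.snp_ids),
    )
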