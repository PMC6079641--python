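"""Clinal-variation screen: do tree-ring traits track provenance climate?

Population-level traits are regressed on the mean annual temperature of the
provenance (MAT_p). A linear and a quadratic model are compared by AIC; a
block-sample-size covariate is tried first and dropped when non-significant.
Traits with a highly significant cline (P < 0.01) pass to the association
stage. Mantel tests relate growth-similarity matrices to geographic and
climatic distances between provenances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ProvenanceRecord",
    "ClinalFit",
    "MantelResult",
    "fit_clinal_model",
    "mantel_test",
    "chronology_distance",
    "great_circle_km",
    "select_traits_for_gpa",
]


@dataclass
class ProvenanceRecord:
    population_id: str
    lat: float
    lon: float
    mat_p: float  # mean annual temperature of provenance, degC
    map_p: float  # mean annual precipitation of provenance, mm


@dataclass
class ClinalFit:
    trait: str
    model: str  # "linear" | "quadratic"
    aic_linear: float
    aic_quadratic: float
    adj_r2: float
    p_value: float
    slope_sign: int
    covariate_p: float | None
    covariate_used: bool
    degenerate: bool = False


@dataclass
class MantelResult:
    label: str
    r: float
    p: float
    n_perm: int


def fit_clinal_model(
    trait: np.ndarray,
    mat_p: np.ndarray,
    block_ratio: np.ndarray | None = None,
    trait_name: str = "",
    covariate_alpha: float = 0.05,
    allow_quadratic: bool = True,
) -> ClinalFit:
    """AIC-selected linear vs quadratic regression of a population trait on MAT_p.

    The overall-F p-value tests H0 "no relationship with MAT_p". The block
    sample-size ratio covariate is kept only if significant in a preliminary
    fit. AIC ties (|dAIC| < 1e-6) go to the simpler linear model.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(mat_p, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    cov = None
    if block_ratio is not None:
        cov = np.asarray(block_ratio, dtype=float)[ok]
    if y.size < 6:
        raise ValueError("need >= 6 populations for the clinal fit")
    if np.ptp(y) == 0:
        return ClinalFit(trait_name, "linear", np.nan, np.nan, 0.0, 1.0, 0, None,
                         False, degenerate=True)

    xc = x - x.mean()  # centering stabilises the quadratic term

    covariate_p = None
    use_cov = False
    if cov is not None and np.ptp(cov) > 0:
        pre = sm.OLS(y, sm.add_constant(np.column_stack([xc, cov]))).fit()
        covariate_p = float(pre.pvalues[-1])
        use_cov = covariate_p < covariate_alpha

    def _fit(design):
        return sm.OLS(y, sm.add_constant(design)).fit()

    lin_design = [xc]
    quad_design = [xc, xc**2]
    if use_cov:
        lin_design.append(cov)
        quad_design.append(cov)
    lin = _fit(np.column_stack(lin_design))
    quad = _fit(np.column_stack(quad_design)) if allow_quadratic else None

    # a numerically perfect linear fit cannot be improved upon; AIC computed
    # from ~zero residuals is rounding noise
    lin_perfect = lin.ssr <= 1e-12 * max(float(np.sum((y - y.mean()) ** 2)), 1e-300)
    if quad is not None and not lin_perfect and quad.aic < lin.aic - 1e-6:
        chosen, model = quad, "quadratic"
        slope_sign = int(np.sign(quad.params[2]))  # curvature sign
    else:
        chosen, model = lin, "linear"
        slope_sign = int(np.sign(lin.params[1]))
    return ClinalFit(
        trait=trait_name,
        model=model,
        aic_linear=float(lin.aic),
        aic_quadratic=float(quad.aic) if quad is not None else np.nan,
        adj_r2=float(chosen.rsquared_adj),
        p_value=float(chosen.f_pvalue),
        slope_sign=slope_sign,
        covariate_p=covariate_p,
        covariate_used=use_cov,
    )


def _offdiag_upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel_test(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    label: str = "",
    exhaustive: bool = False,
) -> MantelResult:
    """Two-sided Mantel test by simultaneous row/column permutation of B.

    p = (1 + #{|r*| >= |r|}) / (1 + n_perm); with ``exhaustive=True`` all n!
    permutations are enumerated instead (only sensible for tiny matrices) and
    p = #{|r*| >= |r|} / n!.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and of equal shape")
    for m, name in ((a, "A"), (b, "B")):
        if not np.allclose(m, m.T):
            raise ValueError(f"matrix {name} not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError(f"matrix {name} diagonal not zero")
    n = a.shape[0]
    va = _offdiag_upper(a)

    def _r(bmat):
        vb = _offdiag_upper(bmat)
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = _r(b)
    if exhaustive:
        count = total = 0
        for perm in permutations(range(n)):
            p_idx = np.array(perm)
            r_star = _r(b[np.ix_(p_idx, p_idx)])
            total += 1
            if abs(r_star) >= abs(r_obs) - 1e-12:
                count += 1
        return MantelResult(label, r_obs, count / total, total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        if abs(_r(b[np.ix_(p_idx, p_idx)])) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(label, r_obs, p, n_perm)


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in kilometres."""
    r_earth = 6371.0
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * r_earth * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def chronology_distance(
    pop_chronologies: dict[str, "np.ndarray | object"],
    provenances: list[ProvenanceRecord] | None = None,
) -> dict[str, pd.DataFrame]:
    """Distance matrices among populations.

    ``growth``: d_ij = 1 - r_ij between standardized residual chronologies
    (computed over common years). With provenance records also ``geo``
    (great-circle km) and ``dmat`` (|delta MAT_p|).
    """
    ids = sorted(pop_chronologies)
    series = {}
    for pid in ids:
        c = pop_chronologies[pid]
        if hasattr(c, "years"):
            series[pid] = (np.asarray(c.years), np.asarray(c.score, dtype=float))
        else:
            years, score = c
            series[pid] = (np.asarray(years), np.asarray(score, dtype=float))
    common = series[ids[0]][0]
    for pid in ids[1:]:
        common = np.intersect1d(common, series[pid][0])
    if common.size < 2:
        raise ValueError("fewer than 2 common years across population chronologies")
    mat = np.vstack([
        series[pid][1][np.searchsorted(series[pid][0], common)] for pid in ids
    ])
    r = np.corrcoef(mat)
    growth = 1.0 - r
    np.fill_diagonal(growth, 0.0)
    out = {"growth": pd.DataFrame(growth, index=ids, columns=ids)}
    if provenances is not None:
        recs = {p.population_id: p for p in provenances}
        npop = len(ids)
        geo = np.zeros((npop, npop))
        dmat = np.zeros((npop, npop))
        for i, pi in enumerate(ids):
            for j, pj in enumerate(ids):
                if i < j:
                    geo[i, j] = geo[j, i] = great_circle_km(
                        recs[pi].lat, recs[pi].lon, recs[pj].lat, recs[pj].lon
                    )
                    dmat[i, j] = dmat[j, i] = abs(recs[pi].mat_p - recs[pj].mat_p)
        out["geo"] = pd.DataFrame(geo, index=ids, columns=ids)
        out["dmat"] = pd.DataFrame(dmat, index=ids, columns=ids)
    return out


def select_traits_for_gpa(
    clinal_fits: list[ClinalFit],
    p_threshold: float = 0.01,
    dendrometric_traits: list[str] | None = None,
) -> list[str]:
    """Traits with clinal p < 0.01, plus externally measured dendrometric
    traits (DBH, height) which are always carried into the association stage."""
    kept = [f.trait for f in clinal_fits if np.isfinite(f.p_value) and f.p_value < p_threshold]
    if dendrometric_traits:
        kept.extend(t for t in dendrometric_traits if t not in kept)
    return kept
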