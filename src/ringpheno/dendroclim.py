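"""The three tree-ring phenotype classes.

Type A: period means of raw BAI / ring density (classic forestry metrics).
Type B: the standardized residual score of a single event year (e.g. the
growth collapse following the cold autumn 2002 / spring 2003).
Type C: climatic-sensitivity (CS) traits — bootstrapped Pearson correlations
between standardized residual growth scores and one monthly climate variable
in the 16-month window, at population or at individual-tree level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import VARIABLES
from .ringchron import BAISeries, Chronology

__all__ = [
    "CSTrait",
    "bootstrap_correlation",
    "cs_profile",
    "response_function",
    "type_a_traits",
    "type_b_trait",
    "screen_cs_traits",
]


@dataclass
class CSTrait:
    unit_id: str
    growth_metric: str  # "BAI" | "Dens"
    variable: str       # temp | prec | dc | freeze
    month_label: str
    r: float
    ci_low: float
    ci_high: float
    significant: bool
    n_years: int

    @property
    def label(self) -> str:
        return f"CS_{self.growth_metric}-{self.variable}.{self.month_label}"


def _pearson_boot(x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator,
                  batch: int = 1000) -> np.ndarray:
    """Percentile-bootstrap correlations from year resampling with replacement.

    Degenerate resamples (zero variance in either member) are redrawn.
    """
    n = x.size
    out = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        k = min(batch, n_boot - filled)
        idx = rng.integers(0, n, size=(k, n))
        xs, ys = x[idx], y[idx]
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        sx = np.sqrt((xs_c**2).sum(axis=1))
        sy = np.sqrt((ys_c**2).sum(axis=1))
        ok = (sx > 0) & (sy > 0)
        r = (xs_c * ys_c).sum(axis=1)[ok] / (sx[ok] * sy[ok])
        take = min(r.size, n_boot - filled)
        out[filled:filled + take] = r[:take]
        filled += take
    return out


def bootstrap_correlation(
    growth: np.ndarray,
    climate_col: np.ndarray,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator = 0,
    unit_id: str = "",
    growth_metric: str = "BAI",
    variable: str = "",
    month_label: str = "",
) -> CSTrait:
    """Pearson correlation with a percentile bootstrap CI over years.

    The association is called significant when the CI excludes zero.
    """
    x = np.asarray(growth, dtype=float)
    y = np.asarray(climate_col, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError(f"need >= 10 paired years, got {x.size}")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance series")
    r = float(np.corrcoef(x, y)[0, 1])
    boots = _pearson_boot(x, y, n_boot, rng)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    lo = float(min(lo, r))
    hi = float(max(hi, r))
    sig = bool(lo > 0 or hi < 0)
    return CSTrait(unit_id, growth_metric, variable, month_label, r, lo, hi, sig, x.size)


def cs_profile(
    chronology: Chronology,
    windows: dict[str, pd.DataFrame],
    n_boot: int = 1000,
    seed: int = 0,
    growth_metric: str = "BAI",
    ci_level: float = 0.95,
) -> list[CSTrait]:
    """One CS trait per (variable, month label) for one growth unit.

    `windows` maps variable name -> window matrix (rows indexed by ring year)
    from :func:`ringpheno.climate.build_window_matrix`. A fixed seed makes the
    whole profile bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    out = []
    for variable in VARIABLES:
        if variable not in windows:
            continue
        wm = windows[variable]
        years = np.intersect1d(chronology.years, wm.index.to_numpy())
        missing = np.setdiff1d(chronology.years, wm.index.to_numpy())
        if years.size < 10:
            raise ValueError(
                f"{chronology.id}: cannot align chronology with {variable} window; "
                f"missing years {missing.tolist()}"
            )
        g = np.array([chronology.at(int(y)) for y in years])
        for lab in wm.columns:
            if np.ptp(wm.loc[years, lab].to_numpy()) == 0:
                continue  # e.g. freezing days in summer months: always zero
            out.append(
                bootstrap_correlation(
                    g, wm.loc[years, lab].to_numpy(), n_boot=n_boot,
                    ci_level=ci_level, seed=rng, unit_id=chronology.id,
                    growth_metric=growth_metric, variable=variable, month_label=lab,
                )
            )
    return out


def cs_point_estimates(
    score_matrix: np.ndarray, window: pd.DataFrame, years: np.ndarray
) -> np.ndarray:
    """Correlation point estimates for many units at once (no bootstrap).

    `score_matrix` is units x years aligned with `years`; returns a
    units x n_labels array of Pearson correlations. Used where only the CS
    phenotype values are needed (e.g. as GPA traits), not their significance.
    """
    wm = window.loc[years].to_numpy(dtype=float)  # years x labels
    g = np.asarray(score_matrix, dtype=float)
    g_c = g - g.mean(axis=1, keepdims=True)
    w_c = wm - wm.mean(axis=0, keepdims=True)
    num = g_c @ w_c
    den = np.sqrt((g_c**2).sum(axis=1, keepdims=True) * (w_c**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def response_function(
    chronology: Chronology,
    window: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    eig_threshold: float = 1.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Principal-component response function.

    PCA on the standardized climate columns, keep components with eigenvalue
    above `eig_threshold`, regress the chronology on the retained scores and
    rotate the coefficients back to monthly space; significance by bootstrap
    over years. Complements the simple correlations by controlling for the
    collinearity of monthly predictors.
    """
    years = np.intersect1d(chronology.years, window.index.to_numpy())
    g = np.array([chronology.at(int(y)) for y in years])
    if np.std(g) == 0:
        raise ValueError("zero-variance chronology")
    X = window.loc[years].to_numpy(dtype=float)
    n, p = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("singular design: zero-variance climate column")
    Z = (X - mu) / sd

    def _coefs(zmat, yvec, rng_idx=None):
        if rng_idx is not None:
            zmat, yvec = zmat[rng_idx], yvec[rng_idx]
        u, s, vt = np.linalg.svd(zmat - zmat.mean(axis=0), full_matrices=False)
        eig = s**2 / (zmat.shape[0] - 1)
        k = max(1, int(np.sum(eig > eig_threshold)))
        k = min(k, zmat.shape[0] - 2)
        scores = u[:, :k] * s[:k]
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(yvec)), scores]), yvec, rcond=None
        )
        return vt[:k].T @ beta[1:]

    rng = np.random.default_rng(seed)
    point = _coefs(Z, g)
    boots = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.std(g[idx]) == 0:
            idx = rng.integers(0, n, size=n)
        boots[b] = _coefs(Z, g, idx)
    alpha = 1 - ci_level
    lo = np.quantile(boots, alpha / 2, axis=0)
    hi = np.quantile(boots, 1 - alpha / 2, axis=0)
    return pd.DataFrame(
        {
            "coef": point,
            "ci_low": np.minimum(lo, point),
            "ci_high": np.maximum(hi, point),
            "significant": (np.minimum(lo, point) > 0) | (np.maximum(hi, point) < 0),
        },
        index=window.columns,
    )


def type_a_traits(
    raw_series: dict[str, BAISeries] | dict[str, tuple[np.ndarray, np.ndarray]],
    period: tuple[int, int],
) -> pd.Series:
    """Arithmetic mean of raw annual values over the analysis period, per unit.

    Accepts BAISeries (mean BAI, mm^2/yr) or (years, values) pairs (e.g. ring
    density, kg/m^3). Computed from raw, not standardized, values.
    """
    start, end = period
    if end < start:
        raise ValueError("empty period")
    out = {}
    for uid, obj in raw_series.items():
        if isinstance(obj, BAISeries):
            years, vals = obj.years, obj.bai_mm2
        else:
            years, vals = obj
        years = np.asarray(years)
        m = (years >= start) & (years <= end)
        if not m.any():
            raise ValueError(f"{uid}: no data in period {start}-{end}")
        out[uid] = float(np.mean(np.asarray(vals, dtype=float)[m]))
    return pd.Series(out)


def type_b_trait(chronology: Chronology, year: int) -> float:
    """The standardized residual score for one event year.

    A value below 1 means growth below the unit's average level that year.
    """
    return chronology.at(year)


def screen_cs_traits(
    cs_by_population: list[CSTrait], min_populations: int = 5
) -> list[tuple[str, str]]:
    """Keep (variable, month label) pairs significant in >= `min_populations`
    populations — the variance screen applied before clinal testing."""
    counts: dict[tuple[str, str], int] = {}
    for t in cs_by_population:
        key = (t.variable, t.month_label)
        counts.setdefault(key, 0)
        if t.significant:
            counts[key] += 1
    kept = sorted(k for k, c in counts.items() if c >= min_populations)
    if not kept:
        warnings.warn("no CS trait significant in enough populations")
    return kept
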