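"""Ring-width ingestion, BAI conversion, detrending and chronology statistics.

The growth signal used throughout the pipeline is the *standardized residual
BAI score*: annual basal area increment is log-transformed, an age/size trend
is removed with a Hugershoff-type curve, serial autocorrelation is removed
with an AR model, and the residuals are exponentiated back so that the index
is a ratio-type score centered near 1 (a score of 0.7 in a given year means
growth 30% below the tree's expected level).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "RingSeries",
    "BAISeries",
    "Chronology",
    "ChronStats",
    "read_rwl",
    "write_rwl",
    "read_long_csv",
    "ringwidth_to_bai",
    "fit_hugershoff",
    "HugershoffFit",
    "standardize_series",
    "prewhiten_ar",
    "biweight_mean",
    "build_population_chronology",
    "interseries_rbar",
    "eps",
]

# Widths of exactly zero (locally absent rings) are floored before the log
# transform; interior missing years are rejected outright.
ZERO_RING_FLOOR_MM = 0.001


@dataclass
class RingSeries:
    """Per-tree annual ring widths with calendar years and garden labels."""

    tree_id: str
    population_id: str
    block: int
    years: np.ndarray
    width_mm: np.ndarray
    density_kgm3: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.width_mm = np.asarray(self.width_mm, dtype=float)
        if self.years.size != self.width_mm.size:
            raise ValueError(f"{self.tree_id}: years and widths differ in length")
        if self.years.size and np.any(np.diff(self.years) != 1):
            raise ValueError(
                f"{self.tree_id}: years must be strictly increasing and contiguous"
            )
        if np.any(self.width_mm < 0):
            raise ValueError(f"{self.tree_id}: negative ring width")
        if self.density_kgm3 is not None:
            self.density_kgm3 = np.asarray(self.density_kgm3, dtype=float)
            if self.density_kgm3.size != self.years.size:
                raise ValueError(f"{self.tree_id}: density length mismatch")


@dataclass
class BAISeries:
    """Per-tree annual basal area increment (mm^2 yr^-1)."""

    tree_id: str
    years: np.ndarray
    bai_mm2: np.ndarray


@dataclass
class Chronology:
    """Annual standardized residual index, at tree or population level."""

    level: str  # "tree" | "population"
    id: str
    years: np.ndarray
    score: np.ndarray
    n_series_per_year: np.ndarray = field(default=None)  # type: ignore[assignment]
    population_id: str | None = None
    block: int | None = None
    ar_order: int | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        if self.n_series_per_year is None:
            self.n_series_per_year = np.ones_like(self.years)
        if not np.all(np.isfinite(self.score)):
            raise ValueError(f"{self.id}: non-finite chronology score")

    def window(self, start: int, end: int) -> "Chronology":
        m = (self.years >= start) & (self.years <= end)
        return Chronology(
            self.level, self.id, self.years[m], self.score[m],
            self.n_series_per_year[m], self.population_id, self.block, self.ar_order,
        )

    def at(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"{self.id}: year {year} not in chronology")
        return float(self.score[idx[0]])


@dataclass
class ChronStats:
    rbar: float
    rbar_sd: float
    eps: float
    n_series: int


# ---------------------------------------------------------------------------
# Tucson (decadal) format
# ---------------------------------------------------------------------------

def read_rwl(path, units_mm: float = 0.01, meta: dict | None = None) -> list[RingSeries]:
    """Read a Tucson decadal ``.rwl`` file.

    Values are multiples of `units_mm` (0.01 mm by default; pass 0.001 for
    the -9999 dialect). `meta` optionally maps series id ->
    (population_id, block) since the Tucson format carries neither.
    """
    chunks: dict[str, dict[int, float]] = {}
    stop_values = {999, -9999}
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"{path}: empty ring-width file")
        return []
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed decade row: {line!r}")
        sid = parts[0]
        try:
            decade_year = int(parts[1])
            values = [int(v) for v in parts[2:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed decade row: {line!r}") from exc
        if len(values) > 10:
            raise ValueError(f"{path}:{lineno}: more than 10 values in decade row")
        series = chunks.setdefault(sid, {})
        for i, v in enumerate(values):
            if v in stop_values:
                break
            year = decade_year + i
            if year in series:
                raise ValueError(f"{path}:{lineno}: duplicate year {year} for series {sid}")
            series[year] = v * units_mm
    out = []
    for sid, yearmap in chunks.items():
        years = np.array(sorted(yearmap))
        widths = np.array([yearmap[y] for y in years])
        pop, block = (meta or {}).get(sid, (sid, 1))
        out.append(RingSeries(sid, pop, int(block), years, widths))
    return out


def write_rwl(series_list: list[RingSeries], path, units_mm: float = 0.01) -> None:
    """Write Tucson decadal rows with a 999 terminator after the last year."""
    with open(path, "w") as fh:
        for s in series_list:
            y0, y1 = int(s.years[0]), int(s.years[-1])
            vals = dict(zip(s.years.tolist(), s.width_mm.tolist()))
            year = y0
            while year <= y1:
                decade_end = (year // 10) * 10 + 9
                row_years = range(year, min(decade_end, y1) + 1)
                fields = [f"{s.tree_id:<8s}", f"{year:5d}"]
                for ry in row_years:
                    fields.append(f"{int(round(vals[ry] / units_mm)):6d}")
                if min(decade_end, y1) == y1:
                    fields.append(f"{999:6d}")
                fh.write("".join(fields) + "\n")
                year = decade_end + 1


def read_long_csv(path) -> list[RingSeries]:
    """Read the long-format alternative: tree_id, population_id, block, year,
    width_mm and optionally density_kgm3."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"tree_id", "population_id", "block", "year", "width_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("tree_id", sort=True):
        grp = grp.sort_values("year")
        dens = None
        if "density_kgm3" in grp.columns and grp["density_kgm3"].notna().all():
            dens = grp["density_kgm3"].to_numpy()
        out.append(
            RingSeries(
                str(tid),
                str(grp["population_id"].iloc[0]),
                int(grp["block"].iloc[0]),
                grp["year"].to_numpy(),
                grp["width_mm"].to_numpy(),
                dens,
            )
        )
    return out


def write_long_csv(series_list: list[RingSeries], path) -> None:
    import pandas as pd  # local to keep module import light

    rows = []
    for s in series_list:
        for i, y in enumerate(s.years):
            rec = {
                "tree_id": s.tree_id,
                "population_id": s.population_id,
                "block": s.block,
                "year": int(y),
                "width_mm": s.width_mm[i],
            }
            if s.density_kgm3 is not None:
                rec["density_kgm3"] = s.density_kgm3[i]
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BAI conversion
# ---------------------------------------------------------------------------

def ringwidth_to_bai(
    series: RingSeries,
    pith_offset_mm: float = 0.0,
    direction: str = "from_pith",
) -> BAISeries:
    """Convert ring widths to basal area increments.

    With cumulative radius R_t = pith_offset + sum_{i<=t} w_i the increment is
    pi * (R_t^2 - R_{t-1}^2). ``from_bark`` instead anchors the accumulation
    at the outermost (known total) radius, which is how cores taken bark-to-
    pith with a missing pith offset are usually handled.
    """
    if direction not in ("from_pith", "from_bark"):
        raise ValueError(f"invalid direction {direction!r}")
    if pith_offset_mm < 0:
        raise ValueError("pith offset must be >= 0")
    w = series.width_mm
    if direction == "from_pith":
        radius = pith_offset_mm + np.cumsum(w)
        inner = np.concatenate([[pith_offset_mm], radius[:-1]])
    else:
        total = pith_offset_mm + w.sum()
        outer_missing = total - np.cumsum(w[::-1])[::-1]  # radius before each ring
        inner = outer_missing
        radius = inner + w
    bai = np.pi * (radius**2 - inner**2)
    return BAISeries(series.tree_id, series.years.copy(), bai)


# ---------------------------------------------------------------------------
# Hugershoff detrending
# ---------------------------------------------------------------------------

@dataclass
class HugershoffFit:
    params: tuple[float, float, float, float]  # a, b, c, d
    fitted: np.ndarray
    converged: bool
    rss: float


def _hugershoff(t, a, b, c, d):
    return a * np.power(t, b) * np.exp(-c * t) + d


def _hugershoff_jac(t, a, b, c, d):
    core = np.power(t, b) * np.exp(-c * t)
    return np.column_stack([core, a * core * np.log(t), -a * core * t, np.ones_like(t)])


def fit_hugershoff(y: np.ndarray, t: np.ndarray | None = None) -> HugershoffFit:
    """Least-squares fit of the Hugershoff growth curve a*t^b*exp(-c*t)+d.

    `y` is the (typically log-transformed) series; `t` is cambial age 1..n.
    Constraints a>0, b>=0, c>=0 keep the curve in the unimodal family. Falls
    back to an ordinary linear trend (flagged converged=False) if the
    nonlinear fit fails or does no better than the line.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("series too short to detrend (need >= 8 years)")
    if t is None:
        t = np.arange(1, n + 1, dtype=float)
    else:
        t = np.asarray(t, dtype=float)

    # Linear fallback, also the benchmark the nonlinear fit must beat.
    slope, intercept = np.polyfit(t, y, 1)
    lin_fitted = intercept + slope * t
    lin_rss = float(np.sum((y - lin_fitted) ** 2))

    # Profile out (a, d): for fixed (b, c) the model is linear in them, so a
    # coarse grid plus one Levenberg-Marquardt polish is fast and robust.
    best = None
    for b in (0.0, 0.25, 0.5, 1.0, 1.5, 2.5):
        shape_b = np.power(t, b)
        for c in (0.0, 0.01, 0.03, 0.06, 0.12, 0.25):
            shape = shape_b * np.exp(-c * t)
            A = np.column_stack([shape, np.ones_like(t)])
            (a, d), *_ = np.linalg.lstsq(A, y, rcond=None)
            if a <= 0:
                continue
            rss = float(np.sum((y - (a * shape + d)) ** 2))
            if best is None or rss < best[1]:
                best = ((float(a), b, c, float(d)), rss)
    polished = None
    if best is not None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _hugershoff, t, y, p0=best[0],
                    bounds=([1e-12, 0.0, 0.0, -np.inf], [np.inf] * 4),
                    jac=_hugershoff_jac, maxfev=400,
                )
            fitted = _hugershoff(t, *popt)
            rss = float(np.sum((y - fitted) ** 2))
            if np.all(np.isfinite(fitted)) and rss <= best[1] + 1e-12:
                polished = (tuple(popt), rss, fitted)
        except (RuntimeError, ValueError):
            pass
    if polished is None and best is not None:
        popt, rss = best
        polished = (popt, rss, _hugershoff(t, *popt))
    if polished is not None and polished[1] <= lin_rss + 1e-12:
        popt, rss, fitted = polished
        return HugershoffFit(tuple(popt), fitted, True, rss)
    return HugershoffFit((0.0, 0.0, 0.0, float(intercept)), lin_fitted, False, lin_rss)


def prewhiten_ar(index: np.ndarray, p_max: int | None = None) -> tuple[np.ndarray, int]:
    """Remove serial autocorrelation with an AR(p) model chosen by AIC.

    Residuals are recentered to the pre-whitening mean so the index scale is
    preserved. The first p values (which have no full AR prediction) are
    passed through unchanged, keeping the series aligned on the calendar.
    """
    x = np.asarray(index, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("series too short to prewhiten (need >= 10)")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("zero variance input")
    if p_max is None:
        p_max = min(10, n // 4)
    mean = x.mean()
    # Conditional-least-squares AR(p), orders compared by AIC on the common
    # sample t = p_max..n (same likelihood basis for every order). The chosen
    # order is the smallest one within 2 AIC units of the minimum: models
    # closer than that are statistically indistinguishable, so parsimony wins.
    n_eff = n - p_max
    ycmp = x[p_max:]
    aics = np.full(p_max + 1, np.inf)
    for p in range(0, p_max + 1):
        X = np.column_stack(
            [np.ones(n_eff)] + [x[p_max - j : n - j] for j in range(1, p + 1)]
        )
        beta, *_ = np.linalg.lstsq(X, ycmp, rcond=None)
        rss = float(np.sum((ycmp - X @ beta) ** 2))
        if rss <= 0:
            continue
        aics[p] = n_eff * np.log(rss / n_eff) + 2 * (p + 1)
    best_p = int(np.argmax(aics <= aics.min() + 2.0))
    if best_p == 0:
        return x.copy(), 0
    p = best_p
    X = np.column_stack([np.ones(n - p)] + [x[p - j : n - j] for j in range(1, p + 1)])
    beta, *_ = np.linalg.lstsq(X, x[p:], rcond=None)
    out = x.copy()
    out[p:] = (x[p:] - X @ beta) + mean
    return out, p


def standardize_series(
    bai: BAISeries,
    ar: bool = True,
    p_max: int | None = None,
    floor: float = 1e-6,
    population_id: str | None = None,
    block: int | None = None,
) -> Chronology:
    """Log-scale Hugershoff detrending followed by AR prewhitening.

    index_t = exp(log(bai_t) - fit_t), a ratio-type score centered near 1.
    """
    y = np.maximum(np.asarray(bai.bai_mm2, dtype=float), floor)
    logy = np.log(y)
    fit = fit_hugershoff(logy)
    index = np.exp(logy - fit.fitted)
    order = None
    if ar:
        index, order = prewhiten_ar(index, p_max=p_max)
    return Chronology(
        "tree", bai.tree_id, bai.years.copy(), index,
        population_id=population_id, block=block, ar_order=order,
    )


# ---------------------------------------------------------------------------
# Robust averaging and chronology statistics
# ---------------------------------------------------------------------------

def biweight_mean(values, c: float = 9.0, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Tukey biweight robust location (tuning constant c, MAD scale)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("biweight_mean of empty input")
    if v.size == 1:
        return float(v[0])
    m = float(np.median(v))
    for _ in range(max_iter):
        mad = np.median(np.abs(v - m))
        if mad == 0:
            return m
        u = (v - m) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        new = float(np.sum(w * v) / w.sum())
        if abs(new - m) < tol:
            return new
        m = new
    return m


def build_population_chronology(
    tree_chronologies: list[Chronology], population_id: str
) -> Chronology:
    """Per-year biweight mean of tree-level scores within a population."""
    if not tree_chronologies:
        raise ValueError("no tree chronologies supplied")
    if len(tree_chronologies) == 1:
        warnings.warn(f"population {population_id}: single tree, pass-through chronology")
        c = tree_chronologies[0]
        return Chronology("population", population_id, c.years.copy(), c.score.copy(),
                          np.ones_like(c.years))
    common = tree_chronologies[0].years
    for c in tree_chronologies[1:]:
        common = np.intersect1d(common, c.years)
    if common.size == 0:
        raise ValueError(f"population {population_id}: no overlapping years")
    scores = np.empty(common.size)
    for i, y in enumerate(common):
        vals = [c.score[np.searchsorted(c.years, y)] for c in tree_chronologies]
        scores[i] = biweight_mean(vals)
    return Chronology(
        "population", population_id, common, scores,
        np.full(common.size, len(tree_chronologies)),
    )


def interseries_rbar(
    tree_chronologies: list[Chronology], min_overlap_years: int = 15
) -> ChronStats:
    """Mean (and SD) of all pairwise Pearson correlations over common years."""
    n = len(tree_chronologies)
    if n < 2:
        raise ValueError("need >= 2 series for rbar")
    rs = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = tree_chronologies[i], tree_chronologies[j]
            common, ia, ib = np.intersect1d(a.years, b.years, return_indices=True)
            if common.size < min_overlap_years:
                continue
            x, y = a.score[ia], b.score[ib]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    if not rs:
        raise ValueError("no series pair with sufficient overlap")
    rbar = float(np.mean(rs))
    rbar_sd = float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0
    e = eps(rbar, n) if rbar > 0 else float("nan")
    return ChronStats(rbar, rbar_sd, e, n)


def eps(rbar: float, n_series: int) -> float:
    """Expressed population signal: EPS = n*rbar / (n*rbar + (1 - rbar)).

    Quantifies how well an n-series chronology approximates the (infinite)
    population chronology; values above 0.85 are the conventional threshold
    for growth-climate work.
    """
    if not 0 < rbar <= 1:
        raise ValueError("EPS is defined for 0 < rbar <= 1")
    if n_series < 1:
        raise ValueError("need n_series >= 1")
    return n_series * rbar / (n_series * rbar + (1.0 - rbar))
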