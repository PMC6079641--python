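"""Genotype-phenotype association under three correction levels.

The full model is y = Xb + Sa + Qv + Zu + e with fixed block (b), SNP (a)
and structure-covariate (v) effects and a polygenic random effect
u ~ N(0, 2K sigma_a^2), e ~ N(0, sigma_e^2 I). Three nested corrections are
tested per SNP-trait pair: none (drop Q and u), Q (structure covariates
only) and Q+K (the full mixed model). Each pair is then classified by how
many of the three models reach P < alpha: 3 -> "very likely", 2 -> "likely",
1 -> "uncertain", 0 -> "no evidence". P-values are deliberately left
uncorrected for multiple testing.

The mixed model is solved EMMA-style: one spectral decomposition of 2K per
trait, REML estimation of the variance ratio delta = sigma_e^2/sigma_a^2 by
grid search plus golden-section refinement, then GLS F-tests for each SNP at
the optimum (P3D: variance components from the no-SNP null model are reused
across SNPs; a full per-SNP REML mode exists for small problems).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "glm_association",
    "mlm_association",
    "reml_delta",
    "classify_association",
    "run_gpa_suite",
    "AssociationResult",
    "LABELS",
]

LABELS = {3: "very likely", 2: "likely", 1: "uncertain", 0: "no evidence"}


@dataclass
class AssociationResult:
    snp: str
    trait: str
    p_none: float
    p_q: float
    p_qk: float
    effect_none: float
    effect_q: float
    effect_qk: float
    n_used: int
    label: str


@dataclass
class GLSFit:
    p_value: float
    effect: float
    se: float
    n: int
    delta: float | None = None
    sigma_a2: float | None = None
    sigma_e2: float | None = None


def _ftest_last(y, X):
    """OLS fit; partial F (== t^2) test of the last column of X."""
    n, q = X.shape
    XtX = X.T @ X
    try:
        XtXi = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None
    beta = XtXi @ (X.T @ y)
    resid = y - X @ beta
    df = n - q
    if df <= 0:
        return None
    s2 = float(resid @ resid) / df
    var_b = s2 * XtXi[-1, -1]
    if var_b <= 0 or not np.isfinite(var_b):
        return None
    t = beta[-1] / np.sqrt(var_b)
    p = 2 * stats.t.sf(abs(t), df)
    return float(p), float(beta[-1]), float(np.sqrt(var_b)), n


def _design(n, block=None, q_covariates=None):
    cols = [np.ones(n)]
    if block is not None:
        b = np.asarray(block)
        # dummy-code blocks (drop first level)
        for lev in np.unique(b)[1:]:
            cols.append((b == lev).astype(float))
    if q_covariates is not None:
        qc = np.atleast_2d(np.asarray(q_covariates, dtype=float))
        if qc.shape[0] != n:
            qc = qc.T
        cols.extend(qc.T)
    return np.column_stack(cols)


def glm_association(y, snp, block=None, q_covariates=None) -> GLSFit:
    """OLS of the trait on intercept + block (+ Q covariates) + SNP dosage.

    The SNP is tested with the partial F (equivalently t) test. Trees with a
    missing trait or genotype are dropped pairwise. Collinear designs (SNP
    confounded with covariates) yield p = NaN.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(snp, dtype=float)
    ok = np.isfinite(y) & np.isfinite(s)
    if block is not None:
        block = np.asarray(block)[ok]
    qc = None
    if q_covariates is not None:
        qc = np.atleast_2d(np.asarray(q_covariates, dtype=float))
        if qc.shape[0] != y.size:
            qc = qc.T
        qc = qc[ok]
    y, s = y[ok], s[ok]
    if y.size < 10:
        raise ValueError("need >= 10 trees with trait and genotype")
    if np.ptp(s) == 0:
        raise ValueError("SNP monomorphic in the tested subset")
    X = np.column_stack([_design(y.size, block, qc), s])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return GLSFit(np.nan, np.nan, np.nan, y.size)
    res = _ftest_last(y, X)
    if res is None:
        return GLSFit(np.nan, np.nan, np.nan, y.size)
    p, eff, se, n = res
    return GLSFit(p, eff, se, n)


# ---------------------------------------------------------------------------
# EMMA-style REML machinery
# ---------------------------------------------------------------------------

def _reml_loglik(delta: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Restricted log-likelihood (up to a constant) at variance ratio delta.

    lam: eigenvalues of G = 2K; yr, Xr: response/design rotated by the
    eigenvectors. V = sigma_a^2 (G + delta I) is diagonal in this basis.
    """
    w = lam + delta
    if np.any(w <= 0):
        return -np.inf
    Xw = Xr / w[:, None]
    XtVX = Xr.T @ Xw
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, Xw.T @ yr)
    r = yr - Xr @ beta
    quad = float(r @ (r / w))
    n, q = Xr.shape
    df = n - q
    if quad <= 0:
        return -np.inf
    sigma_a2 = quad / df
    return -0.5 * (
        df * np.log(2 * np.pi * sigma_a2) + df
        + float(np.sum(np.log(w))) + logdet_xvx
    )


def reml_delta(
    lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray,
    grid_points: int = 100, log10_range: tuple[float, float] = (-5.0, 5.0),
) -> tuple[float, float]:
    """REML variance ratio delta = sigma_e^2/sigma_a^2 by log-grid search with
    golden-section refinement. Returns (delta, restricted log-likelihood)."""
    grid = np.logspace(log10_range[0], log10_range[1], grid_points)
    lls = np.array([_reml_loglik(d, lam, yr, Xr) for d in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_reml_loglik(10**ld, lam, yr, Xr),
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(10**res.x)
    ll = _reml_loglik(delta, lam, yr, Xr)
    if lls[i] > ll:  # refinement must not lose the grid optimum
        delta, ll = float(grid[i]), float(lls[i])
    return delta, ll


def _gls_last(yr, Xr, w):
    """GLS fit with diagonal weights w; F-test on the last column."""
    Xw = Xr / w[:, None]
    XtVX = Xr.T @ Xw
    try:
        XtVXi = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError:
        return None
    beta = XtVXi @ (Xw.T @ yr)
    r = yr - Xr @ beta
    df = Xr.shape[0] - Xr.shape[1]
    if df <= 0:
        return None
    s2 = float(r @ (r / w)) / df
    var_b = s2 * XtVXi[-1, -1]
    if var_b <= 0 or not np.isfinite(var_b):
        return None
    t = beta[-1] / np.sqrt(var_b)
    p = 2 * stats.t.sf(abs(t), df)
    return float(p), float(beta[-1]), float(np.sqrt(var_b))


class MixedModelTrait:
    """Per-trait EMMA machinery: eigendecompose 2K once, estimate delta on
    the null (no-SNP) model, then test SNPs by GLS at that optimum (P3D)."""

    def __init__(self, y, K, block=None, q_covariates=None, jitter: float = 1e-6,
                 bend: bool = True):
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y)
        self.ok = ok
        self.y = y[ok]
        n = self.y.size
        K = np.asarray(K, dtype=float)[np.ix_(ok, ok)]
        G = 2.0 * K + jitter * np.eye(n)
        lam, U = np.linalg.eigh((G + G.T) / 2.0)
        if lam.min() < -1e-8 and not bend:
            raise ValueError("kinship matrix not positive semi-definite after jitter")
        # marker-based kinship estimates are routinely indefinite; bend by
        # clipping negative eigenvalues to zero (nearest-PSD in Frobenius norm)
        self.lam = np.maximum(lam, 0.0)
        self.U = U
        self.X0 = _design(
            n,
            None if block is None else np.asarray(block)[ok],
            None if q_covariates is None else np.atleast_2d(
                np.asarray(q_covariates, dtype=float)
            ).reshape(y.size, -1)[ok],
        )
        self.yr = U.T @ self.y
        self.X0r = U.T @ self.X0
        self.delta, self.ll = reml_delta(self.lam, self.yr, self.X0r)
        self.w = self.lam + self.delta
        df = n - self.X0.shape[1]
        # variance components at the null optimum
        Xw = self.X0r / self.w[:, None]
        beta = np.linalg.solve(self.X0r.T @ Xw, Xw.T @ self.yr)
        resid = self.yr - self.X0r @ beta
        self.sigma_a2 = float(resid @ (resid / self.w)) / df
        self.sigma_e2 = self.sigma_a2 * self.delta

    def test_snp(self, snp, p3d: bool = True) -> GLSFit:
        s = np.asarray(snp, dtype=float)[self.ok]
        miss = ~np.isfinite(s)
        if miss.any():
            # drop trees missing this SNP: refit on the subset (exact, still
            # one eigendecomposition because the rotation no longer applies --
            # fall back to a dense GLS on the subset at the same delta)
            keep = ~miss
            return self._test_subset(s[keep], keep, p3d=p3d)
        if np.ptp(s) == 0:
            return GLSFit(np.nan, np.nan, np.nan, self.y.size, self.delta,
                          self.sigma_a2, self.sigma_e2)
        Xr = np.column_stack([self.X0r, self.U.T @ s])
        if np.linalg.matrix_rank(Xr) < Xr.shape[1]:
            return GLSFit(np.nan, np.nan, np.nan, self.y.size, self.delta,
                          self.sigma_a2, self.sigma_e2)
        if p3d:
            res = _gls_last(self.yr, Xr, self.w)
            delta = self.delta
        else:
            delta, _ = reml_delta(self.lam, self.yr, Xr)
            res = _gls_last(self.yr, Xr, self.lam + delta)
        if res is None:
            return GLSFit(np.nan, np.nan, np.nan, self.y.size, delta,
                          self.sigma_a2, self.sigma_e2)
        p, eff, se = res
        return GLSFit(p, eff, se, self.y.size, delta, self.sigma_a2, self.sigma_e2)

    def _test_subset(self, s, keep, p3d: bool = True) -> GLSFit:
        if np.ptp(s) == 0:
            return GLSFit(np.nan, np.nan, np.nan, int(keep.sum()), self.delta,
                          self.sigma_a2, self.sigma_e2)
        G = (self.U * self.lam) @ self.U.T
        G = G[np.ix_(keep, keep)]
        lam, U = np.linalg.eigh((G + G.T) / 2.0)
        lam = np.maximum(lam, 0.0)
        yr = U.T @ self.y[keep]
        Xr = U.T @ np.column_stack([self.X0[keep], s])
        if np.linalg.matrix_rank(Xr) < Xr.shape[1]:
            return GLSFit(np.nan, np.nan, np.nan, int(keep.sum()))
        if p3d:
            delta = self.delta
        else:
            delta, _ = reml_delta(lam, yr, Xr)
        res = _gls_last(yr, Xr, lam + delta)
        if res is None:
            return GLSFit(np.nan, np.nan, np.nan, int(keep.sum()))
        p, eff, se = res
        return GLSFit(p, eff, se, int(keep.sum()), delta, self.sigma_a2, self.sigma_e2)


def mlm_association(y, snp, block, q_covariates, K, p3d: bool = False,
                    jitter: float = 1e-6) -> GLSFit:
    """Single SNP-trait mixed-model association (Q+K).

    Convenience wrapper around :class:`MixedModelTrait`; for SNP scans build
    the MixedModelTrait once per trait and call ``test_snp`` repeatedly.
    """
    mm = MixedModelTrait(y, K, block=block, q_covariates=q_covariates, jitter=jitter)
    return mm.test_snp(snp, p3d=p3d)


def classify_association(p_none, p_q, p_qk, alpha: float = 0.05) -> str:
    """Confidence label from the number of models significant at alpha.

    NaN p-values count as non-significant.
    """
    c = sum(1 for p in (p_none, p_q, p_qk) if np.isfinite(p) and 0 <= p < alpha)
    return LABELS[c]


def run_gpa_suite(
    traits: pd.DataFrame,
    genotypes,
    q_covariates: pd.DataFrame,
    K: pd.DataFrame,
    block=None,
    alpha: float = 0.05,
    p3d: bool = True,
) -> pd.DataFrame:
    """All SNP x trait combinations under the three correction levels.

    `traits`: trees x traits (index = tree ids); `genotypes`: GenotypeMatrix
    aligned by tree id; `q_covariates` and `K` labelled DataFrames. Returns
    one row per SNP-trait pair with the three p-values, effects and the
    confidence label. No multiple-testing correction is applied.
    """
    tree_ids = [t for t in traits.index if t in set(genotypes.tree_ids)]
    g = genotypes.subset_trees(tree_ids)
    Ksub = K.loc[tree_ids, tree_ids].to_numpy()
    np.fill_diagonal(Ksub, np.where(np.isfinite(np.diag(Ksub)), np.diag(Ksub), 0.5))
    qc = q_covariates.loc[tree_ids].to_numpy()
    blk = None if block is None else np.asarray(pd.Series(block).loc[tree_ids])
    rows = []
    for trait_name in traits.columns:
        y = traits.loc[tree_ids, trait_name].to_numpy(dtype=float)
        mm = MixedModelTrait(y, Ksub, block=blk, q_covariates=qc)
        for j, snp_id in enumerate(g.snp_ids):
            s = g.codes[:, j]
            try:
                fit_none = glm_association(y, s, block=blk)
            except ValueError:
                fit_none = GLSFit(np.nan, np.nan, np.nan, 0)
            try:
                fit_q = glm_association(y, s, block=blk, q_covariates=qc)
            except ValueError:
                fit_q = GLSFit(np.nan, np.nan, np.nan, 0)
            fit_qk = mm.test_snp(s, p3d=p3d)
            rows.append(
                AssociationResult(
                    snp_id, trait_name, fit_none.p_value, fit_q.p_value,
                    fit_qk.p_value, fit_none.effect, fit_q.effect, fit_qk.effect,
                    fit_qk.n, classify_association(
                        fit_none.p_value, fit_q.p_value, fit_qk.p_value, alpha
                    ),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
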