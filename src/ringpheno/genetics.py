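"""Genotype ingestion/filtering, Ritland marker-based kinship, and DAPC
population-structure covariates.

Kinship enters the mixed association model as 2K (so that the polygenic
variance component is the additive genetic variance). The Q matrix is the
posterior cluster-membership probability from a discriminant analysis of
principal components; with k clusters, k-1 columns act as fixed covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "GenotypeMatrix",
    "load_genotypes",
    "load_genotypes_vcf",
    "filter_genotypes",
    "ritland_kinship",
    "dapc",
    "DAPCResult",
]


@dataclass
class GenotypeMatrix:
    """Trees x SNPs additive minor-allele dosages (0/1/2, NaN = missing)."""

    tree_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray  # float array, NaN for missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.tree_ids), len(self.snp_ids)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing trees."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.codes, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    @property
    def snp_call_rate(self) -> np.ndarray:
        return np.mean(np.isfinite(self.codes), axis=0)

    @property
    def tree_call_rate(self) -> np.ndarray:
        return np.mean(np.isfinite(self.codes), axis=1)

    def to_minor(self) -> "GenotypeMatrix":
        """Re-express dosages as counts of the minor allele (sample-defined)."""
        codes = self.codes.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(codes, axis=0) / 2.0
        flip = p > 0.5
        codes[:, flip] = 2.0 - codes[:, flip]
        return GenotypeMatrix(list(self.tree_ids), list(self.snp_ids), codes)

    def subset_trees(self, tree_ids: list[str]) -> "GenotypeMatrix":
        pos = {t: i for i, t in enumerate(self.tree_ids)}
        missing = [t for t in tree_ids if t not in pos]
        if missing:
            raise ValueError(f"trees absent from genotype matrix: {missing}")
        idx = [pos[t] for t in tree_ids]
        return GenotypeMatrix(list(tree_ids), list(self.snp_ids), self.codes[idx])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.codes, index=self.tree_ids, columns=self.snp_ids).to_csv(
            path, index_label="tree_id", na_rep="NA"
        )


def load_genotypes(path, minor: bool = True) -> GenotypeMatrix:
    """Load trees x SNPs additive codes from CSV (NA = missing).

    With ``minor=True`` dosages are re-expressed as minor-allele counts on
    the loaded sample.
    """
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    g = GenotypeMatrix(
        [str(t) for t in df.index], [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
    )
    bad = ~np.isin(np.unique(g.codes[np.isfinite(g.codes)]), [0.0, 1.0, 2.0])
    if bad.any():
        raise ValueError(f"{path}: genotype codes outside {{0,1,2,NA}}")
    return g.to_minor() if minor else g


def load_genotypes_vcf(path, minor: bool = True) -> GenotypeMatrix:
    """Load a biallelic diploid VCF (GT field); multiallelic sites skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    tree_ids = list(vcf.samples)
    snp_ids, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"{var.ID or var.POS}: multiallelic site skipped")
            continue
        gts = var.genotype.array()[:, :2]
        col = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1))
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(col.astype(float))
    g = GenotypeMatrix(tree_ids, snp_ids, np.column_stack(cols))
    return g.to_minor() if minor else g


def filter_genotypes(
    g: GenotypeMatrix,
    maf_min: float = 0.03,
    snp_call_min: float = 0.5,
    tree_call_min: float | None = None,
) -> GenotypeMatrix:
    """Drop failed SNPs (call rate below `snp_call_min`), then SNPs with
    MAF strictly below `maf_min`. Trees are filtered only when
    `tree_call_min` is given (by default none are dropped)."""
    for thr in (maf_min, snp_call_min):
        if not 0 <= thr <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    keep_snp = g.snp_call_rate >= snp_call_min
    g2 = GenotypeMatrix(
        list(g.tree_ids),
        [s for s, k in zip(g.snp_ids, keep_snp) if k],
        g.codes[:, keep_snp],
    )
    keep_maf = g2.maf >= maf_min  # strict < maf_min is discarded
    g3 = GenotypeMatrix(
        list(g2.tree_ids),
        [s for s, k in zip(g2.snp_ids, keep_maf) if k],
        g2.codes[:, keep_maf],
    )
    if tree_call_min is not None:
        keep_tree = g3.tree_call_rate >= tree_call_min
        g3 = GenotypeMatrix(
            [t for t, k in zip(g3.tree_ids, keep_tree) if k],
            list(g3.snp_ids),
            g3.codes[keep_tree],
        )
    if len(g3.snp_ids) == 0:
        raise ValueError("all SNPs removed by filtering")
    return g3


def ritland_kinship(g: GenotypeMatrix, truncate_negative: bool = False) -> pd.DataFrame:
    """Ritland pairwise kinship from multilocus SNP dosages.

    Per biallelic locus k with sample allele frequency p (of the allele whose
    dosage is counted) and individual dosages P in {0, 0.5, 1} (half the 0/1/2
    code), the estimator for a pair (x, y) is

        r_k = (P_x*P_y/p + (1-P_x)*(1-P_y)/(1-p) - 1) / (m_k - 1)

    with m_k = 2 alleles; the multilocus value is the (m_k - 1)-weighted
    average over loci typed in both trees (here a plain average since every
    SNP has m_k = 2). Monomorphic loci are excluded. Negative estimates are
    kept unless `truncate_negative`.
    """
    codes = g.codes
    n, L = codes.shape
    if L < 2:
        raise ValueError("need >= 2 SNPs for kinship")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(codes, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    P = codes[:, poly] / 2.0
    p = p[poly]
    obs = np.isfinite(P)
    P0 = np.nan_to_num(P)
    Q0 = np.nan_to_num(1.0 - P)
    # per-pair sum over loci of P_x P_y / p + (1-P_x)(1-P_y)/(1-p), missing -> 0
    A = (P0 / p) @ P0.T + (Q0 / (1.0 - p)) @ Q0.T
    counts = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (A - counts) / counts  # mean over typed loci of (term - 1)/(m-1)
    K[counts == 0] = np.nan
    K = (K + K.T) / 2.0
    if truncate_negative:
        K = np.maximum(K, 0.0)
    return pd.DataFrame(K, index=g.tree_ids, columns=g.tree_ids)


@dataclass
class DAPCResult:
    q: pd.DataFrame                 # trees x k membership probabilities
    covariates: pd.DataFrame        # trees x (k-1) columns for the Q model
    assignments: np.ndarray
    n_pcs: int
    bic: pd.Series = field(default=None)  # type: ignore[assignment]


def _kmeans_bic(scores: np.ndarray, k: int, labels: np.ndarray) -> float:
    # BIC as used for DAPC k selection: n*log(WSS/n) + k*log(n)
    n = scores.shape[0]
    wss = 0.0
    for c in range(k):
        pts = scores[labels == c]
        if len(pts):
            wss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return n * np.log(wss / n) + k * np.log(n)


def dapc(
    g: GenotypeMatrix,
    k: int = 3,
    n_pcs: int | None = None,
    seed: int = 0,
    bic_range: range = range(1, 11),
) -> DAPCResult:
    """Discriminant analysis of principal components.

    Missing dosages are mean-imputed; columns centred/scaled; PCA retains
    `n_pcs` components (default: smallest number explaining >= 90% of the
    variance, capped at n_trees/3); k-means with `k` clusters on the PC
    scores; LDA posteriors on the clusters give the Q matrix. The BIC curve
    over `bic_range` is reported for diagnostics but k stays as configured.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = g.codes.copy()
    mu = np.nanmean(X, axis=0)
    ix = np.where(~np.isfinite(X))
    X[ix] = np.take(mu, ix[1])
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n = X.shape[0]
    cap = max(2, n // 3)
    pca = PCA(n_components=min(X.shape) - 1, svd_solver="full")
    all_scores = pca.fit_transform(X)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, 0.90) + 1)
        n_pcs = min(n_pcs, cap)
    if n_pcs >= n:
        raise ValueError("n_pcs must be < n_trees")
    scores = all_scores[:, :n_pcs]
    if k > len(np.unique(scores.round(12), axis=0)):
        raise ValueError("k exceeds the number of distinct genotype points")
    bic = {}
    for kk in bic_range:
        km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(scores)
        bic[kk] = _kmeans_bic(scores, kk, km.labels_)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
    labels = km.labels_
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, labels)
    q = lda.predict_proba(scores)
    qdf = pd.DataFrame(q, index=g.tree_ids, columns=[f"cluster{c}" for c in range(k)])
    cov = qdf.iloc[:, : k - 1].copy()
    cov.columns = [f"Q{c+1}" for c in range(k - 1)]
    return DAPCResult(qdf, cov, labels, n_pcs, pd.Series(bic, name="bic"))
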