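import numpy as np
import pandas as pd
import pytest

from ringpheno.genetics import (
    GenotypeMatrix,
    dapc,
    filter_genotypes,
    load_genotypes,
    load_genotypes_vcf,
    ritland_kinship,
)


def _gm(codes, tree_ids=None, snp_ids=None):
    codes = np.asarray(codes, dtype=float)
    tree_ids = tree_ids or [f"T{i}" for i in range(codes.shape[0])]
    snp_ids = snp_ids or [f"S{j}" for j in range(codes.shape[1])]
    return GenotypeMatrix(tree_ids, snp_ids, codes)


class TestLoading:
    def test_csv_round_trip_with_missing(self, tmp_path):
        g = _gm([[0, 1, np.nan], [2, 1, 0], [1, np.nan, 2], [0, 0, 1]])
        path = tmp_path / "g.csv"
        g.to_csv(path)
        back = load_genotypes(path, minor=False)
        np.testing.assert_array_equal(np.isnan(back.codes), np.isnan(g.codes))
        np.testing.assert_array_equal(
            back.codes[np.isfinite(back.codes)], g.codes[np.isfinite(g.codes)]
        )

    def test_maf_hand_count(self):
        g = _gm([[0], [0], [1], [2]])
        assert g.maf[0] == pytest.approx(3 / 8)

    def test_minor_allele_recoding(self):
        g = _gm([[2], [2], [2], [1]]).to_minor()  # p = 7/8 -> flip
        np.testing.assert_array_equal(g.codes[:, 0], [0, 0, 0, 1])

    def test_vcf_additive_codes(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
        )
        g = load_genotypes_vcf(vcf, minor=False)
        assert g.tree_ids == ["A", "B", "C"]
        np.testing.assert_array_equal(g.codes[:, 0], [0, 1, 2])
        assert np.isnan(g.codes[0, 1])
        np.testing.assert_array_equal(g.codes[1:, 1], [0, 1])


class TestFilter:
    def test_maf_boundary_strict(self):
        # 50 trees: one SNP at MAF 0.02 (2/100 alleles), one exactly 0.03
        n = 50
        low = np.zeros(n); low[:2] = 1     # MAF 0.02 -> dropped
        edge = np.zeros(n); edge[:3] = 1   # MAF 0.03 -> retained
        keep = np.zeros(n); keep[: n // 2] = 1
        g = _gm(np.column_stack([low, edge, keep]), snp_ids=["low", "edge", "keep"])
        out = filter_genotypes(g, maf_min=0.03)
        assert out.snp_ids == ["edge", "keep"]

    def test_counts_mirror_study_filtering(self):
        """153 assayed SNPs, 6 genotyping failures, 19 below MAF -> 128 kept."""
        rng = np.random.default_rng(0)
        n = 225
        cols, names = [], []
        for j in range(153):
            if j < 6:  # failed assays: almost entirely missing
                col = np.full(n, np.nan)
                col[:5] = rng.integers(0, 3, 5)
            elif j < 25:  # rare variants below the MAF filter
                col = np.zeros(n)
                col[: rng.integers(1, 13)] = 1  # MAF <= 12/450 < 0.03
            else:
                col = rng.binomial(2, rng.uniform(0.1, 0.9), n).astype(float)
            cols.append(col)
            names.append(f"S{j}")
        g = _gm(np.column_stack(cols), snp_ids=names)
        out = filter_genotypes(g, maf_min=0.03, snp_call_min=0.5)
        assert len(out.snp_ids) == 128

    def test_all_removed_errors(self):
        g = _gm(np.zeros((20, 3)))
        g.codes[0, :] = 1  # MAF 1/40 < 0.03 everywhere
        with pytest.raises(ValueError, match="all SNPs"):
            filter_genotypes(g)


class TestRitland:
    def test_hand_values_at_p_half(self):
        # two trees, opposite homozygotes at a locus with p = 0.5
        g = _gm([[2, 2], [0, 0]])
        K = ritland_kinship(g)
        assert K.loc["T0", "T1"] == pytest.approx(-1.0)
        assert K.loc["T0", "T0"] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(5, 10)).astype(float)
        codes[rng.random(codes.shape) < 0.15] = np.nan
        g = _gm(codes)
        K = ritland_kinship(g).to_numpy()

        p = np.nanmean(codes, axis=0) / 2.0
        expect = np.full((5, 5), np.nan)
        for x in range(5):
            for y in range(5):
                terms = []
                for k in range(10):
                    if not (np.isfinite(codes[x, k]) and np.isfinite(codes[y, k])):
                        continue
                    if p[k] <= 0 or p[k] >= 1:
                        continue
                    px, py = codes[x, k] / 2, codes[y, k] / 2
                    val = px * py / p[k] + (1 - px) * (1 - py) / (1 - p[k]) - 1
                    terms.append(val)  # (m_k - 1) = 1
                if terms:
                    expect[x, y] = np.mean(terms)
        np.testing.assert_allclose(K, expect, atol=1e-12)

    def test_symmetric_and_column_order_invariant(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(8, 12)).astype(float)
        g = _gm(codes)
        K1 = ritland_kinship(g).to_numpy()
        perm = rng.permutation(12)
        g2 = GenotypeMatrix(g.tree_ids, [g.snp_ids[j] for j in perm], codes[:, perm])
        K2 = ritland_kinship(g2).to_numpy()
        np.testing.assert_allclose(K1, K1.T, atol=1e-12)
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_unstructured_sample_centers_near_zero(self):
        rng = np.random.default_rng(3)
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 80), size=(150, 80)).astype(float)
        K = ritland_kinship(_gm(codes)).to_numpy()
        off = K[np.triu_indices(150, 1)]
        assert abs(off.mean()) < 0.02

    def test_monomorphic_locus_excluded(self):
        poly = np.array([[1, 0], [0, 2], [2, 1], [1, 1]], dtype=float)
        with_mono = np.column_stack([np.full(4, 2.0), poly])  # S0 fixed
        K_mono = ritland_kinship(_gm(with_mono))
        K_poly = ritland_kinship(_gm(poly))
        np.testing.assert_allclose(K_mono.to_numpy(), K_poly.to_numpy(), atol=1e-12)


class TestDAPC:
    def _two_cluster_geno(self, rng, n_per=40, n_snps=60, fst=0.2):
        p = rng.uniform(0.2, 0.8, n_snps)
        a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
        p1, p2 = rng.beta(a, b), rng.beta(a, b)
        codes = np.vstack([
            rng.binomial(2, p1, size=(n_per, n_snps)),
            rng.binomial(2, p2, size=(n_per, n_snps)),
        ]).astype(float)
        return _gm(codes), np.repeat([0, 1], n_per)

    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(4)
        g, truth = self._two_cluster_geno(rng)
        res = dapc(g, k=2, seed=0)
        own = np.array([res.q.iloc[i, res.assignments[i]] for i in range(len(truth))])
        assert np.mean(own > 0.9) >= 0.95
        agree = np.mean(res.assignments == truth)
        assert max(agree, 1 - agree) >= 0.95

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        g, _ = self._two_cluster_geno(rng, n_per=25)
        res = dapc(g, k=3, seed=0)
        np.testing.assert_allclose(res.q.sum(axis=1), 1.0, atol=1e-9)

    def test_k3_yields_two_covariates(self):
        rng = np.random.default_rng(6)
        g, _ = self._two_cluster_geno(rng, n_per=30)
        res = dapc(g, k=3, seed=0)
        assert res.covariates.shape[1] == 2

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        g, _ = self._two_cluster_geno(rng, n_per=20)
        perm = rng.permutation(len(g.tree_ids))
        g2 = GenotypeMatrix([g.tree_ids[i] for i in perm], g.snp_ids, g.codes[perm])
        q1 = dapc(g, k=2, seed=0).q
        q2 = dapc(g2, k=2, seed=0).q
        q2_aligned = q2.loc[q1.index]
        # cluster labels may swap; compare the membership structure
        direct = np.abs(q1.to_numpy() - q2_aligned.to_numpy()).max()
        swapped = np.abs(q1.to_numpy() - q2_aligned.to_numpy()[:, ::-1]).max()
        assert min(direct, swapped) < 1e-6

    def test_k_too_large_errors(self):
        g = _gm(np.tile([[0.0, 1.0]], (6, 1)))  # all trees identical
        with pytest.raises(ValueError):
            dapc(g, k=3, seed=0)
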