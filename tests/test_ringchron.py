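import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringpheno.ringchron import (
    BAISeries,
    RingSeries,
    biweight_mean,
    build_population_chronology,
    eps,
    fit_hugershoff,
    interseries_rbar,
    prewhiten_ar,
    read_rwl,
    ringwidth_to_bai,
    standardize_series,
    write_rwl,
)


def _series(widths, tree_id="T1", start=1993, pop="P1", block=1):
    widths = np.asarray(widths, dtype=float)
    years = np.arange(start, start + widths.size)
    return RingSeries(tree_id, pop, block, years, widths)


class TestRWL:
    def test_round_trip(self, tmp_path):
        s1 = _series([1.23, 0.98, 2.01, 1.5, 0.77], "TREE1")
        s2 = _series([0.5, 0.51, 0.52], "TREE2", start=2001)
        path = tmp_path / "x.rwl"
        write_rwl([s1, s2], path)
        back = {s.tree_id: s for s in read_rwl(path)}
        for s in (s1, s2):
            np.testing.assert_allclose(back[s.tree_id].width_mm, s.width_mm, atol=0.005)
            np.testing.assert_array_equal(back[s.tree_id].years, s.years)

    def test_hand_decoded_hundredth_mm(self, tmp_path):
        path = tmp_path / "h.rwl"
        path.write_text("TST01 1993 100 100 999\n")
        (s,) = read_rwl(path)
        np.testing.assert_allclose(s.width_mm, [1.00, 1.00])
        np.testing.assert_array_equal(s.years, [1993, 1994])

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "e.rwl"
        path.write_text("\n")
        with pytest.warns(UserWarning):
            assert read_rwl(path) == []

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.rwl"
        path.write_text("TST01 1993 100\nTST01 xxxx 100 999\n")
        with pytest.raises(ValueError, match=":2"):
            read_rwl(path)


class TestBAI:
    def test_single_ring(self):
        bai = ringwidth_to_bai(_series([1.0]))
        np.testing.assert_allclose(bai.bai_mm2, [np.pi])

    def test_two_rings_hand_value(self):
        bai = ringwidth_to_bai(_series([1.0, 1.0]))
        np.testing.assert_allclose(bai.bai_mm2, [np.pi, 3 * np.pi])

    def test_invalid_direction(self):
        with pytest.raises(ValueError, match="direction"):
            ringwidth_to_bai(_series([1.0]), direction="sideways")

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=1, max_size=40),
        st.floats(0.0, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation(self, widths, offset):
        """Sum of increments telescopes to pi*(R_n^2 - R_0^2)."""
        bai = ringwidth_to_bai(_series(widths), pith_offset_mm=offset)
        rn = offset + sum(widths)
        assert np.isclose(bai.bai_mm2.sum(), np.pi * (rn**2 - offset**2), rtol=1e-9)

    def test_from_bark_matches_from_pith_at_zero_offset(self):
        s = _series([1.0, 2.0, 0.5, 1.5])
        a = ringwidth_to_bai(s, direction="from_pith")
        b = ringwidth_to_bai(s, direction="from_bark")
        np.testing.assert_allclose(a.bai_mm2, b.bai_mm2)


class TestHugershoff:
    def test_exact_recovery_on_noiseless_curve(self):
        t = np.arange(1, 51, dtype=float)
        y = 2.0 * t**0.5 * np.exp(-0.05 * t) + 0.1
        fit = fit_hugershoff(y)
        assert fit.converged
        assert fit.rss < 1e-8

    def test_constant_series(self):
        fit = fit_hugershoff(np.full(20, 3.3))
        np.testing.assert_allclose(fit.fitted, 3.3, atol=1e-8)

    def test_never_worse_than_linear_oracle(self):
        rng = np.random.default_rng(3)
        t = np.arange(1, 41, dtype=float)
        y = 3.0 * np.exp(-0.08 * t) + 1.0 + rng.normal(0, 0.1, t.size)
        slope, intercept = np.polyfit(t, y, 1)
        lin_rss = np.sum((y - (intercept + slope * t)) ** 2)
        fit = fit_hugershoff(y)
        assert fit.rss <= lin_rss + 1e-12

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="too short"):
            fit_hugershoff(np.ones(5))


class TestStandardize:
    def test_on_curve_scores_are_one(self):
        t = np.arange(1, 31, dtype=float)
        logbai = 1.5 * t**0.4 * np.exp(-0.06 * t) + 4.0
        bai = BAISeries("T1", np.arange(1990, 2020), np.exp(logbai))
        c = standardize_series(bai, ar=False)
        np.testing.assert_allclose(c.score, 1.0, atol=1e-4)

    def test_doubled_year_scores_two(self):
        t = np.arange(1, 31, dtype=float)
        logbai = 1.5 * t**0.4 * np.exp(-0.06 * t) + 4.0
        vals = np.exp(logbai)
        vals[12] *= 2.0
        bai = BAISeries("T1", np.arange(1990, 2020), vals)
        c = standardize_series(bai, ar=False)
        assert c.score[12] == pytest.approx(2.0, abs=0.1)

    def test_centering_contract(self, small_bundle):
        for s in small_bundle.rings[:8]:
            c = standardize_series(ringwidth_to_bai(s))
            assert 0.95 <= c.score.mean() <= 1.05
            assert np.all(np.isfinite(c.score))


class TestPrewhiten:
    def test_white_noise_keeps_order_zero(self):
        rng = np.random.default_rng(7)
        hits = sum(prewhiten_ar(rng.normal(size=200))[1] == 0 for _ in range(100))
        assert hits >= 85

    def test_ar1_autocorrelation_removed(self):
        rng = np.random.default_rng(8)
        reduced = 0
        for _ in range(60):
            x = np.empty(150)
            x[0] = rng.normal()
            for t in range(1, 150):
                x[t] = 0.7 * x[t - 1] + rng.normal()
            out, p = prewhiten_ar(x)
            r1_in = np.corrcoef(x[:-1], x[1:])[0, 1]
            r1_out = np.corrcoef(out[:-1], out[1:])[0, 1]
            assert abs(r1_out) < 0.15
            if abs(r1_out) < abs(r1_in):
                reduced += 1
        assert reduced >= 57  # >=95% of replicates

    def test_mean_preserved_under_shift(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=80)
        for t in range(1, 80):
            x[t] = 0.5 * x[t - 1] + x[t]
        out, _ = prewhiten_ar(x)
        out_shift, _ = prewhiten_ar(x + 10.0)
        np.testing.assert_allclose(out_shift, out + 10.0, atol=1e-8)
        # recentering keeps the residual series on the input's level
        assert out.mean() == pytest.approx(x.mean(), abs=0.1)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            prewhiten_ar(np.ones(50))


class TestBiweight:
    def test_identical_values(self):
        assert biweight_mean([5, 5, 5]) == 5

    def test_symmetric(self):
        assert biweight_mean([1, 2, 3]) == pytest.approx(2.0)

    def test_outlier_downweighted_vs_mean(self):
        vals = [1.0, 1.1, 0.9, 1.05, 8.0]
        bw = biweight_mean(vals)
        med, mean = np.median(vals), np.mean(vals)
        assert abs(bw - med) < 0.05
        assert abs(bw - med) < abs(mean - med)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            biweight_mean([])


class TestPopulationChronology:
    def _chron(self, scores, tid="T1"):
        from ringpheno.ringchron import Chronology

        return Chronology("tree", tid, np.arange(2000, 2000 + len(scores)), scores)

    def test_identical_trees_pass_through(self):
        c = [self._chron([1.0, 1.1, 0.9, 1.05] * 5, f"T{i}") for i in range(3)]
        pop = build_population_chronology(c, "P1")
        np.testing.assert_allclose(pop.score, c[0].score)

    def test_outlier_year_robust(self):
        rng = np.random.default_rng(4)
        base = 1 + rng.normal(0, 0.05, 20)
        # five trees with distinct small deviations; one disturbed year
        scores = [base + rng.normal(0, 0.02, 20) for _ in range(5)]
        scores[0][10] = 4.0
        pop = build_population_chronology(
            [self._chron(s, f"T{i}") for i, s in enumerate(scores)], "P1"
        )
        plain = np.mean([s[10] for s in scores])
        clean = np.mean([s[10] for s in scores[1:]])
        assert pop.score[10] < plain
        assert abs(pop.score[10] - clean) < abs(plain - clean)

    def test_single_tree_warns(self):
        with pytest.warns(UserWarning, match="single tree"):
            pop = build_population_chronology([self._chron([1.0, 1.2, 0.8])], "P1")
        np.testing.assert_allclose(pop.score, [1.0, 1.2, 0.8])

    def test_no_overlap_errors(self):
        from ringpheno.ringchron import Chronology

        a = Chronology("tree", "A", np.arange(1990, 1995), np.ones(5) + 0.1)
        b = Chronology("tree", "B", np.arange(2000, 2005), np.ones(5) - 0.1)
        with pytest.raises(ValueError, match="overlap"):
            build_population_chronology([a, b], "P1")


class TestRbarEPS:
    def _chron(self, scores, tid):
        from ringpheno.ringchron import Chronology

        return Chronology("tree", tid, np.arange(1990, 1990 + len(scores)), scores)

    def test_identical_pair(self):
        s = np.sin(np.arange(20.0)) + 2
        st_ = interseries_rbar([self._chron(s, "A"), self._chron(s, "B")])
        assert st_.rbar == pytest.approx(1.0)

    def test_negated_pair(self):
        s = np.sin(np.arange(20.0))
        st_ = interseries_rbar([self._chron(s, "A"), self._chron(-s, "B")])
        assert st_.rbar == pytest.approx(-1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        chrons = [self._chron(rng.normal(size=25), f"T{i}") for i in range(5)]
        st_ = interseries_rbar(chrons)
        rs = []
        for i in range(5):
            for j in range(i + 1, 5):
                rs.append(np.corrcoef(chrons[i].score, chrons[j].score)[0, 1])
        assert st_.rbar == pytest.approx(np.mean(rs), abs=1e-12)
        assert st_.rbar_sd == pytest.approx(np.std(rs, ddof=1), abs=1e-12)

    def test_eps_closed_forms(self):
        assert eps(1.0, 17) == pytest.approx(1.0)
        assert eps(0.5, 1) == pytest.approx(0.5)

    def test_eps_monotone_in_n(self):
        for rbar in (0.2, 0.5, 0.85):
            vals = [eps(rbar, n) for n in range(1, 60)]
            assert np.all(np.diff(vals) > 0)

    def test_eps_rejects_nonpositive_rbar(self):
        with pytest.raises(ValueError):
            eps(0.0, 10)
        with pytest.raises(ValueError):
            eps(-0.3, 10)
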