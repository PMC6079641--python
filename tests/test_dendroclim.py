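import numpy as np
import pandas as pd
import pytest

from ringpheno.climate import build_window_matrix, window_labels
from ringpheno.dendroclim import (
    CSTrait,
    bootstrap_correlation,
    cs_point_estimates,
    cs_profile,
    response_function,
    screen_cs_traits,
    type_a_traits,
    type_b_trait,
)
from ringpheno.ringchron import BAISeries, Chronology


def _chron(scores, years=None, cid="P1"):
    years = np.arange(1993, 1993 + len(scores)) if years is None else years
    return Chronology("population", cid, years, np.asarray(scores, dtype=float))


def _windows(years, rng, variables=("temp",)):
    rows = []
    for y in range(years[0] - 1, years[-1] + 1):
        for mo in range(1, 13):
            rows.append({"year": y, "month": mo,
                         "temp_C": rng.normal(), "prec": rng.normal(),
                         "dc": rng.normal(), "freeze_days": rng.normal()})
    monthly = pd.DataFrame(rows)
    return {v: build_window_matrix(monthly, v, years) for v in variables}


class TestBootstrapCorrelation:
    def test_identical_series(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=22)
        t = bootstrap_correlation(x, x, seed=1)
        assert t.r == pytest.approx(1.0)
        assert t.significant

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=22), rng.normal(size=22)
        a = bootstrap_correlation(x, y, seed=42)
        b = bootstrap_correlation(x, y, seed=42)
        assert (a.r, a.ci_low, a.ci_high) == (b.r, b.ci_low, b.ci_high)

    def test_ci_significance_equivalence(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.normal(size=22)
            y = 0.5 * x + rng.normal(size=22)
            t = bootstrap_correlation(x, y, seed=int(rng.integers(1 << 30)))
            assert t.ci_low <= t.r <= t.ci_high
            assert t.significant == (not (t.ci_low <= 0 <= t.ci_high))

    def test_planted_correlation_covered(self):
        rng = np.random.default_rng(3)
        hits = 0
        true_r = 0.8 / np.sqrt(0.8**2 + 0.6**2)
        for i in range(40):
            x = rng.normal(size=22)
            y = 0.8 * x + rng.normal(0, 0.6, 22)
            t = bootstrap_correlation(x, y, seed=i)
            if t.ci_low <= true_r <= t.ci_high:
                hits += 1
        assert hits >= 36  # >=90% coverage

    def test_too_few_years(self):
        with pytest.raises(ValueError, match="10"):
            bootstrap_correlation(np.ones(5), np.ones(5) * 2, seed=0)


class TestCSProfile:
    def test_trait_count(self):
        rng = np.random.default_rng(4)
        years = np.arange(1994, 2015)
        wins = _windows(years, rng, ("temp", "prec", "dc", "freeze"))
        chron = _chron(1 + rng.normal(0, 0.1, years.size), years)
        traits = cs_profile(chron, wins, n_boot=100, seed=0)
        # 16 labels for temp/prec/freeze, 10 in-season labels for dc
        assert len(traits) == 3 * 16 + 10
        assert len(traits) <= 64

    def test_bit_reproducible(self):
        rng = np.random.default_rng(5)
        years = np.arange(1994, 2015)
        wins = _windows(years, rng)
        chron = _chron(1 + rng.normal(0, 0.1, years.size), years)
        a = cs_profile(chron, wins, n_boot=200, seed=9)
        b = cs_profile(chron, wins, n_boot=200, seed=9)
        assert [(t.r, t.ci_low, t.ci_high) for t in a] == [
            (t.r, t.ci_low, t.ci_high) for t in b
        ]

    def test_planted_signal_is_top_label(self):
        rng = np.random.default_rng(6)
        years = np.arange(1994, 2015)
        hits = 0
        for rep in range(20):
            wins = _windows(years, np.random.default_rng(100 + rep))
            sig = wins["temp"]["JUL(t)"].to_numpy()
            chron = _chron(1 + 0.5 * sig + rng.normal(0, 0.15, years.size), years)
            traits = cs_profile(chron, wins, n_boot=100, seed=rep)
            top = max(traits, key=lambda t: abs(t.r))
            if (top.variable, top.month_label) == ("temp", "JUL(t)"):
                hits += 1
        assert hits >= 18

    def test_population_of_identical_trees_matches_tree_cs(self):
        rng = np.random.default_rng(7)
        years = np.arange(1994, 2015)
        wins = _windows(years, rng)
        scores = 1 + rng.normal(0, 0.1, years.size)
        tree = _chron(scores, years, "T1")
        pop = _chron(scores, years, "P1")
        rt = {t.month_label: t.r for t in cs_profile(tree, wins, n_boot=100, seed=0)}
        rp = {t.month_label: t.r for t in cs_profile(pop, wins, n_boot=100, seed=0)}
        assert rt == rp

    def test_point_estimates_match_corrcoef(self):
        rng = np.random.default_rng(8)
        years = np.arange(1994, 2015)
        wins = _windows(years, rng)
        mat = 1 + rng.normal(0, 0.1, (4, years.size))
        cs = cs_point_estimates(mat, wins["temp"], years)
        for i in range(4):
            for j, lab in enumerate(wins["temp"].columns):
                expect = np.corrcoef(mat[i], wins["temp"].loc[years, lab])[0, 1]
                assert cs[i, j] == pytest.approx(expect, abs=1e-12)


class TestResponseFunction:
    def test_orthogonal_design_matches_marginal_slopes(self):
        rng = np.random.default_rng(9)
        n = 40
        q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        X = q * np.sqrt(n - 1)  # orthonormal columns scaled to unit variance
        y = 1 + 0.5 * X[:, 0] - 0.3 * X[:, 2] + rng.normal(0, 0.01, n)
        years = np.arange(1960, 1960 + n)
        wm = pd.DataFrame(X, index=pd.Index(years, name="year"),
                          columns=["a", "b", "c"])
        chron = Chronology("population", "P", years, y)
        rf = response_function(chron, wm, n_boot=100, seed=0, eig_threshold=0.0)
        marginal = [np.polyfit((X[:, j] - X[:, j].mean()) / X[:, j].std(ddof=1), y, 1)[0]
                    for j in range(3)]
        np.testing.assert_allclose(rf["coef"], marginal, atol=0.02)

    def test_planted_month_dominates(self):
        rng = np.random.default_rng(10)
        years = np.arange(1994, 2015)
        wins = _windows(years, rng)
        sig = wins["temp"]["MAY(t)"].to_numpy()
        chron = _chron(1 + 0.4 * sig + rng.normal(0, 0.05, years.size), years)
        rf = response_function(chron, wins["temp"], n_boot=100, seed=0)
        assert rf["coef"].abs().idxmax() == "MAY(t)"

    def test_zero_variance_chronology_errors(self):
        rng = np.random.default_rng(11)
        years = np.arange(1994, 2015)
        wins = _windows(years, rng)
        with pytest.raises(ValueError, match="zero-variance"):
            response_function(_chron(np.ones(years.size), years), wins["temp"],
                              n_boot=100, seed=0)


class TestTypeATypeB:
    def test_constant_bai_mean(self):
        years = np.arange(1993, 2015)
        series = {"T1": BAISeries("T1", years, np.full(years.size, 10.0))}
        out = type_a_traits(series, (1993, 2014))
        assert out["T1"] == pytest.approx(10.0)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(12)
        years = np.arange(1990, 2015)
        vals = rng.gamma(5, 100, years.size)
        out = type_a_traits({"T1": (years, vals)}, (1995, 2005))
        expect = vals[(years >= 1995) & (years <= 2005)].mean()
        assert out["T1"] == pytest.approx(expect, abs=1e-12)

    def test_empty_period_errors(self):
        years = np.arange(1993, 2015)
        series = {"T1": BAISeries("T1", years, np.ones(years.size))}
        with pytest.raises(ValueError):
            type_a_traits(series, (2014, 1993))

    def test_event_year_score(self):
        c = _chron(np.ones(22))
        assert type_b_trait(c, 2003) == 1.0
        with pytest.raises(KeyError):
            type_b_trait(c, 1800)


class TestScreen:
    def _trait(self, variable, label, sig, uid):
        r = 0.5 if sig else 0.1
        lo, hi = (0.2, 0.8) if sig else (-0.2, 0.4)
        return CSTrait(uid, "BAI", variable, label, r, lo, hi, sig, 22)

    def test_threshold_boundary(self):
        traits = [self._trait("temp", "JUL(t)", i < 5, f"P{i}") for i in range(10)]
        traits += [self._trait("prec", "MAY(t)", i < 4, f"P{i}") for i in range(10)]
        kept = screen_cs_traits(traits, min_populations=5)
        assert kept == [("temp", "JUL(t)")]

    def test_none_significant_warns(self):
        traits = [self._trait("temp", "JUL(t)", False, f"P{i}") for i in range(6)]
        with pytest.warns(UserWarning):
            assert screen_cs_traits(traits) == []
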