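"""SMA fitting, multi-group slope/shift/elevation tests, Tukey and ANOVA."""

import numpy as np
import pytest
from scipy import stats

from alpgraze.allometry import (
    anova_breed_size,
    grouped_allometry,
    sma_common_slope,
    sma_elevation_test,
    sma_fit,
    sma_shift_test,
    tukey_pairwise,
)
from alpgraze.records import DegenerateDataError


def _correlated(rng, n, slope=2.0, intercept=0.0, noise=0.5, xloc=0.0):
    x = rng.normal(xloc, 1.0, n)
    y = intercept + slope * x + rng.normal(0, noise, n)
    return x, y


class TestSmaFit:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        f = sma_fit(x, 2 * x)
        assert f.slope == pytest.approx(2.0)
        assert f.intercept == pytest.approx(0.0, abs=1e-12)
        assert f.r_squared == pytest.approx(1.0)

    def test_closed_form_example(self):
        f = sma_fit([1, 2, 3], [1, 2, 4])
        # closed form: b = s_y/s_x = sqrt(7/3), a = 7/3 - 2b, r^2 = 27/28
        assert f.slope == pytest.approx(np.sqrt(7 / 3), abs=1e-10)
        assert f.slope == pytest.approx(1.5275, abs=1e-4)
        assert f.intercept == pytest.approx(7 / 3 - 2 * np.sqrt(7 / 3), abs=1e-10)
        assert f.r_squared == pytest.approx(27 / 28, abs=1e-10)

    def test_swap_symmetry(self, rng):
        x, y = _correlated(rng, 40)
        assert sma_fit(y, x).slope == pytest.approx(1 / sma_fit(x, y).slope)

    def test_equals_standardized_pca_oracle(self, rng):
        """SMA line = first principal axis of the z-scored variables,
        back-transformed to the original scale."""
        for _ in range(50):
            x, y = _correlated(rng, 30, slope=rng.uniform(-3, 3), noise=1.0)
            f = sma_fit(x, y)
            zx = (x - x.mean()) / x.std(ddof=1)
            zy = (y - y.mean()) / y.std(ddof=1)
            evals, evecs = np.linalg.eigh(np.cov(zx, zy, ddof=1))
            v = evecs[:, np.argmax(evals)]
            b_pca = (v[1] / v[0]) * (y.std(ddof=1) / x.std(ddof=1))
            assert f.slope == pytest.approx(b_pca, abs=1e-10)

    def test_ci_contains_slope_and_sign_matches_r(self, rng):
        x, y = _correlated(rng, 25, slope=-1.5)
        f = sma_fit(x, y)
        assert f.slope_ci[0] <= f.slope <= f.slope_ci[1]
        assert np.sign(f.slope) == np.sign(f.r)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            sma_fit([1, 2], [1, 2])
        with pytest.raises(DegenerateDataError):
            sma_fit([1, 1, 1], [1, 2, 3])


class TestCommonSlope:
    def test_identical_groups_lr_zero(self, rng):
        x, y = _correlated(rng, 30)
        res = sma_common_slope({"a": (x, y), "b": (x.copy(), y.copy())})
        assert res.lr_statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_power_against_distinct_slopes(self):
        """True slopes 1 vs 3 at n=50, r ~ 0.95: detected nearly always."""
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(3000 + s)
            x1 = rng.normal(0, 1, 50)
            x2 = rng.normal(0, 1, 50)
            g = {
                "a": (x1, 1.0 * x1 + rng.normal(0, 0.33, 50)),
                "b": (x2, 3.0 * x2 + rng.normal(0, 1.0, 50)),
            }
            if sma_common_slope(g).p_value < 0.01:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_affine_invariance_of_p(self, rng):
        gs = {
            str(i): _correlated(rng, 30, slope=1.2 + 0.3 * i) for i in range(3)
        }
        p0 = sma_common_slope(gs).p_value
        scaled = {k: (5.0 * x + 2.0, 0.5 * y - 7.0) for k, (x, y) in gs.items()}
        assert sma_common_slope(scaled).p_value == pytest.approx(p0, abs=1e-6)


class TestShiftElevation:
    def _base_groups(self, rng, n=50, noise=0.3):
        x = rng.normal(5.0, 1.0, n)
        y = 1.0 + 2.0 * x + rng.normal(0, noise, n)
        return x, y

    def test_identical_groups_not_significant(self, rng):
        x, y = self._base_groups(rng)
        g = {"a": (x, y), "b": (x.copy(), y.copy())}
        cs = sma_common_slope(g)
        assert sma_shift_test(g, cs).p_value == pytest.approx(1.0, abs=1e-6)
        assert sma_elevation_test(g, cs).p_value == pytest.approx(1.0, abs=1e-6)

    def test_translation_along_line_is_shift_not_elevation(self):
        hits_shift = hits_elev = 0
        n_sim = 100
        for s in range(n_sim):
            rng = np.random.default_rng(8000 + s)
            x, y = self._base_groups(rng)
            dx = 2.0
            g = {"a": (x, y), "b": (x + dx, y + 2.0 * dx)}
            cs = sma_common_slope(g)
            if sma_shift_test(g, cs).p_value < 0.05:
                hits_shift += 1
            if sma_elevation_test(g, cs).p_value < 0.05:
                hits_elev += 1
        assert hits_shift / n_sim >= 0.95   # shift detected
        assert hits_elev / n_sim <= 0.20    # elevation mostly not

    def test_parallel_offset_is_elevation(self):
        hits = 0
        n_sim = 100
        for s in range(n_sim):
            rng = np.random.default_rng(9000 + s)
            x, y = self._base_groups(rng)
            x2, y2 = self._base_groups(rng)
            g = {"a": (x, y), "b": (x2, y2 + 5.0)}
            cs = sma_common_slope(g)
            if sma_elevation_test(g, cs).p_value < 0.05:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_permuted_labels_give_uniformish_p(self):
        """Random relabelling of one pooled sample: p should not pile up
        near 0 (light permutation sanity check)."""
        ps = []
        for s in range(100):
            rng = np.random.default_rng(11000 + s)
            x, y = self._base_groups(rng, n=60)
            perm = rng.permutation(60)
            g = {"a": (x[perm[:30]], y[perm[:30]]), "b": (x[perm[30:]], y[perm[30:]])}
            cs = sma_common_slope(g)
            ps.append(sma_elevation_test(g, cs).p_value)
        assert np.mean(np.array(ps) < 0.05) <= 0.12


class TestTukey:
    def test_two_groups_equals_pooled_t(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        tuk = tukey_pairwise({"a": a, "b": b})
        t_p = stats.ttest_ind(a, b).pvalue
        assert tuk["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-8)

    def test_identical_groups_p_one(self):
        x = np.arange(10.0)
        tuk = tukey_pairwise({"a": x, "b": x.copy(), "c": x.copy()})
        assert (tuk["p_adj"] > 0.999).all()

    def test_separated_group_detected(self, rng):
        g = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0, 1, 10),
            "c": rng.normal(5, 1, 10),
        }
        tuk = tukey_pairwise(g).set_index(["group_a", "group_b"])
        assert tuk.loc[("a", "c"), "p_adj"] < 0.001
        assert tuk.loc[("b", "c"), "p_adj"] < 0.001

    def test_matches_scipy_tukey_hsd(self, rng):
        g = {k: rng.normal(loc, 1, 11) for k, loc in zip("abc", (0.0, 0.5, 1.1))}
        ours = tukey_pairwise(g)
        oracle = stats.tukey_hsd(*g.values())
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for (i, j), row in pairs.items():
            assert ours["p_adj"].iloc[row] == pytest.approx(
                oracle.pvalue[i, j], abs=1e-6
            )


class TestAnova:
    def _data(self, rng, effect):
        import pandas as pd

        rows = []
        for breed in ("A", "B", "C"):
            for size in (0.3, 0.7, 1.6):
                for _ in range(4):
                    y = rng.normal(0, 1) + effect(breed, size)
                    rows.append({"breed": breed, "paddock_size_ha": size, "resp": y})
        return pd.DataFrame(rows)

    def test_size_only_effect(self, rng):
        df = self._data(rng, lambda b, s: 3.0 * s)
        tab = anova_breed_size(df, "resp")
        assert tab.loc["size", "PR(>F)"] < 0.001
        assert tab.loc["breed:size", "PR(>F)"] > 0.05

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for s in range(200):
            rng = np.random.default_rng(40000 + s)
            df = self._data(rng, lambda b, s_: 0.0)
            tab = anova_breed_size(df, "resp")
            ps.append(tab.loc["breed", "PR(>F)"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_balanced_sequential_equals_marginal(self, rng):
        """With breeds crossed over identical size levels the factors are
        orthogonal, so sequential (type-I) and marginal (type-II) tests
        agree for the main effects."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = self._data(rng, lambda b, s: {"A": 0, "B": 1, "C": 2}[b] + s)
        t1 = anova_breed_size(df, "resp")
        m = smf.ols(
            "resp ~ C(breed) * paddock_size_ha", data=df
        ).fit()
        t2 = anova_lm(m, typ=2)
        assert t1.loc["breed", "F"] == pytest.approx(t2.loc["C(breed)", "F"])
        assert t1.loc["size", "F"] == pytest.approx(
            t2.loc["paddock_size_ha", "F"]
        )


def test_grouped_allometry_flags_heterogeneous_slopes():
    rng = np.random.default_rng(5)
    x1 = rng.normal(0, 1, 60)
    x2 = rng.normal(0, 1, 60)
    g = {
        "a": (x1, 1.0 * x1 + rng.normal(0, 0.2, 60)),
        "b": (x2, 3.0 * x2 + rng.normal(0, 0.6, 60)),
    }
    ga = grouped_allometry(g)
    assert ga.common_slope_rejected
    assert ga.shift is not None and ga.elevation is not None
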