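"""Classical measurements and univariate statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from snailmorph.traditional import (aperture_area, growth_check, mann_whitney,
                                    rank_correlation, relative_aperture,
                                    screen_collinear, t_test, welch_anova,
                                    whorl_height_screen)


class TestApertureArea:
    def test_circle(self):
        assert aperture_area(2, 2) == pytest.approx(math.pi)
        assert aperture_area(4, 2) == pytest.approx(2 * math.pi)

    def test_monte_carlo_oracle(self, rng):
        h, w = 3.2, 1.7
        pts = rng.uniform(-0.5, 0.5, (10**6, 2)) * [w, h]
        inside = ((pts[:, 0] / (w / 2)) ** 2 + (pts[:, 1] / (h / 2)) ** 2 <= 1).mean()
        mc_area = inside * h * w
        assert aperture_area(h, w) == pytest.approx(mc_area, rel=0.01)

    def test_nonpositive_error(self):
        with pytest.raises(ValueError):
            aperture_area(0, 1)


class TestRelativeAperture:
    def test_scale_invariance(self):
        r1 = relative_aperture(2.0, 1.0, 0.8)
        r2 = relative_aperture(4.0, 2.0, 1.6)
        assert r1 == pytest.approx(r2)
        assert relative_aperture(1.0, 1.0, 1.0) == pytest.approx(math.pi / 4)

    def test_rankings_agree_at_constant_height(self, rng):
        h = np.full(20, 3.0)
        ah = rng.uniform(0.5, 2, 20)
        aw = rng.uniform(0.5, 2, 20)
        r_sq = relative_aperture(h, ah, aw)
        r_lin = relative_aperture(h, ah, aw, normalization="height")
        assert np.array_equal(np.argsort(r_sq), np.argsort(r_lin))


class TestRankCorrelation:
    def test_perfect_concordance(self):
        x = [1, 2, 3, 4, 5]
        assert rank_correlation(x, [2, 4, 6, 8, 10], "spearman").statistic == pytest.approx(1.0)
        assert rank_correlation(x, [10, 8, 6, 4, 2], "kendall").statistic == pytest.approx(-1.0)

    def test_kendall_matches_pair_counting(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        conc = disc = 0
        for (i, j) in itertools.combinations(range(8), 2):
            s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
            conc += s > 0
            disc += s < 0
        expected = (conc - disc) / math.comb(8, 2)
        assert rank_correlation(x, y, "kendall").statistic == pytest.approx(expected)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 1, 1], [1, 2, 3])


class TestGroupTests:
    def test_identical_groups_null(self):
        a = np.arange(10.0)
        w = welch_anova(a, a.copy())
        assert w.statistic == pytest.approx(0.0, abs=1e-12)
        t = t_test(a, a.copy(), paired=True)
        assert (t.statistic, t.p_value) == (0.0, 1.0)

    def test_u_complete_separation(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0

    def test_welch_matches_published_formula(self, rng):
        groups = [rng.normal(m, s, n) for m, s, n in
                  ((0, 1, 12), (0.5, 2, 18), (-0.3, 0.5, 9))]
        res = welch_anova(*groups)
        # brute-force Welch F from the defining formula
        k = 3
        ns = np.array([len(g) for g in groups], float)
        vs = np.array([g.var(ddof=1) for g in groups])
        ms = np.array([g.mean() for g in groups])
        w = ns / vs
        yb = (w * ms).sum() / w.sum()
        num = (w * (ms - yb) ** 2).sum() / (k - 1)
        h = ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
        f = num / (1 + 2 * (k - 2) / (k**2 - 1) * h)
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.df[1] == pytest.approx((k**2 - 1) / (3 * h), rel=1e-12)

    def test_welch_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 2, 20),
                               rng.normal(0.5, 0.8, 10)])
        grp = np.repeat(["a", "b", "c"], [15, 20, 10])
        df = pd.DataFrame({"y": vals, "g": grp})
        ours = welch_anova(vals[:15], vals[15:35], vals[35:])
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        assert ours.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert ours.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)


class TestGrowthCheck:
    def test_no_change(self):
        h = np.array([3.0, 3.5, 4.0, 4.4])
        res = growth_check(h, h.copy())
        assert res.statistic == 0.0
        assert res.extra["mean_change"] == 0.0

    def test_uniform_growth_detected(self, rng):
        h0 = rng.uniform(3, 5, 21)
        h1 = h0 + 1 + rng.normal(0, 0.1, 21)
        res = growth_check(h0, h1)
        assert res.p_value < 1e-6
        assert res.extra["mean_change"] == pytest.approx(1.0, abs=0.15)

    def test_null_calibration(self, rng):
        """Zero-mean symmetric noise gives uniform p-values."""
        from scipy import stats
        ps = []
        for _ in range(300):
            h0 = rng.uniform(3, 5, 21)
            h1 = h0 + rng.normal(0, 0.2, 21)
            ps.append(growth_check(h0, h1).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_id_matching(self):
        with pytest.raises(ValueError, match="unmatched"):
            growth_check([1, 2], [1, 2], ids_t0=["a", "b"], ids_t1=["a", "c"])
        res = growth_check([1.0, 2.0, 3.0], [3.1, 1.1, 2.1],
                           ids_t0=["a", "b", "c"], ids_t1=["c", "a", "b"])
        assert res.extra["mean_change"] == pytest.approx(0.1)


class TestScreenCollinear:
    def test_identical_columns_dropped(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        retained, dropped = screen_collinear(df, threshold_tau=0.9)
        assert retained == ["a", "c"]
        assert dropped[0][:2] == ("b", "a")

    def test_independent_columns_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        retained, dropped = screen_collinear(df, threshold_tau=0.9)
        assert retained == list("abcd") and dropped == []

    def test_named_drop_list_honoured(self, rng):
        n = 100
        cond = rng.normal(600, 150, n)
        lat = rng.normal(52, 2, n)
        df = pd.DataFrame({
            "salinity": cond * 5e-4 + rng.normal(0, 1e-3, n),
            "conductivity": cond,
            "latitude": lat,
            "longitude": lat * 1.5 + rng.normal(0, 0.5, n),
        })
        retained, dropped = screen_collinear(
            df, threshold_tau=0.38,
            drop_map={"salinity": "conductivity", "longitude": "latitude"})
        assert set(retained) == {"conductivity", "latitude"}
        assert {d[0] for d in dropped} == {"salinity", "longitude"}

    def test_bad_threshold(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            screen_collinear(df, threshold_tau=1.5)


class TestWhorlScreen:
    def test_synthetic_cohort_triggers_exclusion(self):
        """Whorl counts built to track height are flagged for exclusion."""
        from snailmorph.synthetic import GeneratorConfig, generate_cohort

        _, specimens, *_ = generate_cohort(
            GeneratorConfig(seed=0, n_sites=8, specimens_per_site=15))
        res = whorl_height_screen(specimens["shell_height"], specimens["whorls"])
        assert res.extra["exclude_whorls"]
        assert abs(res.statistic) >= 0.5

    def test_independent_whorls_retained(self, rng):
        h = rng.uniform(3, 5, 200)
        w = rng.uniform(3, 6, 200)
        res = whorl_height_screen(h, w)
        assert not res.extra["exclude_whorls"]
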