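"""Agreement statistics: Bland-Altman, bias tests, Jaccard, z-scores, Bartlett."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reflexmri import agreement as ag


def _means(values, session="IN1", flt="STD"):
    rows = []
    for (p, m, v), h in values.items():
        rows.append(
            dict(participant=p, session=session, filter=flt, muscle=m, velocity=v,
                 H_mean=h,
                 direction="stretch" if (m == "FCR") == (v > 0) else "shortening")
        )
    return pd.DataFrame(rows)


class TestPairSets:
    def test_full_factorial_join(self):
        keys = {(f"P{p:02d}", m, v)
                for p in range(12) for m in ("FCR", "ECU") for v in (50.0, 125.0, 200.0)}
        a = _means({k: 1.0 for k in keys})
        b = _means({k: 2.0 for k in keys})
        stretch = ag.pair_sets(a, b, "stretch")
        assert stretch.n == 36  # FCR cells only at positive v
        both = ag.pair_sets(a, b, "shortening")
        assert both.n == 36

    def test_identical_tables_zero_differences(self):
        keys = {("P01", "FCR", v) for v in (50.0, 125.0, 200.0)}
        a = _means({k: 3.0 for k in keys})
        ps = ag.pair_sets(a, a, "stretch")
        assert np.all(ps.b - ps.a == 0.0)

    def test_disjoint_keys_raise(self):
        a = _means({("P01", "FCR", 50.0): 1.0})
        b = _means({("P02", "FCR", 50.0): 1.0})
        with pytest.raises(ValueError):
            ag.pair_sets(a, b, "stretch")


class TestBlandAltman:
    def test_identical_measurements(self):
        res = ag.bland_altman(([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.bias == 0.0
        assert res.loa == (0.0, 0.0)

    def test_constant_offset(self):
        res = ag.bland_altman(([1.0, 2.0, 3.0], [1.5, 2.5, 3.5]))
        assert res.bias == pytest.approx(0.5)
        assert res.loa_high - res.loa_low == pytest.approx(0.0)

    def test_closed_form_oracle(self):
        """diffs [1,0,1,0]: bias 0.5, sd sqrt(1/3), LoA 0.5 -+ 1.96*sd."""
        res = ag.bland_altman(([1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 4.0, 4.0]))
        sd = np.sqrt(1.0 / 3.0)
        assert res.bias == pytest.approx(0.5, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-4)
        assert res.loa_low == pytest.approx(0.5 - 1.96 * sd, abs=1e-4)
        assert res.loa_high == pytest.approx(0.5 + 1.96 * sd, abs=1e-4)
        # t-based CI half-widths
        t = stats.t.ppf(0.975, 3)
        assert res.ci_bias[1] - res.bias == pytest.approx(t * sd / 2.0, rel=1e-9)
        assert res.ci_loa_low[1] - res.loa_low == pytest.approx(
            t * sd * np.sqrt(3.0 / 4.0), rel=1e-9
        )

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        r1 = ag.bland_altman((a, b))
        r2 = ag.bland_altman((b, a))
        assert r1.bias == pytest.approx(-r2.bias)
        assert r1.loa_low == pytest.approx(-r2.loa_high)
        assert r1.loa_high == pytest.approx(-r2.loa_low)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ag.bland_altman(([1.0, 2.0], [1.0, 2.0]))


class TestCompareBias:
    def _ba(self, bias, sd, n=10):
        import dataclasses

        return ag.BlandAltmanResult(
            bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
            ci_bias=(0, 0), ci_loa_low=(0, 0), ci_loa_high=(0, 0), n=n,
        )

    def test_identical_results(self):
        z, p = ag.compare_bias(self._ba(1.0, 0.5), self._ba(1.0, 0.5))
        assert z == 0.0 and p == 1.0

    def test_normal_quantile_oracle(self):
        """Bias gap of 1.96 combined SEs gives unadjusted p = 0.05."""
        ba1 = self._ba(0.0, 1.0, n=25)  # SE 0.2
        se = np.sqrt(2 * 0.2**2)
        ba2 = self._ba(1.96 * se, 1.0, n=25)
        z, p = ag.compare_bias(ba2, ba1, n_comparisons=1)
        assert z == pytest.approx(1.96)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_bonferroni_triples_then_caps(self):
        ba1 = self._ba(0.0, 1.0)
        ba2 = self._ba(0.3, 1.0)
        _, p1 = ag.compare_bias(ba1, ba2, n_comparisons=1)
        _, p3 = ag.compare_bias(ba1, ba2, n_comparisons=3)
        assert p3 == pytest.approx(min(3 * p1, 1.0))


class TestJaccard:
    def test_oracles(self):
        assert ag.jaccard((0.0, 2.0), (0.0, 2.0)) == 1.0
        assert ag.jaccard((0.0, 2.0), (1.0, 3.0)) == pytest.approx(1.0 / 3.0)
        assert ag.jaccard((0.0, 1.0), (2.0, 3.0)) == 0.0

    def test_degenerate_intervals(self):
        assert ag.jaccard((1.0, 1.0), (1.0, 1.0)) == 1.0
        assert ag.jaccard((1.0, 1.0), (2.0, 2.0)) == 0.0

    @given(
        st.tuples(*[st.floats(-50, 50) for _ in range(4)]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, endpoints):
        i1 = (endpoints[0], endpoints[1])
        i2 = (endpoints[2], endpoints[3])
        j = ag.jaccard(i1, i2)
        assert 0.0 <= j <= 1.0
        assert j == ag.jaccard(i2, i1)

    def test_equals_one_iff_identical(self):
        assert ag.jaccard((0.0, 2.0), (0.0, 2.0 + 1e-6)) < 1.0


class TestJaccardBootstrap:
    def _ba(self, lo, hi, se_sd=0.0, n=10):
        sd = se_sd
        return ag.BlandAltmanResult(
            bias=(lo + hi) / 2, sd_diff=sd, loa_low=lo, loa_high=hi,
            ci_bias=(0, 0), ci_loa_low=(0, 0), ci_loa_high=(0, 0), n=n,
        )

    def test_degenerate_at_one(self):
        ba = self._ba(-1.0, 1.0, se_sd=0.0)
        res = ag.jaccard_bootstrap(ba, ba, n_boot=200, seed=0)
        assert res.mean == 1.0 and res.ci95 == (1.0, 1.0)

    def test_widened_reference_interval_oracle(self):
        """[-a, a] against [-2a, 2a] with zero SE gives exactly 0.5."""
        res = ag.jaccard_bootstrap(
            self._ba(-1.0, 1.0), self._ba(-2.0, 2.0), n_boot=200, seed=0
        )
        assert res.mean == pytest.approx(0.5)

    def test_seeded_determinism(self):
        ba1 = self._ba(-1.0, 1.0, se_sd=0.3)
        ba2 = self._ba(-1.5, 1.2, se_sd=0.2)
        r1 = ag.jaccard_bootstrap(ba1, ba2, n_boot=500, seed=3)
        r2 = ag.jaccard_bootstrap(ba1, ba2, n_boot=500, seed=3)
        assert r1.mean == r2.mean and r1.ci95 == r2.ci95


def _h_table(rng, n_participants=4, reps=10, session="OUT1", flt="STD", shift=0.0):
    rows = []
    for p in range(n_participants):
        for m in ("FCR", "ECU"):
            for v in (-200.0, -125.0, -50.0, 50.0, 125.0, 200.0):
                base = 0.1 * abs(v)
                for i in range(reps):
                    rows.append(
                        dict(participant=f"P{p:02d}", session=session, filter=flt,
                             muscle=m, velocity=v, repetition=i,
                             H=base + shift + rng.normal(0, 0.02 * abs(v)))
                    )
    return pd.DataFrame(rows)


class TestZScores:
    def test_mean_value_scores_zero(self):
        rng = np.random.default_rng(0)
        ref = _h_table(rng)
        key = ["participant", "muscle", "velocity"]
        mu = ref.groupby(key)["H"].transform("mean")
        test = ref.copy()
        test["H"] = mu
        res = ag.zscores(test, ref)
        assert np.allclose(res.table["z"], 0.0)

    def test_two_sigma_value_scores_two(self):
        rng = np.random.default_rng(1)
        ref = _h_table(rng)
        key = ["participant", "muscle", "velocity"]
        g = ref.groupby(key)["H"]
        test = ref.drop_duplicates(subset=key).copy()
        stats_ = ref.groupby(key)["H"].agg(["mean", "std"]).reset_index()
        test = test.merge(stats_, on=key)
        test["H"] = test["mean"] + 2 * test["std"]
        res = ag.zscores(test[ref.columns], ref)
        assert np.allclose(res.table["z"], 2.0)

    def test_self_standardization_identity(self):
        """Each reference cell standardized against itself has mean 0, SD 1."""
        rng = np.random.default_rng(2)
        ref = _h_table(rng)
        res = ag.zscores(ref, ref)
        cells = res.table.groupby(["participant", "muscle", "velocity"])["z"]
        assert np.allclose(cells.mean(), 0.0, atol=1e-9)
        assert np.allclose(cells.std(ddof=1), 1.0, atol=1e-9)


class TestBartlett:
    def test_equal_variances_zero_statistic(self):
        g = [1.0, 2.0, 3.0]
        res = ag.bartlett(g, [x + 10 for x in g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_large_variance_ratio_detected(self):
        """Variance ratio 9 at n=50 per group is overwhelming evidence."""
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 3, 50)
        res = ag.bartlett(a, b)
        assert res.p < 1e-3
        assert res.df == 1
        # closed-form statistic oracle
        k, n = 2, 50
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        num = (2 * n - k) * np.log(sp2) - (n - 1) * (
            np.log(np.var(a, ddof=1)) + np.log(np.var(b, ddof=1))
        )
        c = 1 + (2 / (n - 1) - 1 / (2 * n - k)) / (3 * (k - 1))
        assert res.statistic == pytest.approx(num / c, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ag.bartlett([1.0], [1.0, 2.0])

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            ag.bartlett([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
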