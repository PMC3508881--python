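"""ANOVA, Spearman and normality checks against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from assertnet.validation_stats import (
    GroupSummary,
    StatsError,
    anova_from_summary,
    anova_oneway,
    normality_check,
    spearman,
    summarize_groups,
    _ks_fitted_normal,
)


def _table(groups):
    rows = []
    for label, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"subject_id": f"{label}{i}", "group": label, "value": v})
    return pd.DataFrame(rows)


def _anova_oracle(groups):
    """Sum-of-squares ANOVA written out longhand, plus the F tail from scipy."""
    values = [v for g in groups.values() for v in g]
    grand = sum(values) / len(values)
    ssb = 0.0
    ssw = 0.0
    for g in groups.values():
        mean = sum(g) / len(g)
        ssb += len(g) * (mean - grand) ** 2
        for v in g:
            ssw += (v - mean) ** 2
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    F = (ssb / df_b) / (ssw / df_w)
    return F, float(sps.f.sf(F, df_b, df_w))


class TestAnovaOneway:
    def test_toy_three_groups_match_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.5, 4.0], "c": [5.0, 6.0, 8.0]}
        res = anova_oneway(_table(groups))
        F, p = _anova_oracle(groups)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        groups = {f"g{i}": list(rng.normal(i * 0.3, 1.0, 12)) for i in range(3)}
        res = anova_oneway(_table(groups))
        ref = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(float(ref.statistic), rel=1e-12)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_all_values_equal_gives_f_zero_p_one(self):
        res = anova_oneway(_table({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0]}))
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_within_variance_with_effect_is_error(self):
        with pytest.raises(StatsError, match="unbounded"):
            anova_oneway(_table({"a": [1.0, 1.0], "b": [2.0, 2.0]}))

    def test_group_of_one_rejected(self):
        with pytest.raises(StatsError):
            anova_oneway(_table({"a": [1.0], "b": [2.0, 3.0]}))


class TestAnovaFromSummary:
    def test_summaries_reproduce_raw_anova(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            k = rng.integers(2, 5)
            groups = {
                f"g{i}": list(rng.normal(rng.normal(0, 1), 1.0, int(rng.integers(3, 15))))
                for i in range(k)
            }
            table = _table(groups)
            raw = anova_oneway(table)
            summ = anova_from_summary(summarize_groups(table))
            assert summ.F == pytest.approx(raw.F, rel=1e-10)
            assert summ.p == pytest.approx(raw.p, rel=1e-10)

    def test_two_identical_groups_f_zero(self):
        res = anova_from_summary(
            [GroupSummary("a", 10, 1.5, 0.4), GroupSummary("b", 10, 1.5, 0.4)]
        )
        assert res.F == pytest.approx(0.0, abs=1e-12) and res.p == pytest.approx(1.0)

    def test_plasma_group_summaries_highly_significant(self):
        # three diagnostic groups of a plasma protein assay (arbitrary units)
        res = anova_from_summary(
            [
                GroupSummary("Controls", 82, 1.63, 0.9),
                GroupSummary("MCI", 80, 0.98, 0.7),
                GroupSummary("AD", 78, 0.85, 0.3),
            ]
        )
        # direct formula evaluation: SSB/2 = 14.098..., MSW = 111.25/237
        assert res.F == pytest.approx(30.04, abs=0.01)
        assert res.p < 0.001
        assert (res.df_between, res.df_within) == (2, 237)

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            GroupSummary("tiny", 1, 0.0, 1.0)


def _spearman_oracle(x, y):
    """Rank by hand (average ties), then Pearson on the ranks via numpy."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    return float(np.corrcoef(ranks(list(x)), ranks(list(y)))[0, 1])


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_closed_form_example(self):
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 4
        assert res.rho == pytest.approx(0.8)

    def test_all_permutations_n5_match_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        for perm in itertools.permutations(x):
            got = spearman(x, list(perm)).rho
            assert got == pytest.approx(_spearman_oracle(x, perm), abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0, 7.0, 6.0, 9.0, 8.0, 11.0, 10.0, 12.0]
        ref = sps.spearmanr(x, y)
        res = spearman(x, y)
        assert res.rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_large_n_p_matches_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = spearman(x, y)
        t = res.rho * math.sqrt(38 / (1 - res.rho**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 38), rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_short_rejected(self):
        with pytest.raises(StatsError):
            spearman([1.0, 2.0], [2.0, 1.0])

    # integers keep the transforms strictly monotone in float arithmetic
    # (cubing a subnormal float would underflow and create ties)
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=5, max_size=20, unique=True),
        st.randoms(use_true_random=False),
    )
    def test_invariant_under_monotone_transforms(self, x, rnd):
        x = [float(v) for v in x]
        y = list(x)
        rnd.shuffle(y)
        base = spearman(x, y)
        transformed = spearman([2.0 * v + 1.0 for v in x], [v**3 for v in y])
        assert transformed.rho == pytest.approx(base.rho, abs=1e-12)
        assert transformed.p == pytest.approx(base.p, abs=1e-12)


class TestNormalityCheck:
    def test_statistic_matches_brute_force_scan(self):
        x = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        d = _ks_fitted_normal(x)
        mu, sd = x.mean(), x.std(ddof=1)
        xs = np.sort(x)
        brute = 0.0
        n = len(x)
        for i, v in enumerate(xs):
            c = sps.norm.cdf(v, mu, sd)
            brute = max(brute, abs((i + 1) / n - c), abs(c - i / n))
        assert d == pytest.approx(brute, abs=1e-15)

    def test_statistic_matches_statsmodels_lilliefors(self):
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 3.0, 150)
        stat, _ = lilliefors(x, dist="norm")
        assert _ks_fitted_normal(x) == pytest.approx(float(stat), abs=1e-12)

    def test_normal_data_rarely_rejected(self):
        rng = np.random.default_rng(8)
        ok = 0
        reps = 60
        for i in range(reps):
            x = rng.standard_normal(200)
            if normality_check(x, n_mc=400, seed=1000 + i).p > 0.01 :
                ok += 1
        assert ok / reps >= 0.98

    def test_bimodal_data_rejected(self):
        x = np.tile([0.0, 1.0], 100) + np.linspace(0, 1e-6, 200)  # break exact ties
        assert normality_check(x, n_mc=400, seed=4).p < 0.01

    def test_seed_reproducible(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(50)
        assert normality_check(x, seed=9) == normality_check(x, seed=9)

    def test_small_sample_rejected(self):
        with pytest.raises(StatsError):
            normality_check([1.0, 2.0, 3.0], seed=0)
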