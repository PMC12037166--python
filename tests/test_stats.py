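"""Statistical kernels against brute-force oracles and pingouin."""

import numpy as np
import pytest
from scipy import stats as sps

from reactivate.stats import (
    SubjectResult,
    behavior_improvement,
    bonferroni,
    fraction_difference,
    mixed_anova_2x2,
    one_sample_t,
    paired_t,
    pearson_corr,
)


def anova_oracle(pre, post, groups):
    """Model-comparison oracle: Type-III SS via explicit lstsq refits."""
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    d = post - pre
    m = 0.5 * (pre + post)
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels))
    x = np.where(labels == uniq[0], 1.0, -1.0)
    n = d.size

    def rss(y, cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    one = np.ones(n)
    rss_d_full = rss(d, [one, x])
    ss_session = rss(d, [x]) - rss_d_full
    ss_inter = rss(d, [one]) - rss_d_full
    rss_m_full = rss(m, [one, x])
    ss_group = rss(m, [one]) - rss_m_full
    out = {}
    for name, ss_eff, ss_err in (
        ("session", ss_session, rss_d_full),
        ("interaction", ss_inter, rss_d_full),
        ("group", ss_group, rss_m_full),
    ):
        F = (ss_eff / 1.0) / (ss_err / (n - 2))
        out[name] = (F, sps.f.sf(F, 1, n - 2), ss_eff / (ss_eff + ss_err))
    return out


class TestMixedAnova:
    def test_all_equal_values(self):
        tab = mixed_anova_2x2([5.0] * 6, [5.0] * 6, ["a"] * 3 + ["b"] * 3)
        for eff in (tab.session, tab.group, tab.interaction):
            assert eff.F == 0.0 and eff.eta_p_sq == 0.0

    def test_paper_sized_dfs(self, rng):
        pre = rng.normal(50, 5, 41)
        post = rng.normal(52, 5, 41)
        tab = mixed_anova_2x2(pre, post, ["R"] * 21 + ["L"] * 20)
        assert (tab.session.df1, tab.session.df2) == (1, 39)
        assert (tab.group.df1, tab.group.df2) == (1, 39)

    @pytest.mark.parametrize("n1,n2", [(21, 20), (10, 10), (5, 9)])
    def test_matches_ss_oracle(self, rng, n1, n2):
        for _ in range(30):
            pre = rng.normal(50, 8, n1 + n2)
            post = pre + rng.normal(2, 4, n1 + n2)
            groups = ["R"] * n1 + ["L"] * n2
            tab = mixed_anova_2x2(pre, post, groups)
            oracle = anova_oracle(pre, post, groups)
            for name in ("session", "group", "interaction"):
                F, p, eta = oracle[name]
                eff = getattr(tab, name)
                assert eff.F == pytest.approx(F, abs=1e-10)
                assert eff.p == pytest.approx(p, abs=1e-10)
                assert eff.eta_p_sq == pytest.approx(eta, abs=1e-10)

    def test_one_group_reduces_to_paired_t(self, rng):
        pre = rng.normal(50, 5, 15)
        post = pre + rng.normal(1, 2, 15)
        tab = mixed_anova_2x2(pre, post, None)
        tt = paired_t(post, pre)
        assert tab.session.F == pytest.approx(tt.t**2, abs=1e-8)
        assert tab.session.df2 == tt.df
        assert tab.group is None and tab.interaction is None

    def test_matches_pingouin_balanced(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 12
        pre = rng.normal(40, 6, 2 * n)
        post = pre + rng.normal(3, 5, 2 * n)
        groups = ["R"] * n + ["L"] * n
        tab = mixed_anova_2x2(pre, post, groups)
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(2 * n), 2),
                "session": ["pre", "post"] * (2 * n),
                "group": np.repeat(groups, 2),
                "y": np.column_stack([pre, post]).ravel(),
            }
        )
        ref = pg.mixed_anova(df, dv="y", within="session", subject="subj", between="group")
        for name, row in (("group", 0), ("session", 1), ("interaction", 2)):
            eff = getattr(tab, name)
            assert eff.F == pytest.approx(ref.loc[row, "F"], abs=1e-8)
            assert eff.p == pytest.approx(ref.loc[row, "p_unc"], abs=1e-8)
            assert eff.eta_p_sq == pytest.approx(ref.loc[row, "np2"], abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mixed_anova_2x2([1.0, 2.0], [1.0], None)
        with pytest.raises(ValueError):
            mixed_anova_2x2([1, 2, 3], [2, 3, 4], ["a", "a", "b"])  # group of 1
        with pytest.raises(ValueError):
            mixed_anova_2x2([1, 2, 3], [2, 3, 4], ["a", "b", "c"])  # 3 groups


class TestTTests:
    def test_paired_identical_vectors_error(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_paired_constant_shift_with_jitter(self, rng):
        base = rng.normal(size=30)
        res = paired_t(base + 5.0 + rng.normal(0, 1e-3, 30), base)
        assert res.t > 0 and res.cohen_d > 100

    def test_paired_matches_formula_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=21)
            y = rng.normal(size=21)
            res = paired_t(x, y)
            d = x - y
            t = d.mean() / (d.std(ddof=1) / np.sqrt(21))
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 20), abs=1e-12)
            assert res.cohen_d == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)

    def test_one_sample_near_mu0(self, rng):
        values = 50.0 + rng.normal(0, 1e-9, 20)
        res = one_sample_t(values, 50.0)
        assert abs(res.t) < 5.0  # jitter-scale t, not inflated

    def test_one_sample_effect_size_unit(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mu0 = values.mean() - values.std(ddof=1)
        assert one_sample_t(values, mu0).cohen_d == pytest.approx(1.0)

    def test_one_sample_matches_formula_oracle(self, rng):
        for _ in range(100):
            v = rng.normal(2, 3, size=15)
            res = one_sample_t(v, 1.0)
            t = (v.mean() - 1.0) / (v.std(ddof=1) / np.sqrt(15))
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 14), abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            one_sample_t([3.0, 3.0, 3.0], 0.0)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_orthogonal_centered(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_corr(x, y).r == pytest.approx(0.0, abs=1e-15)

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=21)
            y = rng.normal(size=21)
            res = pearson_corr(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert res.r == pytest.approx(r, abs=1e-12)
            t = r * np.sqrt(19 / (1 - r**2))
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 19), abs=1e-9)

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBonferroniAndHelpers:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
        extra=st.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bonferroni_properties(self, p, extra):
        m = len(p) + extra
        adj = bonferroni(p, m)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(p))  # never anti-conservative
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # rank preserved

    def test_bonferroni_values(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.5], 4), [0.04, 1.0])

    def test_bonferroni_order_preserving(self, rng):
        p = np.sort(rng.random(6)) * 0.2
        adj = bonferroni(p, 10)
        assert np.all(np.diff(adj) >= 0)

    def test_bonferroni_family_too_small(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    def test_behavior_improvement(self):
        assert behavior_improvement([40, 35, 30, 25]) == pytest.approx(10.0)
        assert behavior_improvement([30, 30, 30, 30]) == 0.0
        # linear in the session-4 value
        a = behavior_improvement([40, 35, 30, 20])
        b = behavior_improvement([40, 35, 30, 10])
        assert b - a == pytest.approx(10.0)
        with pytest.raises(ValueError):
            behavior_improvement([40, 35, 30])

    def test_fraction_difference(self):
        cell = ("svm", "roi", "L")
        res = SubjectResult(
            "s1",
            "right-hand",
            {("svm", "roi", "L", "pre"): 50.0, ("svm", "roi", "L", "post"): 60.0},
        )
        assert fraction_difference(res, cell) == pytest.approx(10.0)
        swapped = SubjectResult(
            "s1",
            "right-hand",
            {("svm", "roi", "L", "pre"): 60.0, ("svm", "roi", "L", "post"): 50.0},
        )
        assert fraction_difference(swapped, cell) == -fraction_difference(res, cell)
        with pytest.raises(ValueError, match="missing"):
            fraction_difference(SubjectResult("s", "g", {}), cell)

    def test_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            SubjectResult("s", "g", {("svm", "r", "L", "pre"): 120.0})
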