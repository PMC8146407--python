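"""Statistical kernel: hand-derived values, algebraic identities, and
cross-checks against independent reference implementations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from flankerlab.stats import (StatResult, fdr_adjust, gg_epsilon, mauchly_test,
                              paired_t, rm_anova)


class TestPairedT:
    def test_hand_value_differences_1_2_3(self):
        # d = (1,2,3): mean 2, sd 1 -> t = 2*sqrt(3), df 2
        res = paired_t([2, 4, 6], [1, 2, 3])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.df == (1.0, 2.0)

    def test_identical_vectors_t_zero_p_one(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.statistic)

    def test_antisymmetry_and_scipy_agreement(self):
        from scipy import stats as sps
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert paired_t(y, x).statistic == pytest.approx(-res.statistic)


class TestFdr:
    def test_hand_recursion(self):
        # BH step-up on (0.005, 0.01, 0.02, 0.04), m = 4:
        # ranked p*m/i = (0.02, 0.02, 0.0267, 0.04); cumulative min from
        # the top leaves (0.02, 0.02, 0.026667, 0.04)
        adj = fdr_adjust([0.005, 0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.02, 0.02, 0.08 / 3, 0.04], abs=1e-12)

    def test_single_p_unchanged_and_equal_ps_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_never_below_raw(self, ps):
        ps = np.asarray(ps)
        adj = fdr_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(adj, ref, atol=1e-12)
        assert np.all(adj >= ps - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSphericity:
    def test_identity_contrast_covariance_is_spherical(self):
        w, p = mauchly_test(np.eye(3), n_error=20)
        assert w == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_nonspherical_covariance_eigenvalue_oracle(self):
        cov = np.diag([4.0, 1.0, 0.25])
        w, p = mauchly_test(cov, n_error=20)
        eigs = np.array([4.0, 1.0, 0.25])
        w_expect = np.prod(eigs) / (eigs.mean() ** 3)
        assert w == pytest.approx(w_expect, abs=1e-12)
        assert w < 1 and p < 0.05

    def test_epsilon_bounds_and_compound_symmetry(self):
        # compound-symmetric within covariance has spherical contrasts
        k = 4
        sigma = 0.5 * np.eye(k) + 0.5
        from scipy.linalg import helmert
        c = helmert(k, full=False)
        s = c @ sigma @ c.T
        assert gg_epsilon(s) == pytest.approx(1.0, abs=1e-12)
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(3, 3))
            eps = gg_epsilon(a @ a.T)
            assert 1.0 / 3 <= eps <= 1.0


def _mixed_2within_oracle(y, groups):
    """Brute-force balanced mixed-design (A x B within, group between)
    F statistics from classical marginal-mean sums of squares."""
    labels = np.unique(groups)
    n_tot, a, b = y.shape
    n_g = {g: int((groups == g).sum()) for g in labels}
    grand = y.mean()
    m_subj = y.mean(axis=(1, 2))
    m_grp = {g: y[groups == g].mean() for g in labels}

    ss_g = a * b * sum(n_g[g] * (m_grp[g] - grand) ** 2 for g in labels)
    ss_subj = a * b * sum(
        ((m_subj[groups == g] - m_grp[g]) ** 2).sum() for g in labels)
    out = {"group": (ss_g / (len(labels) - 1)) / (ss_subj / (n_tot - len(labels)))}

    def _within(margin_axis, name, df1, per_level):
        # margin_axis: the within axes to average OUT
        m_eff = y.mean(axis=0).mean(axis=margin_axis)  # marginal means
        ss_eff = n_tot * per_level * np.sum((m_eff - grand) ** 2)
        ss_eff_g = 0.0
        ss_err = 0.0
        for g in labels:
            yg = y[groups == g]
            mg = yg.mean(axis=0).mean(axis=margin_axis)
            ss_eff_g += n_g[g] * per_level * np.sum((mg - m_grp[g]) ** 2)
            subj_marg = yg.mean(axis=tuple(ax + 1 for ax in np.atleast_1d(margin_axis)))
            dev = (subj_marg - subj_marg.mean(axis=tuple(range(1, subj_marg.ndim)),
                                              keepdims=True)
                   - mg[None] + m_grp[g])
            ss_err += per_level * np.sum(dev ** 2)
        ss_eff_g -= ss_eff
        df_err = df1 * (n_tot - len(labels))
        out[name] = (ss_eff / df1) / (ss_err / df_err)
        out[f"{name} * group"] = (ss_eff_g / df1) / (ss_err / df_err)

    _within(1, "A", a - 1, b)   # average out B
    _within(0, "B", b - 1, a)   # average out A

    # A x B interaction: double-centered cell means
    m_ab = y.mean(axis=0)
    ia = m_ab - m_ab.mean(axis=0) - m_ab.mean(axis=1, keepdims=True) + grand
    ss_ab = n_tot * np.sum(ia ** 2)
    ss_abg = 0.0
    ss_err = 0.0
    for g in labels:
        yg = y[groups == g]
        mg_ab = yg.mean(axis=0)
        ig = (mg_ab - mg_ab.mean(axis=0) - mg_ab.mean(axis=1, keepdims=True)
              + m_grp[g])
        ss_abg += n_g[g] * np.sum(ig ** 2)
        subj_i = (yg - yg.mean(axis=1, keepdims=True)
                  - yg.mean(axis=2, keepdims=True)
                  + yg.mean(axis=(1, 2), keepdims=True))
        ss_err += np.sum((subj_i - ig[None]) ** 2)
    ss_abg -= ss_ab
    df1 = (a - 1) * (b - 1)
    df_err = df1 * (n_tot - len(labels))
    out["A * B"] = (ss_ab / df1) / (ss_err / df_err)
    out["A * B * group"] = (ss_abg / df1) / (ss_err / df_err)
    return out


def _pingouin_rm(vals):
    n, k = vals.shape
    df = pd.DataFrame({"y": vals.ravel(), "subj": np.repeat(np.arange(n), k),
                       "w": np.tile(np.arange(k), n)})
    aov = pg.rm_anova(df, dv="y", within="w", subject="subj", correction=True)
    sph = pg.sphericity(df, dv="y", within="w", subject="subj")
    return aov, sph


def _pingouin_mixed(vals, groups):
    n, k = vals.shape
    df = pd.DataFrame({"y": vals.ravel(), "subj": np.repeat(np.arange(n), k),
                       "w": np.tile(np.arange(k), n),
                       "g": np.repeat(groups, k)})
    return pg.mixed_anova(df, dv="y", within="w", subject="subj", between="g")


class TestRmAnova:
    def test_two_level_within_forces_epsilon_one(self):
        rng = np.random.default_rng(2)
        res = rm_anova(rng.normal(size=(8, 2)), ("w",))
        r = res[0]
        assert r.epsilon is None or r.epsilon == 1.0
        assert not r.correction_applied

    def test_f_equals_squared_paired_t_on_two_levels(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.normal(size=(9, 2)) + [0.0, 0.4]
            f = rm_anova(vals, ("w",))[0]
            t = paired_t(vals[:, 0], vals[:, 1])
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
            assert f.p_raw == pytest.approx(t.p, rel=1e-10)

    def test_matches_pingouin_single_group(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, k = int(rng.integers(6, 12)), int(rng.integers(3, 6))
            vals = rng.normal(size=(n, k)) @ np.diag(rng.uniform(0.5, 2, k))
            r = rm_anova(vals, ("w",))[0]
            aov, sph = _pingouin_rm(vals)
            assert r.statistic == pytest.approx(float(aov["F"].iloc[0]), abs=1e-8)
            assert r.epsilon == pytest.approx(float(aov["eps"].iloc[0]), abs=1e-8)
            assert r.mauchly_w == pytest.approx(sph.W, abs=1e-8)
            assert r.mauchly_p == pytest.approx(sph.pval, abs=1e-8)
            if r.correction_applied:
                assert r.p == pytest.approx(float(aov["p_GG_corr"].iloc[0]), abs=1e-8)

    def test_matches_pingouin_mixed_balanced(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, k = int(rng.integers(4, 9)), int(rng.integers(2, 5))
            vals = rng.normal(size=(2 * n, k)) + rng.normal(size=(2 * n, 1))
            groups = np.array(["a"] * n + ["b"] * n)
            mine = {r.effect: r for r in rm_anova(vals, ("w",), groups)}
            ref = _pingouin_mixed(vals, groups)
            for src, key in (("g", "group"), ("w", "w"), ("Interaction", "w * group")):
                f_ref = float(ref.loc[ref.Source == src, "F"].iloc[0])
                p_ref = float(ref.loc[ref.Source == src, "p_unc"].iloc[0])
                assert mine[key].statistic == pytest.approx(f_ref, abs=1e-8)
                assert mine[key].p_raw == pytest.approx(p_ref, abs=1e-8)

    def test_two_within_factors_against_ss_oracle(self):
        """Balanced 2-within x 1-between table vs an independent textbook
        sums-of-squares decomposition computed from cell means."""
        rng = np.random.default_rng(6)
        n, a, b = 4, 3, 2  # subjects per group, within levels
        y = rng.normal(size=(2 * n, a, b)) + rng.normal(size=(2 * n, 1, 1))
        groups = np.array(["g1"] * n + ["g2"] * n)
        mine = {r.effect: r for r in rm_anova(y, ("A", "B"), groups)}
        oracle = _mixed_2within_oracle(y, groups)
        for eff in ("group", "A", "A * group", "B", "B * group",
                    "A * B", "A * B * group"):
            assert mine[eff].statistic == pytest.approx(oracle[eff], rel=1e-10), eff

    def test_identical_conditions_give_zero_f(self):
        vals = np.tile(np.arange(6, dtype=float)[:, None], (1, 2))
        res = rm_anova(vals, ("w",))
        assert res[0].statistic == 0.0

    def test_unbalanced_group_sizes_accepted(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(11, 2))
        groups = ["a"] * 5 + ["b"] * 6
        res = {r.effect: r for r in rm_anova(vals, ("w",), groups)}
        assert set(res) == {"group", "w", "w * group"}

    def test_rejects_nan_and_tiny_groups(self):
        with pytest.raises(ValueError):
            rm_anova(np.array([[1.0, np.nan]]), ("w",))
        with pytest.raises(ValueError):
            rm_anova(np.ones((3, 2)), ("w",), ["a", "a", "b"])
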