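import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from reefstress.stats import (
    AbundanceMatrix,
    ContingencyTable,
    DistanceMatrix,
    InputError,
    StateError,
    bray_curtis,
    chi_square,
    holm_adjust,
    pairwise_posthoc,
    pca,
    permanova_oneway,
    permanova_twoway,
    sqrt_transform,
)


def make_matrix(values, state="raw", **meta):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = len(values)
    m = {k: list(v) for k, v in meta.items()} or {"row": list(range(n))}
    return AbundanceMatrix(
        data=pd.DataFrame(values, columns=[f"c{i}" for i in range(values.shape[1])]),
        meta=pd.DataFrame(m),
        transform_state=state,
    )


def euclidean_dm(x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < x.shape[1]:
        x = x.T
    d = ssd.squareform(ssd.pdist(x, "euclidean"))
    return DistanceMatrix(values=d, labels=list(range(len(x))))


class TestSqrtTransform:
    def test_endpoints(self):
        m = sqrt_transform(make_matrix([[0.0, 100.0]]))
        assert m.data.iloc[0, 0] == 0.0
        assert m.data.iloc[0, 1] == 10.0
        assert m.transform_state == "sqrt"

    def test_inverse_property(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, size=(5, 4))
        m = sqrt_transform(make_matrix(vals))
        np.testing.assert_allclose(m.data.to_numpy() ** 2, vals)

    def test_double_transform_rejected(self):
        m = sqrt_transform(make_matrix([[1.0, 2.0]]))
        with pytest.raises(StateError):
            sqrt_transform(m)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            make_matrix([[-1.0]])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = make_matrix([[1, 2, 3], [1, 2, 3]], state="sqrt")
        assert bray_curtis(m).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        m = make_matrix([[1, 0, 2], [0, 3, 0]], state="sqrt")
        assert bray_curtis(m).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        m = make_matrix([[1, 2, 3], [2, 1, 3]], state="sqrt")
        assert bray_curtis(m).values[0, 1] == pytest.approx(2 / 12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 50, size=(6, 5))
        d = bray_curtis(make_matrix(vals, state="sqrt")).values
        for i, j in itertools.combinations(range(6), 2):
            assert d[i, j] == pytest.approx(ssd.braycurtis(vals[i], vals[j]))

    def test_properties(self):
        rng = np.random.default_rng(3)
        d = bray_curtis(
            make_matrix(rng.uniform(0, 10, size=(8, 6)), state="sqrt")
        ).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_zero_pair_warned(self):
        m = make_matrix([[0, 0], [0, 0], [1, 2]], state="sqrt")
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(m)
        assert d.values[0, 1] == 0.0

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            bray_curtis(make_matrix([[1, 2]], state="sqrt"))

    def test_raw_state_warns(self):
        with pytest.warns(UserWarning, match="untransformed"):
            bray_curtis(make_matrix([[1, 2], [2, 1]]))


def oneway_f_brute(d, groups):
    """Independent loop-based one-way pseudo-F."""
    d = np.asarray(d, dtype=float)
    n = len(groups)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    levels = sorted(set(groups))
    for g in levels:
        idx = [i for i in range(n) if groups[i] == g]
        ss_w += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    a = len(levels)
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


class TestPermanovaOneway:
    def test_ss_conservation(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.uniform(0, 10, size=(12, 5)), state="sqrt")
        d = bray_curtis(m)
        res = permanova_oneway(d, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert res.terms[0].ss + res.residual_ss == pytest.approx(res.total_ss)
        assert res.terms[0].df + res.residual_df == res.total_df

    def test_f_matches_brute_force(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.uniform(0, 10, size=(9, 4)), state="sqrt")
        groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        d = bray_curtis(m)
        res = permanova_oneway(d, groups, n_perm=9, seed=0)
        assert res.terms[0].f == pytest.approx(oneway_f_brute(d.values, groups))

    def test_euclidean_univariate_equals_classical_anova(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        d = euclidean_dm(y[:, None])
        res = permanova_oneway(d, groups, n_perm=9, seed=0)
        f_classic = scipy.stats.f_oneway(*(y[groups == g] for g in "abc")).statistic
        assert res.terms[0].f == pytest.approx(f_classic, rel=1e-10)

    def test_perfect_separation_floor(self):
        x = np.vstack([np.random.default_rng(7).normal(0, 0.01, (8, 3)),
                       np.random.default_rng(8).normal(50, 0.01, (8, 3))])
        d = euclidean_dm(x)
        res = permanova_oneway(d, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=1)
        assert res.terms[0].p == pytest.approx(1 / 1000)

    def test_exact_enumeration_matches_oracle(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.uniform(0, 10, size=(6, 4)), state="sqrt")
        groups = ["a", "a", "a", "b", "b", "b"]
        d = bray_curtis(m)
        res = permanova_oneway(d, groups, n_perm="exact")
        f_obs = oneway_f_brute(d.values, groups)
        count = sum(
            oneway_f_brute(d.values[np.ix_(p, p)], groups) >= f_obs - 1e-12
            for p in map(list, itertools.permutations(range(6)))
        )
        assert res.terms[0].p == pytest.approx(count / 720)

    def test_singleton_group_named(self):
        d = euclidean_dm(np.arange(5)[:, None])
        with pytest.raises(InputError, match="'b'"):
            permanova_oneway(d, ["a", "a", "a", "a", "b"])

    def test_nonconforming_labels(self):
        d = euclidean_dm(np.arange(4)[:, None])
        with pytest.raises(InputError, match="conform"):
            permanova_oneway(d, ["a", "a", "b"])

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.uniform(0, 10, size=(10, 4)), state="sqrt")
        d = bray_curtis(m)
        g = ["a"] * 5 + ["b"] * 5
        p1 = permanova_oneway(d, g, n_perm=199, seed=42).terms[0].p
        p2 = permanova_oneway(d, g, n_perm=199, seed=42).terms[0].p
        assert p1 == p2

    def test_invariant_to_row_order_and_relabel(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 10, size=(10, 4))
        g = np.array(["a"] * 5 + ["b"] * 5)
        d = bray_curtis(make_matrix(vals, state="sqrt"))
        f1 = permanova_oneway(d, g, n_perm=9, seed=0).terms[0].f
        perm = rng.permutation(10)
        d2 = bray_curtis(make_matrix(vals[perm], state="sqrt"))
        f2 = permanova_oneway(d2, g[perm], n_perm=9, seed=0).terms[0].f
        relabel = np.where(g == "a", "x", "y")
        f3 = permanova_oneway(d, relabel, n_perm=9, seed=0).terms[0].f
        assert f1 == pytest.approx(f2)
        assert f1 == pytest.approx(f3)


def anova_typeI_ss(y, fa, fb):
    """Classical sequential two-way ANOVA sums of squares via statsmodels."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": y, "a": fa, "b": fb})
    model = ols("y ~ C(a) + C(b) + C(a):C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    return (
        tab.loc["C(a)", "sum_sq"],
        tab.loc["C(b)", "sum_sq"],
        tab.loc["C(a):C(b)", "sum_sq"],
        tab.loc["Residual", "sum_sq"],
    )


class TestPermanovaTwoway:
    def test_euclidean_univariate_matches_classical_anova(self):
        rng = np.random.default_rng(12)
        fa = np.repeat(["t1", "t2"], 12)
        fb = np.tile(np.repeat(["s1", "s2", "s3"], 4), 2)
        y = rng.normal(size=24) + (fa == "t2") * 1.5
        d = euclidean_dm(y[:, None])
        res = permanova_twoway(d, fa, fb, n_perm=9, seed=0)
        ss = anova_typeI_ss(y, fa, fb)
        assert res.terms[0].ss == pytest.approx(ss[0], abs=1e-8)
        assert res.terms[1].ss == pytest.approx(ss[1], abs=1e-8)
        assert res.terms[2].ss == pytest.approx(ss[2], abs=1e-8)
        assert res.residual_ss == pytest.approx(ss[3], abs=1e-8)

    def test_unbalanced_sequential_partition(self):
        rng = np.random.default_rng(13)
        fa = np.array(["x"] * 5 + ["y"] * 7)
        fb = np.array(["p", "q"] * 6)
        y = rng.normal(size=12)
        res = permanova_twoway(euclidean_dm(y[:, None]), fa, fb, n_perm=9, seed=0)
        ss = anova_typeI_ss(y, fa, fb)
        for got, want in zip(
            [res.terms[0].ss, res.terms[1].ss, res.terms[2].ss, res.residual_ss], ss
        ):
            assert got == pytest.approx(want, abs=1e-8)

    def test_ss_conservation(self):
        rng = np.random.default_rng(14)
        m = make_matrix(rng.uniform(0, 10, size=(16, 5)), state="sqrt")
        d = bray_curtis(m)
        fa = np.repeat(["t1", "t2"], 8)
        fb = np.tile(np.repeat(["s1", "s2"], 4), 2)
        res = permanova_twoway(d, fa, fb, n_perm=49, seed=0)
        total = sum(t.ss for t in res.terms) + res.residual_ss
        assert total == pytest.approx(res.total_ss, abs=1e-8)
        assert sum(t.df for t in res.terms) + res.residual_df == res.total_df

    def test_single_level_b_reduces_to_oneway(self):
        rng = np.random.default_rng(15)
        m = make_matrix(rng.uniform(0, 10, size=(10, 4)), state="sqrt")
        d = bray_curtis(m)
        fa = ["a"] * 5 + ["b"] * 5
        fb = ["only"] * 10
        res2 = permanova_twoway(d, fa, fb, n_perm=99, seed=3)
        res1 = permanova_oneway(d, fa, n_perm=99, seed=3)
        assert res2.terms[1].ss == pytest.approx(0.0, abs=1e-10)
        assert res2.terms[0].ss == pytest.approx(res1.terms[0].ss)
        assert res2.terms[0].f == pytest.approx(res1.terms[0].f)

    def test_empty_cell_rejected(self):
        d = euclidean_dm(np.arange(6)[:, None])
        fa = ["x", "x", "x", "y", "y", "y"]
        fb = ["p", "p", "p", "q", "q", "q"]  # x never meets q
        with pytest.raises(InputError, match="empty"):
            permanova_twoway(d, fa, fb)

    def test_reproducible(self):
        rng = np.random.default_rng(16)
        m = make_matrix(rng.uniform(0, 10, size=(16, 4)), state="sqrt")
        d = bray_curtis(m)
        fa = np.repeat(["t1", "t2"], 8)
        fb = np.tile(np.repeat(["s1", "s2"], 4), 2)
        r1 = permanova_twoway(d, fa, fb, n_perm=99, seed=5)
        r2 = permanova_twoway(d, fa, fb, n_perm=99, seed=5)
        assert [t.p for t in r1.terms] == [t.p for t in r2.terms]


class TestHolm:
    def test_hand_worked_ladder(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_all_equal_first_step(self):
        adj = holm_adjust([0.01] * 4)
        assert adj.min() == pytest.approx(0.04)

    def test_single_pair_unchanged(self):
        assert holm_adjust([0.3])[0] == pytest.approx(0.3)

    def test_capped_at_one(self):
        assert (holm_adjust([0.5, 0.9, 0.99]) <= 1.0).all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_sorted_order(self, pvals):
        adj = holm_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()

    def test_matches_scipy_holm(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0, 1, size=8)
        from scipy.stats import false_discovery_control  # noqa: F401  (not holm)
        import statsmodels.stats.multitest as smm

        _, adj, _, _ = smm.multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), adj, atol=1e-12)


class TestPairwisePosthoc:
    def test_three_groups_table(self):
        rng = np.random.default_rng(18)
        x = np.vstack(
            [
                rng.uniform(0, 5, (4, 3)),
                rng.uniform(5, 10, (4, 3)),
                rng.uniform(10, 15, (4, 3)),
            ]
        )
        d = bray_curtis(make_matrix(x, state="sqrt"))
        groups = np.repeat(["a", "b", "c"], 4)
        out = pairwise_posthoc(d, groups, n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()

    def test_adjustment_is_holm(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 10, (12, 4))
        d = bray_curtis(make_matrix(x, state="sqrt"))
        out = pairwise_posthoc(d, np.repeat(["a", "b", "c"], 4), n_perm=99, seed=1)
        np.testing.assert_allclose(
            out["p_adjusted"], holm_adjust(out["p_raw"].to_numpy())
        )


class TestPca:
    def test_rank1_data_pc1_captures_all(self):
        t = np.linspace(0, 1, 6)
        m = make_matrix(np.column_stack([t, 2 * t]), state="sqrt")
        res = pca(m)
        assert res.variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=(10, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        e1 = pca(make_matrix(np.abs(x), state="sqrt")).eigenvalues
        # rotation can produce negatives; bypass abundance positivity by
        # shifting (PCA is shift invariant)
        xr = np.abs(x) @ q
        xr -= xr.min() - 1.0
        e2 = pca(make_matrix(xr, state="sqrt")).eigenvalues
        np.testing.assert_allclose(np.sort(e1), np.sort(e2), atol=1e-8)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 10, size=(8, 5))
        m = make_matrix(x, state="sqrt")
        res = pca(m)
        xc = x - x.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, xc, atol=1e-8)

    def test_variance_ratios_sum_to_one(self):
        rng = np.random.default_rng(22)
        res = pca(make_matrix(rng.uniform(0, 10, (7, 4)), state="sqrt"))
        assert res.variance_ratio.sum() == pytest.approx(1.0)
        assert (res.eigenvalues >= -1e-9).all()

    def test_sign_convention(self):
        rng = np.random.default_rng(23)
        res = pca(make_matrix(rng.uniform(0, 10, (9, 5)), state="sqrt"))
        for c in res.loadings.columns:
            col = res.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_identical_rows_rejected(self):
        with pytest.raises(InputError, match="rank"):
            pca(make_matrix([[1, 2], [1, 2], [1, 2]], state="sqrt"))

    def test_too_few_rows(self):
        with pytest.raises(InputError):
            pca(make_matrix([[1, 2], [3, 4]], state="sqrt"))


class TestChiSquare:
    def test_pooled_bremer_table(self):
        t = ContingencyTable(np.array([[41, 4], [72, 6]]), ["dec", "mar"], ["UB", "M"])
        res = chi_square(t)
        assert round(res.statistic, 2) == 0.05
        assert res.df == 1
        assert round(res.p, 1) == 0.8

    def test_proportional_rows_zero(self):
        t = ContingencyTable(np.array([[10, 20], [30, 60]]), ["r1", "r2"], ["c1", "c2"])
        assert chi_square(t).statistic == pytest.approx(0.0)

    def test_random_table_matches_brute_oracle(self):
        rng = np.random.default_rng(24)
        counts = rng.integers(1, 40, size=(2, 3))
        t = ContingencyTable(counts, ["r1", "r2"], ["c1", "c2", "c3"])
        res = chi_square(t)
        grand = counts.sum()
        stat = 0.0
        for i in range(2):
            for j in range(3):
                e = counts[i].sum() * counts[:, j].sum() / grand
                stat += (counts[i, j] - e) ** 2 / e
        assert res.statistic == pytest.approx(stat)
        assert res.df == 2

    def test_matches_scipy_with_and_without_yates(self):
        counts = np.array([[12, 7], [5, 22]])
        t = ContingencyTable(counts, ["a", "b"], ["x", "y"])
        for corr, flag in (("none", False), ("yates", True)):
            res = chi_square(t, correction=corr)
            s, p, df, _ = scipy.stats.chi2_contingency(counts, correction=flag)
            assert res.statistic == pytest.approx(s)
            assert res.p == pytest.approx(p)
            assert res.df == df

    def test_zero_margin_named(self):
        t = ContingencyTable(np.array([[0, 0], [1, 2]]), ["dec", "mar"], ["UB", "M"])
        with pytest.raises(InputError, match="row 'dec'"):
            chi_square(t)

    def test_table_shape_validation(self):
        with pytest.raises(InputError):
            ContingencyTable(np.array([[1, 2]]), ["r"], ["c1", "c2"])

    def test_non_integer_rejected(self):
        with pytest.raises(InputError):
            ContingencyTable(np.array([[1.5, 2.0], [1.0, 1.0]]), ["a", "b"], ["x", "y"])


class TestNullValidity:
    """Permutation p-values are valid under the null (small simulations)."""

    def test_oneway_null_uniformity(self):
        rng = np.random.default_rng(100)
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            x = rng.uniform(0, 10, size=(12, 4))
            d = bray_curtis(make_matrix(x, state="sqrt"))
            res = permanova_oneway(
                d, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=rng
            )
            if res.terms[0].p <= 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.11  # alpha + ~3 binomial SE

    def test_twoway_interaction_null(self):
        rng = np.random.default_rng(101)
        rejections = 0
        n_sim = 60
        fa = np.repeat(["t1", "t2"], 8)
        fb = np.tile(np.repeat(["s1", "s2"], 4), 2)
        for _ in range(n_sim):
            # additive shifts, no interaction
            x = rng.uniform(0, 5, size=(16, 4))
            x[fa == "t2"] += 1.0
            x[fb == "s2"] += 0.5
            d = bray_curtis(make_matrix(x, state="sqrt"))
            res = permanova_twoway(d, fa, fb, n_perm=99, seed=rng)
            if res.terms[2].p <= 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.15
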