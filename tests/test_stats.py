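"""Statistical battery against closed forms and independently coded oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats
from hypothesis import given, settings, strategies as st

from bpequant.stats import (
    ConditionalLogit,
    bh_fdr,
    delong_test,
    lr_test,
    paired_t,
    roc_auc,
    spearman,
    unconditional_logistic,
)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3 + 2)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 7.0, 7.0, 9.0])
        rho, _ = spearman(x, y)
        rx = scipy.stats.rankdata(x)  # average ranks
        ry = scipy.stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------

def _conditional_nll(beta, diffs):
    """Independent conditional negative log-likelihood (for oracles)."""
    eta = diffs @ np.atleast_1d(beta)
    return float(np.sum(np.log1p(np.exp(-eta))))


class TestConditionalLogit:
    def test_discordant_pair_closed_form(self):
        # 10 pairs exposed-case-only, 5 pairs exposed-control-only:
        # the discordant-pair ratio gives OR = 10/5 = 2, beta = ln 2
        diffs = np.array([[1.0]] * 10 + [[-1.0]] * 5)
        fit = ConditionalLogit(diffs, ["exposure"], increments=[1.0]).fit()
        assert fit.converged
        assert fit.params["exposure"] == pytest.approx(np.log(2.0), abs=1e-6)
        assert fit.or_per_increment().loc["exposure", "odds_ratio"] == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_grid_search_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        diffs = rng.normal(0.3, 1.0, size=(n, 1))
        fit = ConditionalLogit(diffs, ["x"], increments=[1.0]).fit()
        oracle = scipy.optimize.minimize_scalar(
            lambda b: _conditional_nll(b, diffs), bounds=(-20, 20), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert abs(fit.params["x"] - oracle) < 1e-6

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit as SmClogit

        rng = np.random.default_rng(7)
        n = 40
        x_case = rng.normal(1.0, 1.0, size=(n, 2))
        x_ctrl = rng.normal(0.0, 1.0, size=(n, 2))
        diffs = x_case - x_ctrl
        fit = ConditionalLogit(diffs, ["a", "b"], increments=[1.0, 1.0]).fit()
        endog = np.tile([1.0, 0.0], n)
        exog = np.empty((2 * n, 2))
        exog[0::2] = x_case
        exog[1::2] = x_ctrl
        groups = np.repeat(np.arange(n), 2)
        sm_fit = SmClogit(endog, exog, groups=groups).fit(disp=0)
        assert fit.params.to_numpy() == pytest.approx(sm_fit.params, abs=1e-5)
        assert fit.bse.to_numpy() == pytest.approx(sm_fit.bse, abs=1e-4)

    def test_flat_likelihood_flagged(self):
        fit = ConditionalLogit(np.zeros((8, 1)), ["x"], increments=[1.0]).fit()
        assert "flat" in fit.flags
        assert fit.params["x"] == 0.0
        assert fit.n_pairs_used == 0

    def test_separation_flagged_without_odds_ratio(self):
        diffs = np.ones((12, 1))  # every case exposed, no control: monotone likelihood
        fit = ConditionalLogit(diffs, ["x"], increments=[1.0]).fit()
        assert "separation" in fit.flags
        assert not fit.converged
        with pytest.raises(ValueError):
            fit.or_per_increment()

    def test_summary_mentions_exposure(self):
        fit = ConditionalLogit(
            np.array([[1.0]] * 10 + [[-1.0]] * 5), ["bpe_pct_sub1"]
        ).fit()
        text = fit.summary()
        assert "bpe_pct_sub1" in text and "Conditional logistic" in text


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Step-up adjusted p-values, coded independently from the implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_printed_family_bounded(self):
        # six univariate matched-pair p-values; step-up keeps all below the
        # largest raw value in this configuration
        p = [0.026, 0.025, 0.031, 0.018, 0.012, 0.021]
        adj = bh_fdr(p)
        assert np.all(adj <= 0.031)
        assert adj == pytest.approx(_bh_oracle(p), abs=1e-15)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.042])[0] == pytest.approx(0.042)

    def test_constant_ratio_family(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_properties_and_oracle_equality(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        assert adj == pytest.approx(_bh_oracle(p), abs=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # order-preserving

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# unconditional logistic / AUC / DeLong / LRT / paired t
# ---------------------------------------------------------------------------

def _records(y, **cols):
    df = pd.DataFrame(cols)
    df["group"] = np.where(np.asarray(y, dtype=bool), "case", "control")
    return df


class TestUnconditionalLogistic:
    def test_intercept_only_fits_case_fraction(self):
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        fit = unconditional_logistic(_records(y), [])
        assert fit.fitted == pytest.approx(np.full(10, 0.3), abs=1e-8)

    def test_binary_predictor_matches_contingency_odds_ratio(self):
        # 2x2 table: exposed 12 cases / 4 controls, unexposed 6 / 10
        y = [1] * 12 + [0] * 4 + [1] * 6 + [0] * 10
        x = [1.0] * 16 + [0.0] * 16
        fit = unconditional_logistic(_records(y, x=x), ["x"])
        oracle = np.log((12 * 10) / (4 * 6))
        assert fit.params["x"] == pytest.approx(oracle, abs=1e-6)

    def test_deviance_never_increases_with_predictors(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=80)
        df = _records(y, a=rng.normal(size=80), b=rng.normal(size=80))
        l0 = unconditional_logistic(df, []).llf
        l1 = unconditional_logistic(df, ["a"]).llf
        l2 = unconditional_logistic(df, ["a", "b"]).llf
        assert l0 <= l1 + 1e-10 <= l2 + 2e-10


class TestRocAuc:
    def test_extremes_and_small_oracle(self):
        assert roc_auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([3.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        # cases {3,1}, controls {2,0}: 3 of 4 pairings won -> 0.75
        assert roc_auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_brute_force_pair_oracle(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=30)
        scores[rng.integers(0, 30, 6)] = scores[0]  # inject ties
        y = rng.integers(0, 2, size=30).astype(bool)
        wins = 0.0
        for sc in scores[y]:
            for sn in scores[~y]:
                wins += 1.0 if sc > sn else (0.5 if sc == sn else 0.0)
        assert roc_auc(scores, y) == pytest.approx(wins / (y.sum() * (~y).sum()), abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda s: s ** 3, lambda s: 2 * s + 7])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=40)
        y = rng.integers(0, 2, size=40).astype(bool)
        assert roc_auc(transform(scores), y) == pytest.approx(roc_auc(scores, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


def _delong_oracle(a, b, y):
    """Placement-value DeLong variance, coded directly from the definition."""
    a, b, y = np.asarray(a, float), np.asarray(b, float), np.asarray(y, bool)
    cases, ctrls = np.where(y)[0], np.where(~y)[0]
    m, n = len(cases), len(ctrls)
    v10 = {"a": np.zeros(m), "b": np.zeros(m)}
    v01 = {"a": np.zeros(n), "b": np.zeros(n)}
    for name, s in (("a", a), ("b", b)):
        for i, ci in enumerate(cases):
            v10[name][i] = np.mean(
                [1.0 if s[ci] > s[cj] else 0.5 if s[ci] == s[cj] else 0.0 for cj in ctrls]
            )
        for j, cj in enumerate(ctrls):
            v01[name][j] = np.mean(
                [1.0 if s[ci] > s[cj] else 0.5 if s[ci] == s[cj] else 0.0 for ci in cases]
            )
    s10 = np.cov(np.vstack([v10["a"], v10["b"]]), ddof=1)
    s01 = np.cov(np.vstack([v01["a"], v01["b"]]), ddof=1)
    cov = s10 / m + s01 / n
    return cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]


class TestDelong:
    def test_identical_scores_degenerate(self):
        y = [1, 0, 1, 0, 1, 0]
        s = [3.0, 1.0, 2.5, 0.5, 2.0, 1.5]
        res = delong_test(s, s, y)
        assert res.degenerate and res.p == 1.0
        assert res.auc_a == res.auc_b

    def test_variance_matches_placement_oracle(self):
        rng = np.random.default_rng(19)
        y = np.array([1] * 8 + [0] * 10)
        a = rng.normal(size=18) + y
        b = 0.5 * a + rng.normal(size=18)
        res = delong_test(a, b, y)
        var_oracle = _delong_oracle(a, b, y)
        var_impl = res.var_a + res.var_b - 2 * res.cov_ab
        assert var_impl == pytest.approx(var_oracle, abs=1e-12)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(23)
        y = np.array([1] * 10 + [0] * 10)
        a = rng.normal(size=20) + 0.8 * y
        b = rng.normal(size=20) + 0.4 * y
        ab = delong_test(a, b, y)
        ba = delong_test(b, a, y)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p == pytest.approx(ba.p, abs=1e-12)


class TestLrTest:
    def test_zero_when_models_equal_likelihood(self):
        rng = np.random.default_rng(29)
        y = rng.integers(0, 2, size=60)
        df = _records(y, a=rng.normal(size=60), noise=np.zeros(60) + 1.0)
        base = unconditional_logistic(df, ["a"])
        # adding a constant column cannot improve the likelihood
        full = unconditional_logistic(df, ["a", "noise"])
        chi2, dof, p = lr_test(base, full)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert dof == 1
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_chi2_nonnegative_and_nesting_enforced(self):
        rng = np.random.default_rng(31)
        y = rng.integers(0, 2, size=60)
        df = _records(y, a=rng.normal(size=60), b=rng.normal(size=60))
        base = unconditional_logistic(df, ["a"])
        full = unconditional_logistic(df, ["a", "b"])
        chi2, dof, _ = lr_test(base, full)
        assert chi2 >= 0.0 and dof == 1
        other = unconditional_logistic(df, ["b"])
        with pytest.raises(ValueError):
            lr_test(other, base)


class TestPairedT:
    def test_symmetric_differences_give_null(self):
        res = paired_t([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_constant_difference_degenerate(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate

    def test_matches_scipy_on_fixed_pairs(self):
        case = np.array([45.0, 51.0, 39.0, 60.0, 47.0])
        ctrl = np.array([40.0, 49.0, 41.0, 52.0, 44.0])
        res = paired_t(case, ctrl)
        t_ref, p_ref = scipy.stats.ttest_rel(case, ctrl)
        assert res.t == pytest.approx(t_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)
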