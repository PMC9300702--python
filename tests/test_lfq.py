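"""Unit and property tests of the LFQ interactor-calling statistics."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats
from hypothesis import given, settings, strategies as st

from interactome import (
    BackgroundFrequencyTable,
    CallingParams,
    ImputationParams,
    bh_fdr,
    call_interactors,
    compute_ratios,
    export_volcano,
    filter_by_valid_values,
    flag_background,
    impute_downshifted_normal,
    log2_transform,
    one_sample_ttest,
)
from conftest import make_matrix

NA = float("nan")


# ---------------------------------------------------------------------------
# independent oracles


def bh_bruteforce(pvals):
    """Step-up q-values by direct enumeration: q_(i) = min_{k>=i} p_(k) * n / k."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[k]] * n / (k + 1) for k in range(rank_pos, n)]
        q[idx] = min(1.0, min(candidates))
    return q


def t_pvalue_betainc(x):
    """Two-sided one-sample t p-value via the regularized incomplete beta."""
    x = np.asarray(x, float)
    n = len(x)
    t = x.mean() / (x.std(ddof=1) / math.sqrt(n))
    df = n - 1
    return scipy.special.betainc(df / 2.0, 0.5, df / (df + t * t))


# ---------------------------------------------------------------------------
# filtering


class TestFilter:
    def params(self, min_valid=3, n_rep=4):
        return CallingParams(min_valid=min_valid, n_replicates=n_rep)

    def test_kept_when_one_group_fully_valid(self):
        vals = {f"surface_{i}": [10.0] for i in range(1, 5)}
        vals |= {f"endosomal_{i}": [NA] for i in range(1, 5)}
        vals |= {f"control_{i}": [NA] for i in range(1, 5)}
        m = make_matrix(vals)
        assert list(filter_by_valid_values(m, self.params()).protein_ids) == ["P0"]

    def test_removed_when_below_threshold_everywhere(self):
        vals = {f"{g}_{i}": [10.0 if i <= 2 else NA]
                for g in ("surface", "endosomal", "control") for i in range(1, 5)}
        m = make_matrix(vals)
        assert len(filter_by_valid_values(m, self.params()).protein_ids) == 0

    def test_min_valid_zero_is_row_identity(self):
        vals = {f"{g}_{i}": [NA, 5.0] for g in ("surface", "endosomal", "control")
                for i in range(1, 5)}
        m = make_matrix(vals)
        out = filter_by_valid_values(m, self.params(min_valid=0))
        assert list(out.protein_ids) == list(m.protein_ids)

    def test_column_set_and_order_preserved(self):
        vals = {f"{g}_{i}": [10.0, NA] for g in ("surface", "endosomal", "control")
                for i in range(1, 5)}
        m = make_matrix(vals)
        out = filter_by_valid_values(m, self.params())
        assert list(out.values.columns) == list(m.values.columns)


# ---------------------------------------------------------------------------
# log2


class TestLog2:
    def test_value_and_missingness(self):
        m = make_matrix({"surface_1": [8.0, NA], "control_1": [1.0, 2.0]})
        out = log2_transform(m)
        assert out.scale == "log2"
        assert out.values.iloc[0, 0] == 3.0
        assert np.isnan(out.values.iloc[1, 0])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        m = make_matrix({"surface_1": rng.lognormal(3, 1, 50).tolist()})
        out = log2_transform(m)
        back = 2.0 ** out.values.to_numpy()
        np.testing.assert_allclose(back, m.values.to_numpy(), rtol=1e-12)

    def test_nonpositive_rejected_with_context(self):
        m = make_matrix({"surface_1": [4.0, -1.0]})
        with pytest.raises(ValueError, match="P1.*surface_1"):
            log2_transform(m)


# ---------------------------------------------------------------------------
# imputation


class TestImputation:
    def test_no_missing_is_identity(self, small_log2_matrix):
        out = impute_downshifted_normal(small_log2_matrix, ImputationParams(seed=1))
        pd.testing.assert_frame_equal(out.values, small_log2_matrix.values)

    def test_draws_match_stated_normal(self):
        # column whose observed sample mean is exactly 25 and SD exactly 2
        z = np.array([-1.5, -0.5, 0.5, 1.5])
        observed = 25.0 + 2.0 * z / z.std(ddof=1)
        n_miss = 100_000
        col = np.concatenate([observed, np.full(n_miss, NA)])
        df = pd.DataFrame({"control_1": col})
        df.index = pd.Index([f"P{i}" for i in range(len(col))], name="protein_id")
        from interactome import IntensityMatrix

        m = IntensityMatrix(values=df, scale="log2")
        out = impute_downshifted_normal(m, ImputationParams(width=0.3, downshift=1.8, seed=11))
        draws = out.values["control_1"].to_numpy()[4:]
        # target: Normal(25 - 1.8*2 = 21.4, 0.6^2); 3 Monte-Carlo SEs
        se_mean = 0.6 / math.sqrt(n_miss)
        se_sd = 0.6 / math.sqrt(2 * n_miss)
        assert abs(draws.mean() - 21.4) < 3 * se_mean
        assert abs(draws.std(ddof=1) - 0.6) < 3 * se_sd

    def test_observed_cells_unchanged_and_deterministic(self):
        df = pd.DataFrame({"control_1": [24.0, 26.0, NA, NA, 25.0]})
        df.index = pd.Index([f"P{i}" for i in range(5)], name="protein_id")
        from interactome import IntensityMatrix

        m = IntensityMatrix(values=df, scale="log2")
        a = impute_downshifted_normal(m, ImputationParams(seed=5))
        b = impute_downshifted_normal(m, ImputationParams(seed=5))
        pd.testing.assert_frame_equal(a.values, b.values)
        assert a.values["control_1"].iloc[[0, 1, 4]].tolist() == [24.0, 26.0, 25.0]

    def test_width_zero_forbidden(self):
        with pytest.raises(ValueError):
            ImputationParams(width=0.0)

    def test_too_few_observed_rejected(self):
        df = pd.DataFrame({"control_1": [24.0, NA, NA]})
        df.index = pd.Index(["P0", "P1", "P2"], name="protein_id")
        from interactome import IntensityMatrix

        m = IntensityMatrix(values=df, scale="log2")
        with pytest.raises(ValueError, match="control_1"):
            impute_downshifted_normal(m, ImputationParams(seed=0))


# ---------------------------------------------------------------------------
# ratios


class TestRatios:
    def test_identical_columns_give_zero(self, small_log2_matrix):
        m = small_log2_matrix
        m.values[m.columns_for("surface")] = m.values[m.columns_for("control")].to_numpy()
        ratios = compute_ratios(m, "surface")
        np.testing.assert_allclose(ratios.to_numpy(), 0.0)

    def test_hand_arithmetic_linear_example(self):
        m = make_matrix({"surface_1": [4.0], "surface_2": [8.0],
                         "control_1": [2.0], "control_2": [2.0]})
        ratios = compute_ratios(log2_transform(m), "surface")
        np.testing.assert_allclose(ratios.to_numpy(), [[1.0, 2.0]])

    def test_shift_invariance(self, small_log2_matrix):
        base = compute_ratios(small_log2_matrix, "endosomal")
        shifted = small_log2_matrix.copy_with(small_log2_matrix.values + 3.7)
        np.testing.assert_allclose(
            compute_ratios(shifted, "endosomal").to_numpy(), base.to_numpy(), atol=1e-12
        )

    def test_unequal_replicates_rejected(self):
        m = make_matrix({"surface_1": [4.0], "surface_2": [8.0], "control_1": [2.0]},
                        scale="log2")
        with pytest.raises(ValueError, match="replicate"):
            compute_ratios(m, "surface")


# ---------------------------------------------------------------------------
# one-sample t-test


class TestTTest:
    def frame(self, *rows):
        return pd.DataFrame(list(rows),
                            index=pd.Index([f"P{i}" for i in range(len(rows))]))

    def test_symmetric_mean_zero(self):
        out = one_sample_ttest(self.frame([0.5, -0.5, 0.3, -0.3]))
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_independent_cdf_evaluation(self):
        x = [1.0, 0.8, 1.2, 1.0]
        out = one_sample_ttest(self.frame(x))
        expected_p = t_pvalue_betainc(x)
        res = scipy.stats.ttest_1samp(x, 0.0)
        assert out["p"].iloc[0] == pytest.approx(expected_p, abs=1e-10)
        assert out["t"].iloc[0] == pytest.approx(res.statistic, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(res.pvalue, abs=1e-10)

    def test_single_ratio_rejected(self):
        with pytest.raises(ValueError):
            one_sample_ttest(self.frame([1.0]))

    def test_zero_sd_degenerate_flags(self):
        out = one_sample_ttest(self.frame([1.0, 1.0, 1.0], [0.0, 0.0, 0.0]))
        assert out["degenerate"].all()
        assert out["p"].tolist() == [0.0, 1.0]

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8).filter(
        lambda v: np.std(v, ddof=1) > 1e-6))
    @settings(derandomize=True, max_examples=50)
    def test_property_matches_scipy(self, x):
        out = one_sample_ttest(self.frame(x))
        res = scipy.stats.ttest_1samp(x, 0.0)
        assert out["p"].iloc[0] == pytest.approx(res.pvalue, abs=1e-10)


# ---------------------------------------------------------------------------
# BH FDR


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.04]), [0.04])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=200)
    def test_matches_bruteforce_enumeration(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_bruteforce(pvals), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=50)
    def test_q_monotone_in_p_rank(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(pvals) / len(pvals) - 1e-12).all()


# ---------------------------------------------------------------------------
# calling / flags / volcano


def enrichment_row(fc, p, q=None):
    return pd.DataFrame(
        {"protein_id": ["P0"], "compartment": ["surface"],
         "mean_log2_ratio": [math.log2(fc)], "t": [1.0], "p": [p],
         "q": [p if q is None else q], "degenerate": [False],
         "interactor": [False], "background_flag": [False]}
    )


class TestCalling:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.6, 0.03, True),    # clears both thresholds
            (1.5, 0.049, True),   # "at least 1.5" is inclusive
            (3.0, 0.05, False),   # "lower than 0.05" is strict
            (1.49, 0.001, False),  # fold change below threshold
        ],
    )
    def test_threshold_boundaries(self, fc, p, expected):
        out = call_interactors(enrichment_row(fc, p), CallingParams())
        assert bool(out["interactor"].iloc[0]) is expected

    def test_use_q_mode(self):
        table = enrichment_row(2.0, 0.01, q=0.2)
        assert call_interactors(table, CallingParams()).interactor.iloc[0]
        assert not call_interactors(table, CallingParams(use_q=True)).interactor.iloc[0]

    def test_background_flag_rules(self):
        table = call_interactors(enrichment_row(2.0, 0.01), CallingParams())
        bg = BackgroundFrequencyTable(pd.Series({"P0": 0.60}))
        flagged = flag_background(table, bg)
        assert flagged["background_flag"].iloc[0]
        assert flagged["interactor"].iloc[0]  # flag never changes the call
        absent = flag_background(table, BackgroundFrequencyTable(pd.Series({"X": 0.9})))
        assert not absent["background_flag"].iloc[0]

    def test_volcano_export(self):
        table = call_interactors(enrichment_row(2.0, 0.01), CallingParams())
        v = export_volcano(table)
        assert v["neg_log10_p"].iloc[0] == pytest.approx(2.0)
        assert len(v) == len(table)
        assert v["interactor"].tolist() == table["interactor"].tolist()
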