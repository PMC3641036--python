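"""Statistical operations against independent oracles.

Every closed-form statistic is checked against a brute-force
reduced-vs-full residual-sum-of-squares oracle (or the equivalent scipy /
statsmodels routine) on random instances, and the degenerate-input
conventions are pinned.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from regenscreen.core_io import ExpressionMatrix, SampleDesign
from regenscreen.stats import (
    bh_fdr,
    fold_change,
    lsd_consecutive,
    one_way_anova,
    paired_t_per_timepoint,
    two_fold_rule,
    two_way_anova,
    two_way_time_condition_anova,
)


def rss_f_test(y, design_full, design_reduced, df_effect):
    """Reduced-vs-full regression F from residual sums of squares."""
    rss = []
    for X in (design_reduced, design_full):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss.append(((y - X @ beta) ** 2).sum())
    df_err = len(y) - np.linalg.matrix_rank(design_full)
    f = ((rss[0] - rss[1]) / df_effect) / (rss[1] / df_err)
    return f, sps.f.sf(f, df_effect, df_err)


def one_hot(levels):
    levels = np.asarray(levels)
    uniq = np.unique(levels)
    return (levels[:, None] == uniq[None, :]).astype(float)


class TestOneWay:
    def test_hand_computed_example(self):
        values = np.array([[1, 2, 3, 2, 3, 4, 3, 4, 5]], dtype=float)
        groups = [np.array([0, 1, 2]), np.array([3, 4, 5]), np.array([6, 7, 8])]
        f, p = one_way_anova(values, groups)
        assert f[0] == pytest.approx(3.0, abs=1e-12)  # SSB = 6, SSW = 6, df (2, 6)
        assert p[0] == pytest.approx(sps.f.sf(3.0, 2, 6), abs=1e-12)

    def test_identical_groups_give_f_zero(self):
        values = np.array([[1.0, 2, 3, 1, 2, 3]])
        f, p = one_way_anova(values, [np.arange(3), np.arange(3, 6)])
        assert f[0] == 0.0 and p[0] == 1.0

    def test_matches_rss_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 5)
            n = rng.integers(2, 5)
            y = rng.normal(size=k * n)
            levels = np.repeat(np.arange(k), n)
            groups = [np.flatnonzero(levels == g) for g in range(k)]
            f, p = one_way_anova(y[None, :], groups)
            X_full = one_hot(levels)
            X_red = np.ones((len(y), 1))
            f_o, p_o = rss_f_test(y, X_full, X_red, k - 1)
            assert f[0] == pytest.approx(f_o, abs=1e-10)
            assert p[0] == pytest.approx(p_o, abs=1e-10)
            f_sp, p_sp = sps.f_oneway(*(y[g] for g in groups))
            assert f[0] == pytest.approx(f_sp, rel=1e-10)

    def test_zero_residual_convention(self):
        values = np.array([[1.0, 1, 2, 2]])
        with pytest.warns(UserWarning, match="zero residual"):
            f, p = one_way_anova(values, [np.array([0, 1]), np.array([2, 3])])
        assert np.isinf(f[0]) and p[0] == 0.0


class TestTwoWay:
    def test_additive_cells_have_zero_interaction(self):
        # cell means [[1,2],[3,4]] with symmetric +/- eps replicate noise
        eps = 0.25
        cells = np.zeros((1, 2, 2, 3))
        for i, row in enumerate([[1.0, 2.0], [3.0, 4.0]]):
            for j, mean in enumerate(row):
                cells[0, i, j] = [mean - eps, mean, mean + eps]
        out = two_way_anova(cells)
        assert out["F_interaction"][0] == pytest.approx(0.0, abs=1e-12)
        assert out["p_interaction"][0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_rss_oracle_on_random_designs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, n = rng.integers(2, 5), 2, rng.integers(2, 4)
            cells = rng.normal(size=(1, a, b, n))
            out = two_way_anova(cells)
            y = cells[0].reshape(-1)
            ta = np.repeat(np.arange(a), b * n)
            tb = np.tile(np.repeat(np.arange(b), n), a)
            A, B = one_hot(ta), one_hot(tb)
            AB = np.einsum("ij,ik->ijk", A, B).reshape(len(y), -1)
            inter = np.hstack([A, B, AB])
            main = np.hstack([A, B])
            f_int, p_int = rss_f_test(y, inter, main, (a - 1) * (b - 1))
            assert out["F_interaction"][0] == pytest.approx(f_int, abs=1e-10)
            assert out["p_interaction"][0] == pytest.approx(p_int, abs=1e-10)
            # balanced main effects: SS from adding the factor to the other
            # main effect, residual from the full cell-mean model
            def rss(X):
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                return ((y - X @ beta) ** 2).sum()

            df_err = len(y) - np.linalg.matrix_rank(inter)
            mse = rss(inter) / df_err
            f_a = (rss(B) - rss(main)) / (a - 1) / mse
            f_b = (rss(A) - rss(main)) / (b - 1) / mse
            assert out["F_time"][0] == pytest.approx(f_a, abs=1e-10)
            assert out["F_condition"][0] == pytest.approx(f_b, abs=1e-10)

    def test_null_condition_pvalues_uniform(self):
        # pure time effect, no condition effect: p_condition ~ U(0,1)
        rng = np.random.default_rng(2)
        reps = 1000
        time_effect = rng.normal(size=(1, 12, 1, 1))
        cells = time_effect + rng.normal(size=(reps, 12, 2, 3))
        out = two_way_anova(cells)
        assert sps.kstest(out["p_condition"], "uniform").pvalue > 0.01

    def test_paper_shaped_design_has_df_11_48(self, small_dataset):
        matrix, design, _, _ = small_dataset
        out = two_way_time_condition_anova(matrix, design)
        # recompute one probe's p from its F with the expected df
        f = out["F_interaction"].iloc[0]
        assert out["p_interaction"].iloc[0] == pytest.approx(sps.f.sf(f, 11, 48))

    def test_unbalanced_cells_hard_error(self, small_dataset):
        matrix, design, _, _ = small_dataset
        broken = SampleDesign(design.table[design.table.sample_id != "amp_528_r3"])
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_time_condition_anova(
                matrix.subset_samples(list(broken.sample_ids)), broken
            )


class TestBH:
    def test_step_up_hand_example(self):
        adjusted, reject = bh_fdr([0.001, 0.01, 0.03, 0.5], 0.05)
        np.testing.assert_allclose(adjusted, [0.004, 0.02, 0.04, 0.5], atol=1e-12)
        assert reject.sum() == 3

    def test_all_ones(self):
        adjusted, reject = bh_fdr([1.0, 1.0, 1.0], 0.05)
        np.testing.assert_array_equal(adjusted, 1.0)
        assert not reject.any()

    def test_empty_input(self):
        adjusted, reject = bh_fdr([], 0.05)
        assert adjusted.size == 0 and reject.size == 0

    def test_adjusted_dominates_raw_and_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            adjusted, reject = bh_fdr(p, 0.05)
            assert (adjusted >= p - 1e-15).all()
            sm_reject, sm_adjusted, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adjusted, sm_adjusted, atol=1e-12)
            np.testing.assert_array_equal(reject, sm_reject)


def _paired_matrix(design, amp_rows, lw_rows, time):
    amp_ids, lw_ids = design.paired_samples(time)
    n_probes = len(amp_rows)
    frame = pd.DataFrame(
        np.ones((n_probes, len(design.sample_ids))),
        index=[f"p{i}" for i in range(n_probes)],
        columns=design.sample_ids,
    )
    frame.loc[:, amp_ids] = np.asarray(amp_rows, dtype=float)
    frame.loc[:, lw_ids] = np.asarray(lw_rows, dtype=float)
    return ExpressionMatrix(frame, scale_tag="percentile_shifted")


class TestPairedT:
    def test_identical_conditions_give_p_one(self, small_dataset):
        _, design, _, _ = small_dataset
        m = _paired_matrix(design, [[2, 3, 4]], [[2, 3, 4]], 24)
        out = paired_t_per_timepoint(m, design, 24)
        assert out["t"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_hand_computed_differences(self, small_dataset):
        _, design, _, _ = small_dataset
        # log2 differences [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641, df 2
        m = _paired_matrix(design, [[2.0, 4.0, 8.0]], [[1.0, 1.0, 1.0]], 24)
        out = paired_t_per_timepoint(m, design, 24)
        assert out["t"].iloc[0] == pytest.approx(np.sqrt(12), abs=1e-9)
        assert out["p"].iloc[0] == pytest.approx(2 * sps.t.sf(np.sqrt(12), 2), abs=1e-12)

    def test_matches_one_sample_t_oracle(self, small_dataset):
        _, design, _, _ = small_dataset
        rng = np.random.default_rng(4)
        amp = rng.uniform(1, 16, (50, 3))
        lw = rng.uniform(1, 16, (50, 3))
        m = _paired_matrix(design, amp, lw, 52)
        out = paired_t_per_timepoint(m, design, 52)
        t_o, p_o = sps.ttest_1samp(np.log2(amp) - np.log2(lw), 0.0, axis=1)
        t_rel, p_rel = sps.ttest_rel(np.log2(amp), np.log2(lw), axis=1)
        np.testing.assert_allclose(out["t"], t_o, atol=1e-12)
        np.testing.assert_allclose(out["p"], p_o, atol=1e-12)
        np.testing.assert_allclose(out["p"], p_rel, atol=1e-12)

    def test_constant_nonzero_difference_convention(self, small_dataset):
        _, design, _, _ = small_dataset
        m = _paired_matrix(design, [[4, 8, 16]], [[2, 4, 8]], 24)
        with pytest.warns(UserWarning, match="constant nonzero"):
            out = paired_t_per_timepoint(m, design, 24)
        assert out["p"].iloc[0] == 0.0


class TestFoldChange:
    @pytest.mark.parametrize(
        "amp, lw, passes",
        [(10.0, 5.0, True), (5.0, 10.0, True), (9.5, 5.0, False)],
    )
    def test_two_fold_rule(self, small_dataset, amp, lw, passes):
        _, design, _, _ = small_dataset
        m = _paired_matrix(design, [[amp] * 3], [[lw] * 3], 24)
        fc = fold_change(m, design, 24)
        assert bool(two_fold_rule(fc)[0]) is passes

    def test_fc_value(self, small_dataset):
        _, design, _, _ = small_dataset
        m = _paired_matrix(design, [[10.0, 10, 10]], [[5.0, 5, 5]], 24)
        assert fold_change(m, design, 24).iloc[0] == pytest.approx(2.0)


class TestLSD:
    def test_two_groups_equal_pooled_t(self, small_dataset):
        _, design, _, _ = small_dataset
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            rng.uniform(1, 100, (20, len(design.sample_ids))),
            index=[f"p{i}" for i in range(20)],
            columns=design.sample_ids,
        )
        m = ExpressionMatrix(frame, scale_tag="percentile_shifted")
        out = lsd_consecutive(m, design, "amputation", window=(3, 6))
        assert out.shape[1] == 1
        g3 = np.log2(frame[design.samples("amputation", 3)].to_numpy())
        g6 = np.log2(frame[design.samples("amputation", 6)].to_numpy())
        _, p_oracle = sps.ttest_ind(g3, g6, axis=1)
        np.testing.assert_allclose(out.iloc[:, 0], p_oracle, atol=1e-10)

    def test_identical_group_means_give_p_one(self, small_dataset):
        _, design, _, _ = small_dataset
        base = np.tile([2.0, 4.0, 8.0], (1, 28))
        frame = pd.DataFrame(
            base, index=["p0"], columns=design.sample_ids
        )
        m = ExpressionMatrix(frame, scale_tag="percentile_shifted")
        out = lsd_consecutive(m, design, "amputation")
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-12)

    def test_canonical_window_has_seven_pairs_per_condition(self, small_dataset):
        matrix, design, _, _ = small_dataset
        amp = lsd_consecutive(matrix, design, "amputation")
        lw = lsd_consecutive(matrix, design, "lateral_wound")
        assert amp.shape[1] == 7 and lw.shape[1] == 7
        assert list(amp.columns)[3] == "amputation_12_24"


class TestInvariances:
    def test_sample_order_and_global_scaling_invariance(self, small_dataset):
        matrix, design, _, _ = small_dataset
        sub = matrix.subset_probes(matrix.probe_ids[:40])
        base = two_way_time_condition_anova(sub, design)

        rng = np.random.default_rng(6)
        perm = list(rng.permutation(sub.sample_ids))
        shuffled = sub.subset_samples(perm)
        out_perm = two_way_time_condition_anova(shuffled, design)
        np.testing.assert_allclose(
            base["F_interaction"], out_perm["F_interaction"], rtol=1e-10
        )

        scaled = sub.with_values(sub.values * 7.0, "raw")
        out_scaled = two_way_time_condition_anova(scaled, design)
        np.testing.assert_allclose(
            base["F_interaction"], out_scaled["F_interaction"], rtol=1e-8
        )
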