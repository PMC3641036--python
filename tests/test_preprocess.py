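import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regenscreen.core_io import ExpressionMatrix
from regenscreen.preprocess import (
    filter_expressed,
    filter_marginal,
    floor_signals,
    nearest_rank_percentile,
    percentile_shift_normalize,
    probe_pair_concordance,
    quantile_normalize,
    standardize_rows,
    summarize_replicates,
)
from regenscreen.synthetic import SyntheticConfig, generate_dataset


def _matrix(rows, samples=None, scale="raw"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    frame = pd.DataFrame(rows, index=[f"p{i}" for i in range(rows.shape[0])], columns=samples)
    return ExpressionMatrix(frame, scale_tag=scale)


class TestFloorAndShift:
    def test_floor_rule_and_idempotence(self):
        m = _matrix([[3, 7], [5, 10]])
        once = floor_signals(m, 5.0)
        np.testing.assert_array_equal(once.values, [[5, 7], [5, 10]])
        assert once.scale_tag == "floored"
        twice = floor_signals(once, 5.0)
        np.testing.assert_array_equal(twice.values, once.values)

    def test_nearest_rank_percentile_definition(self):
        assert nearest_rank_percentile([1, 2, 3, 4], 75) == 3

    def test_percentile_shift_divides_by_sample_p75(self):
        m = _matrix([[1], [2], [3], [4]])
        shifted = percentile_shift_normalize(m, 75)
        np.testing.assert_allclose(shifted.values.ravel(), [1 / 3, 2 / 3, 1, 4 / 3])

    def test_constant_sample_maps_to_ones(self):
        m = _matrix([[7], [7], [7]])
        np.testing.assert_allclose(percentile_shift_normalize(m).values, 1.0)

    def test_every_output_sample_has_unit_p75(self, random_matrix):
        shifted = percentile_shift_normalize(floor_signals(random_matrix))
        for j in range(shifted.shape[1]):
            assert nearest_rank_percentile(shifted.values[:, j], 75) == pytest.approx(1.0)


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        m = _matrix(np.array([[1, 4], [2, 5], [3, 6]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_samples_unchanged(self):
        m = _matrix(np.tile([[5.0], [1.0], [9.0]], (1, 4)))
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_columns_share_sorted_vector_and_idempotent(self, random_matrix):
        out = quantile_normalize(random_matrix)
        ref = np.sort(out.values[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_array_equal(np.sort(out.values[:, j]), ref)
        again = quantile_normalize(out)
        np.testing.assert_array_equal(again.values, out.values)

    def test_rank_order_preserved_within_sample(self, random_matrix):
        out = quantile_normalize(random_matrix)
        for j in range(out.shape[1]):
            assert np.array_equal(
                np.argsort(out.values[:, j]), np.argsort(random_matrix.values[:, j])
            )


class TestExpressionFilters:
    def test_expressed_boundary_above_background(self):
        row = np.full(84, 50.0)
        row[:6] = 51.0
        kept = filter_expressed(_matrix([row]), background=50, min_samples=6)
        assert kept == ["p0"]

    def test_background_value_itself_not_expressed(self):
        kept = filter_expressed(_matrix([np.full(84, 50.0)]), 50, 6)
        assert kept == []

    def test_five_samples_insufficient(self):
        row = np.full(84, 10.0)
        row[:5] = 51.0
        assert filter_expressed(_matrix([row]), 50, 6) == []

    def test_marginal_fraction_is_strict(self):
        n = 100
        row81 = np.full(n, 10.0)
        row81[:19] = 60.0  # below background in 81%
        row80 = np.full(n, 10.0)
        row80[:20] = 60.0  # below background in exactly 80%
        high = np.full(n, 60.0)
        m = _matrix([row81, row80, high])
        assert filter_marginal(m, 50, 0.8) == ["p1", "p2"]

    def test_filters_nested_on_synthetic_data(self, small_dataset):
        matrix, _, _, _ = small_dataset
        expressed = set(filter_expressed(matrix))
        marginal_kept = set(filter_marginal(matrix))
        assert marginal_kept <= expressed


class TestSummarizeAndStandardize:
    def test_replicate_statistics(self):
        from regenscreen.core_io import SampleDesign

        design = SampleDesign(
            pd.DataFrame(
                [(f"a{r}", "amputation", 24, r) for r in (1, 2, 3)]
                + [(f"w{r}", "lateral_wound", 24, r) for r in (1, 2, 3)],
                columns=["sample_id", "condition", "time_hours", "replicate_id"],
            )
        )
        frame = pd.DataFrame(
            [[1, 2, 3, 1, 1, 1], [1, 1, 10, 2, 2, 2]],
            index=["a", "b"],
            columns=["a1", "a2", "a3", "w1", "w2", "w3"],
        )
        m = ExpressionMatrix(frame, scale_tag="raw")
        mean = summarize_replicates(m, design, "mean")
        med = summarize_replicates(m, design, "median")
        assert mean.data.loc["a", "amputation_024"] == 2
        assert med.data.loc["a", "amputation_024"] == 2
        assert mean.data.loc["b", "amputation_024"] == 4
        assert med.data.loc["b", "amputation_024"] == 1

    def test_group_count_matches_design(self, small_dataset):
        matrix, design, _, _ = small_dataset
        out = summarize_replicates(matrix, design)
        n_groups = design.table.groupby(["condition", "time_hours"], dropna=False).ngroups
        assert out.shape[1] == n_groups

    def test_standard_scores_use_population_sd(self):
        m = _matrix([[1, 2, 3]])
        out = standardize_rows(m, log_first=False)
        np.testing.assert_allclose(
            out.values.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )

    def test_rows_have_zero_mean_unit_sd_and_idempotence(self, random_matrix):
        out = standardize_rows(random_matrix, log_first=True)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-9)
        again = standardize_rows(out, log_first=False)
        np.testing.assert_allclose(again.values, out.values, atol=1e-9)

    def test_constant_row_excluded_with_warning(self):
        m = _matrix([[2, 2, 2], [1, 2, 3]])
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_rows(m, log_first=False)
        assert out.probe_ids == ["p1"]
        assert np.isfinite(out.values).all()


class TestConcordance:
    def _annot(self, pairs):
        rows = []
        for target, (pa, pb) in pairs.items():
            rows.append({"probe_id": pa, "target_id": target, "contig_id": target})
            rows.append({"probe_id": pb, "target_id": target, "contig_id": target})
        from regenscreen.core_io import ProbeAnnotation

        return ProbeAnnotation(pd.DataFrame(rows))

    def test_proportional_and_reversed_profiles(self):
        frame = pd.DataFrame(
            [[1, 2, 3], [2, 4, 6], [1, 2, 3], [3, 2, 1]],
            index=["a1", "a2", "b1", "b2"],
            columns=["s1", "s2", "s3"],
        )
        m = ExpressionMatrix(frame, scale_tag="raw")
        rep = probe_pair_concordance(m, self._annot({"A": ("a1", "a2"), "B": ("b1", "b2")}))
        r = rep.pairs.set_index("target_id")["r"]
        assert r["A"] == pytest.approx(1.0)
        assert r["B"] == pytest.approx(-1.0)
        assert rep.frac_r_gt_09 <= rep.frac_r_gt_08

    def test_variance_ratio_nine_gives_r_about_09(self):
        # shared profile variance / noise variance = 9 => expected r = 0.9
        rng = np.random.default_rng(42)
        n_targets, n_samples = 300, 84
        shared = rng.normal(0, 0.75, (n_targets, n_samples))
        rows, ids, pairs = [], [], {}
        for i in range(n_targets):
            a, b = f"t{i}_1", f"t{i}_2"
            rows.append(shared[i] + rng.normal(0, 0.25, n_samples))
            rows.append(shared[i] + rng.normal(0, 0.25, n_samples))
            ids += [a, b]
            pairs[f"t{i}"] = (a, b)
        m = ExpressionMatrix(
            pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n_samples)]),
            scale_tag="log2",
        )
        rep = probe_pair_concordance(m, self._annot(pairs))
        assert rep.n_pairs == n_targets
        assert np.median(rep.pairs["r"]) == pytest.approx(0.9, abs=0.05)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_operations_are_probe_permutation_equivariant(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(1, 500, (12, 5))
    m = _matrix(values)
    perm = rng.permutation(12)
    permuted = ExpressionMatrix(m.data.iloc[perm], scale_tag="raw")
    for op in (
        lambda x: floor_signals(x, 5.0),
        lambda x: percentile_shift_normalize(floor_signals(x)),
        quantile_normalize,
    ):
        direct = op(m).data.iloc[perm]
        via_perm = op(permuted).data
        pd.testing.assert_frame_equal(direct, via_perm)


def test_empirical_noise_sd_matches_config():
    config = SyntheticConfig(
        n_probes=2000,
        class_proportions={"null": 1.0},
        replicate_effect_sd=0.0,
        proximal_signature_fraction=0.0,
        rng_seed=3,
    )
    matrix, design, _, _ = generate_dataset(config)
    log2 = np.log2(matrix.values)
    # per-probe residual sd around the probe mean estimates the noise sd
    resid_sd = log2.std(axis=1, ddof=1).mean()
    assert resid_sd == pytest.approx(config.noise_sd_log2, rel=0.10)
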