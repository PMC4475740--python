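import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connectograph.edge_stats import (
    bh_fdr,
    bonferroni_mask,
    group_strength_anova,
    one_sample_edge_tests,
    select_altered_edges,
    summarize_altered,
    two_sample_edge_tests,
)
from .conftest import covariate_frame, stack_from_edges


def brute_force_bh(p, q):
    """Independent step-up oracle: check every k explicitly."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    if k_star:
        mask = p <= sorted_p[k_star - 1]
    return mask


def _stack(edge_values, group_sizes, atlas):
    return stack_from_edges(np.asarray(edge_values, dtype=float), covariate_frame(group_sizes), atlas)


class TestOneSample:
    def test_all_zero_edge_gives_t0_p1(self, atlas6):
        stack = _stack(np.zeros((4, 15)), {"NC": 4}, atlas6)
        out = one_sample_edge_tests(stack, "NC")
        assert np.all(out["t"] == 0.0) and np.all(out["p"] == 1.0)

    def test_hand_computed_t_statistic(self, atlas6):
        vals = np.zeros((4, 15))
        vals[:, 0] = [0.1, 0.2, 0.3, 0.4]
        out = one_sample_edge_tests(_stack(vals, {"NC": 4}, atlas6), "NC")
        assert out.loc[0, "t"] == pytest.approx(0.25 / (0.1290994 / 2), rel=1e-5)
        assert out.loc[0, "df"] == 3

    def test_matches_scipy_on_random_data(self, atlas6):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((8, 15)) + 0.2
        out = one_sample_edge_tests(_stack(vals, {"NC": 8}, atlas6), "NC")
        ref_t, ref_p = stats.ttest_1samp(vals, 0.0, axis=0)
        np.testing.assert_allclose(out["t"], ref_t, atol=1e-10)
        np.testing.assert_allclose(out["p"], ref_p, atol=1e-10)

    def test_constant_nonzero_edge_takes_limit_branch(self, atlas6, caplog):
        vals = np.zeros((4, 15))
        vals[:, 2] = 0.5
        with caplog.at_level("WARNING"):
            out = one_sample_edge_tests(_stack(vals, {"NC": 4}, atlas6), "NC")
        assert out.loc[2, "p"] == 0.0
        assert "zero-variance" in caplog.text

    def test_too_small_group_rejected(self, atlas6):
        with pytest.raises(ValueError, match=">= 3"):
            one_sample_edge_tests(_stack(np.zeros((2, 15)), {"NC": 2}, atlas6), "NC")


class TestBonferroni:
    def test_whole_brain_threshold(self):
        p = np.array([1.2e-5, 1.3e-5])
        mask = bonferroni_mask(p, alpha=0.05, m=4005)
        assert mask.tolist() == [True, False]  # threshold 0.05/4005 = 1.2484e-5

    def test_m_one_reduces_to_alpha(self):
        assert bonferroni_mask(np.array([0.04, 0.06]), alpha=0.05, m=1).tolist() == [True, False]

    def test_all_unit_p_rejects_nothing(self):
        assert not bonferroni_mask(np.ones(10)).any()

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bonferroni_rejections_subset_of_bh(self, p):
        p = np.asarray(p)
        bonf = bonferroni_mask(p, alpha=0.05)
        bh, _ = bh_fdr(p, q=0.05)
        assert np.all(~bonf | bh)


class TestTwoSample:
    def test_identical_groups_give_null_result(self, atlas6):
        vals = np.vstack([np.full((3, 15), 0.3), np.full((3, 15), 0.3)])
        out = two_sample_edge_tests(_stack(vals, {"NC": 3, "AD": 3}, atlas6), "NC", "AD")
        assert np.all(out["t"] == 0.0) and np.all(out["p"] == 1.0)

    def test_hand_computed_pooled_t(self, atlas6):
        vals = np.zeros((6, 15))
        vals[:3, 0] = [1.0, 2.0, 3.0]
        vals[3:, 0] = [2.0, 3.0, 4.0]
        out = two_sample_edge_tests(_stack(vals, {"NC": 3, "AD": 3}, atlas6), "NC", "AD")
        assert out.loc[0, "t"] == pytest.approx(-1.224745, rel=1e-6)
        assert out.loc[0, "df"] == 4

    def test_df_contract_for_study_sized_groups(self, atlas6):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((62, 15))
        out = two_sample_edge_tests(_stack(vals, {"NC": 27, "AD": 35}, atlas6), "NC", "AD")
        assert np.all(out["df"] == 60)

    def test_matches_scipy_pooled_and_welch(self, atlas6):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((12, 15))
        vals[:5] += 0.4
        stack = _stack(vals, {"NC": 5, "AD": 7}, atlas6)
        for equal_var in (True, False):
            out = two_sample_edge_tests(stack, "NC", "AD", equal_var=equal_var)
            ref_t, ref_p = stats.ttest_ind(vals[:5], vals[5:], axis=0, equal_var=equal_var)
            np.testing.assert_allclose(out["t"], ref_t, atol=1e-10)
            np.testing.assert_allclose(out["p"], ref_p, atol=1e-10)

    def test_sign_encodes_direction_a_minus_b(self, atlas6):
        vals = np.vstack([np.full((3, 15), 1.0), np.full((3, 15), 0.0) +
                          np.random.default_rng(3).normal(0, 0.01, (3, 15))])
        out = two_sample_edge_tests(_stack(vals, {"NC": 3, "AD": 3}, atlas6), "NC", "AD")
        assert np.all(out["t"] > 0)

    def test_pooled_t_equals_paired_one_sample_in_textbook_limit(self, atlas6):
        """Equal-n pooled t on y+d vs y with constant d matches the closed form
        d / sqrt(2 s^2 / n), s^2 the within-group variance."""
        rng = np.random.default_rng(4)
        n = 10
        y = rng.standard_normal(n)
        d = 0.8
        vals = np.zeros((2 * n, 15))
        vals[:n, 0] = y + d
        vals[n:, 0] = y
        out = two_sample_edge_tests(_stack(vals, {"NC": n, "AD": n}, atlas6), "NC", "AD")
        s2 = y.var(ddof=1)
        expected = d / np.sqrt(2 * s2 / n)
        assert out.loc[0, "t"] == pytest.approx(expected, rel=1e-10)


class TestBHFDR:
    def test_step_up_on_frozen_vector(self):
        # oracle: thresholds k*q/m = .01,.02,.03,.04,.05 -> largest passing k is 2
        p = [0.001, 0.008, 0.039, 0.041, 0.27]
        mask, critical = bh_fdr(p, q=0.05)
        assert mask.tolist() == [True, True, False, False, False]
        assert critical == 0.008
        assert mask.tolist() == brute_force_bh(p, 0.05).tolist()

    def test_all_unit_p_rejects_nothing(self):
        mask, critical = bh_fdr(np.ones(8), q=0.05)
        assert not mask.any() and critical == 0.0

    def test_single_p_reduces_to_alpha_comparison(self):
        mask, _ = bh_fdr([0.04], q=0.05)
        assert mask.tolist() == [True]

    def test_empty_input(self):
        mask, critical = bh_fdr([], q=0.05)
        assert mask.size == 0 and critical == 0.0

    def test_ties_share_fate(self):
        mask, _ = bh_fdr([0.03, 0.03, 0.9, 0.9], q=0.05)
        assert mask[0] == mask[1]
        oracle = brute_force_bh([0.03, 0.03, 0.9, 0.9], 0.05)
        assert mask.tolist() == oracle.tolist()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=300)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=50),
        st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    def test_matches_brute_force_oracle(self, p, q):
        mask, _ = bh_fdr(np.asarray(p), q=q)
        assert mask.tolist() == brute_force_bh(p, q).tolist()


class TestSelectAlteredEdges:
    def _planted_stack(self, atlas6, rng, delta=1.0, base=1.0):
        """NC/AD stack: all edges reliably nonzero, edge 0 reduced in AD by delta."""
        m = 15
        nc = base + 0.05 * rng.standard_normal((10, m))
        ad = base + 0.05 * rng.standard_normal((12, m))
        ad[:, 0] -= delta
        return _stack(np.vstack([nc, ad]), {"NC": 10, "AD": 12}, atlas6)

    def test_planted_difference_detected_and_labeled_decreased(self, atlas6):
        stack = self._planted_stack(atlas6, np.random.default_rng(5))
        out = select_altered_edges(stack, "NC", "AD")
        assert (0, 1) in set(zip(out["i"], out["j"]))  # edge index 0 is pair (0, 1)
        row = out[(out["i"] == 0) & (out["j"] == 1)].iloc[0]
        assert row["direction"] == "decreased"
        assert row["passed_control"]

    def test_strong_difference_with_null_strength_excluded_by_criterion_a(self, atlas6):
        """An edge whose z hovers around 0 in both groups fails the one-sample
        criterion even when the between-group contrast alone is significant."""
        n, m = 40, 15
        pattern = np.tile([1.0, -1.0], n // 2)  # mean 0, sd ~1, deterministic
        nc = np.full((n, m), 2.0)  # background edges: strong, identical across groups
        ad = np.full((n, m), 2.0)
        nc[:, 3] = 0.4 + pattern   # edge (0, 4): z ~ N(+-0.4, 1) -> one-sample t ~ 2.5
        ad[:, 3] = -0.4 + pattern
        stack = _stack(np.vstack([nc, ad]), {"NC": n, "AD": n}, atlas6)
        two = two_sample_edge_tests(stack, "NC", "AD")
        assert two.loc[3, "p"] < 0.0033  # criterion (b) alone would select it
        alpha_over_m = 0.05 / m
        assert one_sample_edge_tests(stack, "NC").loc[3, "p"] > alpha_over_m
        assert one_sample_edge_tests(stack, "AD").loc[3, "p"] > alpha_over_m
        out = select_altered_edges(stack, "NC", "AD")
        assert (0, 4) not in set(zip(out["i"], out["j"]))

    def test_classification_columns_present(self, atlas6):
        stack = self._planted_stack(atlas6, np.random.default_rng(7))
        out = select_altered_edges(stack, "NC", "AD")
        assert set(out["lobe_class"]) <= {"interlobe", "intralobe"}
        assert set(out["hemisphere_class"]) <= {"interhemispheric", "intrahemispheric"}


class TestSummarize:
    def test_empty_edge_table(self, atlas6):
        empty = pd.DataFrame(columns=["i", "j"])
        summary = summarize_altered(empty, atlas6)
        assert summary["n_altered"] == 0
        assert summary["node_degree"] == {}

    def test_hub_node_degree_and_ranking(self, atlas6):
        edges = pd.DataFrame({"i": [0, 0, 0], "j": [2, 3, 4]})
        summary = summarize_altered(edges, atlas6)
        top_name = atlas6.names[0]
        assert summary["node_degree"][top_name] == 3
        assert summary["top_nodes"][0] == top_name

    def test_lobe_tallies_partition_total(self, atlas6):
        rng = np.random.default_rng(8)
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        chosen = [pairs[k] for k in rng.choice(len(pairs), size=7, replace=False)]
        edges = pd.DataFrame(chosen, columns=["i", "j"])
        summary = summarize_altered(edges, atlas6)
        t = summary["tallies"]
        assert t["interlobe"] + t["intralobe"] == 7
        assert t["interhemispheric"] + t["intrahemispheric"] == 7


class TestStrengthANOVA:
    def test_study_sized_degrees_of_freedom(self, atlas6):
        rng = np.random.default_rng(9)
        vals = 0.3 + 0.05 * rng.standard_normal((89, 15))
        stack = _stack(vals, {"NC": 27, "AD": 35, "MCI": 27}, atlas6)
        out = group_strength_anova(stack)
        assert out["df1"] == 2 and out["df2"] == 86
        assert len(out["posthoc"]) == 3

    def test_identical_strengths_degenerate(self, atlas6, caplog):
        vals = np.full((6, 15), 0.3)
        stack = _stack(vals, {"NC": 3, "AD": 3}, atlas6)
        with caplog.at_level("WARNING"):
            out = group_strength_anova(stack)
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_fewer_than_two_groups_rejected(self, atlas6):
        stack = _stack(np.zeros((3, 15)), {"NC": 3}, atlas6)
        with pytest.raises(ValueError, match="2 groups"):
            group_strength_anova(stack)

    def test_group_means_reported_in_strength_units(self, atlas6):
        vals = np.vstack([np.full((3, 15), 0.5), np.full((3, 15), 0.2)])
        stack = _stack(vals, {"NC": 3, "AD": 3}, atlas6)
        out = group_strength_anova(stack)
        assert out["group_means"]["NC"] == pytest.approx(0.5)
        assert out["group_means"]["AD"] == pytest.approx(0.2)
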