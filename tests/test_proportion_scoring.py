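"""Region construction and sample counting for the proportion scores."""

import numpy as np
import pytest

from ifser.area_scoring import area_decomposition, class_order
from ifser.proportion_scoring import inclusion_region, overlap_region, proportion_scores
from ifser.stats_core import LabeledMatrix, compute_class_stats, effective_ranges

from conftest import random_range_table, stats_for_table, table_from_ranges


class TestOverlapRegion:
    def test_single_intersection(self):
        table = table_from_ranges([[(0, 2), (1, 3)]])
        assert overlap_region(0, 0, table) == [(1, 2)]
        assert overlap_region(0, 1, table) == [(1, 2)]

    def test_disjoint_classes_give_empty_region(self):
        table = table_from_ranges([[(0, 1), (2, 3)]])
        assert overlap_region(0, 0, table) == []

    def test_union_of_two_intersections(self):
        table = table_from_ranges([[(0, 4), (1, 2), (3, 5)]])
        assert overlap_region(0, 0, table) == [(1, 2), (3, 4)]

    def test_touching_pieces_merge(self):
        table = table_from_ranges([[(0, 4), (1, 2), (2, 3)]])
        assert overlap_region(0, 0, table) == [(1, 3)]


class TestInclusionRegion:
    def test_included_class_owns_its_range(self):
        table = table_from_ranges([[(0, 4), (1, 2)]])
        assert inclusion_region(0, 1, table) == [(1, 2)]
        assert inclusion_region(0, 0, table) == []

    def test_no_inclusion_no_region(self):
        table = table_from_ranges([[(0, 2), (1, 3)]])
        assert inclusion_region(0, 0, table) == []
        assert inclusion_region(0, 1, table) == []

    def test_zero_width_included_range(self):
        table = table_from_ranges([[(0, 2), (1, 1)]])
        assert inclusion_region(0, 1, table) == [(1, 1)]

    def test_both_convention_counts_including_class_too(self):
        table = table_from_ranges([[(0, 4), (1, 2)]])
        assert inclusion_region(0, 0, table, convention="both") == [(1, 2)]


def _data_for(table, values_per_class):
    """LabeledMatrix + stats with given per-class column values (1 feature)."""
    blocks, labels = [], []
    for j, vals in enumerate(values_per_class):
        blocks += [[v] for v in vals]
        labels += [f"c{j + 1}"] * len(vals)
    data = LabeledMatrix(values=np.array(blocks, dtype=float), labels=np.array(labels))
    stats = stats_for_table(table, [len(v) for v in values_per_class])
    return data, stats


class TestProportionScores:
    def test_disjoint_regions_give_perfect_scores(self):
        table = table_from_ranges([[(0, 1), (2, 3)]])
        data, stats = _data_for(table, [(0.2, 0.8), (2.2, 2.8)])
        props = proportion_scores(data, stats, table)
        assert props.h_total[0] == props.g_total[0] == 0.0
        assert props.nh[0] == props.gh[0] == 1.0

    def test_membership_count(self):
        # overlap region for class 1 is [1, 2]; only 1.5 falls inside
        table = table_from_ranges([[(0, 2), (1, 3)]])
        data, stats = _data_for(table, [(0.5, 1.5), (1.6, 2.5)])
        props = proportion_scores(data, stats, table)
        assert props.h_counts[0, 0] == 1
        assert props.h_counts[0, 1] == 1  # 1.6 in [1,2]

    def test_normalization_arithmetic(self):
        # two features with H totals in ratio 1:2 -> NH = (0.5, 0)
        table = table_from_ranges([[(0, 2), (1, 3)], [(0, 2), (0, 2)]])
        data = LabeledMatrix(
            values=np.array([[0.0, 1.0], [1.5, 1.0], [1.5, 1.0], [2.5, 1.0]]),
            labels=np.array(["c1", "c1", "c2", "c2"]),
        )
        stats = stats_for_table(table, [2, 2])
        props = proportion_scores(data, stats, table)
        np.testing.assert_allclose(props.h_total, [1.0, 2.0])
        np.testing.assert_allclose(props.nh, [0.5, 0.0])

    def test_boundary_value_counts_as_inside(self):
        table = table_from_ranges([[(0, 2), (1, 3)]])
        data, stats = _data_for(table, [(1.0, 0.0), (2.0, 2.9)])
        props = proportion_scores(data, stats, table)
        assert props.h_counts[0, 0] == 1  # value exactly at the region's lower end
        assert props.h_counts[0, 1] == 1  # and at its upper end

    def test_shape_mismatch_rejected(self):
        table = table_from_ranges([[(0, 2), (1, 3)]])
        data, stats = _data_for(table, [(0.5, 1.5), (1.6, 2.5)])
        bad = table_from_ranges([[(0, 2), (1, 3)], [(0, 1), (2, 3)]])
        with pytest.raises(ValueError, match="inconsistent"):
            proportion_scores(data, stats, bad)

    def test_extra_sample_in_region_does_not_raise_nh(self):
        table = table_from_ranges([[(0, 2), (1, 3)], [(0, 1), (5, 6)]])
        values = np.array([[0.5, 0.2], [1.5, 0.4], [1.6, 5.5], [2.5, 5.6]])
        data = LabeledMatrix(values=values, labels=np.array(["c1", "c1", "c2", "c2"]))
        stats = stats_for_table(table, [2, 2])
        before = proportion_scores(data, stats, table)
        # new class-a sample inside feature 0's overlap region, outside feature 1's
        values2 = np.vstack([values, [1.2, 3.0]])
        data2 = LabeledMatrix(values=values2, labels=np.array(["c1", "c1", "c2", "c2", "c1"]))
        stats2 = stats_for_table(table, [3, 2])
        after = proportion_scores(data2, stats2, table)
        assert after.nh[0] <= before.nh[0] + 1e-12


def _brute_force_counts(data, stats, table, mode="sorted", convention="included"):
    """Per-sample re-derivation of H and G from the raw pair definitions."""
    d, l = table.lower.shape
    order = class_order(table, mode)
    h = np.zeros((d, l), dtype=int)
    g = np.zeros((d, l), dtype=int)
    masks = [data.labels == c for c in stats.classes]
    for i in range(d):
        lo, hi = table.lower[i], table.upper[i]
        for j in range(l):
            for x in data.values[masks[j], i]:
                in_overlap = any(
                    max(lo[j], lo[k]) <= x <= min(hi[j], hi[k])
                    for k in range(l)
                    if k != j
                )
                h[i, j] += in_overlap
                in_incl = False
                for a in range(l - 1):
                    for b in range(a + 1, l):
                        ja, jb = int(order[i][a]), int(order[i][b])
                        if hi[ja] >= hi[jb]:
                            if j == jb or (convention == "both" and j == ja):
                                in_incl = in_incl or (lo[jb] <= x <= hi[jb])
                g[i, j] += in_incl
    return h, g


class TestCountingOracle:
    @pytest.mark.parametrize("convention", ["included", "both"])
    def test_counts_match_per_sample_brute_force(self, rng, convention):
        for _ in range(20):
            l = int(rng.integers(2, 5))
            d = 3
            table = random_range_table(rng, d, l)
            n_per = rng.integers(3, 8, size=l)
            values = rng.normal(0, 2.5, size=(int(n_per.sum()), d))
            labels = np.repeat([f"c{j + 1}" for j in range(l)], n_per)
            data = LabeledMatrix(values=values, labels=labels)
            stats = stats_for_table(table, n_per)
            props = proportion_scores(data, stats, table, convention=convention)
            h, g = _brute_force_counts(data, stats, table, convention=convention)
            np.testing.assert_array_equal(props.h_counts, h)
            np.testing.assert_array_equal(props.g_counts, g)

    def test_bounds_and_consistency(self, rng):
        for _ in range(20):
            l = int(rng.integers(2, 6))
            table = random_range_table(rng, 4, l)
            n_per = rng.integers(2, 9, size=l)
            values = rng.normal(0, 2, size=(int(n_per.sum()), 4))
            data = LabeledMatrix(
                values=values, labels=np.repeat([f"c{j + 1}" for j in range(l)], n_per)
            )
            stats = stats_for_table(table, n_per)
            props = proportion_scores(data, stats, table)
            scores = area_decomposition(table)
            assert np.all(props.h_counts <= stats.class_size)
            assert np.all(props.g_counts <= stats.class_size)
            assert np.all((props.nh >= 0) & (props.nh <= 1))
            assert np.all((props.gh >= 0) & (props.gh <= 1))
            if props.h_total.max() > 0:
                assert props.nh.min() == 0.0
            # a feature with no overlap (inclusion) area holds no samples there
            assert np.all(props.h_total[scores.oa == 0] == 0)
            assert np.all(props.g_total[scores.ia == 0] == 0)


class TestEndToEnd:
    def test_full_pipeline_consistency(self, two_class_data):
        stats = compute_class_stats(two_class_data)
        table = effective_ranges(stats, 1.732)
        props = proportion_scores(two_class_data, stats, table)
        # separated feature 0 holds far fewer overlap samples than noise features
        assert props.h_total[0] < props.h_total[1:].min()
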