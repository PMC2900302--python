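import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineagetf import (
    ADIPOCYTE,
    OSTEOBLAST,
    Behavior,
    BehaviorCall,
    ClassificationParams,
    ContingencyTable4,
    DataError,
    RatioSeries,
    candidate_switch_genes,
    classify_gene,
    compute_ratios,
    count_changed,
    cross_tabulate,
    per_timepoint_bounds,
)

WIDE = [(-100.0, 100.0)] * 3


def _toy_matrix(values_by_gene, osteo_times=(1.0, 3.0)):
    columns = ["ctrl_0h"] + [f"ob_{t:g}h" for t in osteo_times]
    expr = pd.DataFrame(values_by_gene, columns=columns).set_index(
        pd.Index([f"g{i}" for i in range(len(values_by_gene))], name="gene_id")
    )
    meta = pd.DataFrame(
        [("ctrl_0h", "control", 0.0, 1)]
        + [(f"ob_{t:g}h", OSTEOBLAST, t, 0) for t in osteo_times],
        columns=["sample_id", "lineage", "time_hours", "is_control"],
    )
    return expr, meta


class TestComputeRatios:
    def test_identical_intensities_give_zero_ratios(self):
        expr, meta = _toy_matrix([[8.0, 8.0, 8.0]])
        table = compute_ratios(expr, meta, OSTEOBLAST)
        assert table.series("g0").values == (0.0, 0.0)

    def test_ratio_is_log2_subtraction(self):
        expr, meta = _toy_matrix([[8.0, 10.0, 7.5]])
        table = compute_ratios(expr, meta, OSTEOBLAST)
        assert table.series("g0").values == (2.0, -0.5)

    def test_toy_matrix_matches_hand_subtraction(self):
        rows = [[8.0, 9.0, 6.0], [10.0, 10.0, 12.5], [5.0, 4.0, 5.0]]
        expr, meta = _toy_matrix(rows)
        table = compute_ratios(expr, meta, OSTEOBLAST)
        for i, row in enumerate(rows):
            expected = tuple(v - row[0] for v in row[1:])
            assert table.series(f"g{i}").values == expected

    def test_missing_control_is_hard_error(self):
        expr, meta = _toy_matrix([[8.0, 9.0, 6.0]])
        meta.loc[meta["is_control"] == 1, "is_control"] = 0
        with pytest.raises(DataError, match="control"):
            compute_ratios(expr, meta, OSTEOBLAST)

    def test_duplicate_lineage_time_is_hard_error(self):
        expr, meta = _toy_matrix([[8.0, 9.0, 6.0]], osteo_times=(1.0, 3.0))
        meta.loc[2, "time_hours"] = 1.0
        with pytest.raises(DataError, match="duplicate"):
            compute_ratios(expr, meta, OSTEOBLAST)

    def test_linear_scale_input_rejected(self):
        expr, meta = _toy_matrix([[256.0, 1024.0, 64.0]])
        with pytest.raises(DataError, match="log2"):
            compute_ratios(expr, meta, OSTEOBLAST)


class TestBounds:
    def test_zero_variance_collapses_to_point(self):
        assert per_timepoint_bounds([3.0, 3.0, 3.0], k=3.0) == (3.0, 3.0)

    def test_hand_computed_mean_and_population_sd(self):
        lower, upper = per_timepoint_bounds([0.0, 0.0, 0.0, 4.0], k=3.0)
        assert math.isclose(lower, 1 - 3 * math.sqrt(3))
        assert math.isclose(upper, 1 + 3 * math.sqrt(3))

    def test_degenerate_multiplier_returns_mean(self):
        assert per_timepoint_bounds([1.0, 3.0], k=0.0) == (2.0, 2.0)

    def test_fewer_than_two_values_is_error(self):
        with pytest.raises(DataError):
            per_timepoint_bounds([1.0], k=3.0)


def _series(values, gene="g", lineage=OSTEOBLAST):
    return RatioSeries(gene_id=gene, lineage=lineage, values=tuple(values))


class TestClassifyGene:
    def test_all_zero_series_is_unchanged(self):
        call = classify_gene(_series([0.0, 0.0, 0.0]), WIDE)
        assert call.call is Behavior.UNCHANGED
        assert call.up_times == () and call.down_times == ()

    def test_sustained_up_regulation(self):
        call = classify_gene(_series([1.5, 2.0, 1.2]), WIDE)
        assert call.call is Behavior.UP
        assert len(call.up_times) == 3

    def test_both_directions_give_up_down(self):
        call = classify_gene(_series([1.2, 0.0, -1.3]), WIDE)
        assert call.call is Behavior.UP_DOWN

    def test_value_exactly_at_threshold_does_not_fire(self):
        call = classify_gene(_series([1.0, -1.0, 0.0]), WIDE)
        assert call.call is Behavior.UNCHANGED

    def test_adaptive_bound_fires_below_fold_threshold(self):
        bounds = [(-0.5, 0.5)] * 3
        call = classify_gene(_series([0.8, 0.0, 0.0]), bounds)
        assert call.call is Behavior.UP

    def test_misaligned_bounds_are_an_error(self):
        with pytest.raises(DataError):
            classify_gene(_series([1.0, 2.0]), WIDE)

    def test_oracle_equivalence_over_all_125_three_point_patterns(self):
        # independent restatement of the rule: existential strict threshold
        levels = [-2.0, -1.2, 0.0, 1.2, 2.0]
        params = ClassificationParams(fold_threshold=1.0, sd_multiplier=3.0)
        for pattern in itertools.product(levels, repeat=3):
            up = any(v > 1.0 for v in pattern)
            down = any(v < -1.0 for v in pattern)
            expected = (
                Behavior.UP_DOWN if up and down
                else Behavior.UP if up
                else Behavior.DOWN if down
                else Behavior.UNCHANGED
            )
            call = classify_gene(_series(pattern), WIDE, params)
            assert call.call is expected, pattern

    @given(
        values=st.lists(
            st.floats(min_value=-4, max_value=4, allow_nan=False), min_size=2, max_size=8
        ),
        seed=st.integers(0, 2**16),
    )
    @settings(deadline=None, max_examples=100)
    def test_permutation_invariance_of_the_call(self, values, seed):
        rng = np.random.default_rng(seed)
        bounds = [(-abs(rng.normal()), abs(rng.normal())) for _ in values]
        times = list(range(1, len(values) + 1))
        base = classify_gene(_series(values), bounds, times=times)
        perm = rng.permutation(len(values))
        call = classify_gene(
            _series([values[i] for i in perm]),
            [bounds[i] for i in perm],
            times=[times[i] for i in perm],
        )
        assert call.call is base.call
        assert sorted(call.up_times) == sorted(base.up_times)
        assert sorted(call.down_times) == sorted(base.down_times)

    @given(
        values=st.lists(
            st.floats(min_value=-4, max_value=4, allow_nan=False), min_size=2, max_size=8
        ),
        thresholds=st.tuples(
            st.floats(min_value=0.1, max_value=3), st.floats(min_value=0.1, max_value=3)
        ),
    )
    @settings(deadline=None, max_examples=100)
    def test_raising_the_threshold_never_creates_regulation(self, values, thresholds):
        lo, hi = sorted(thresholds)
        bounds = [(-100.0, 100.0)] * len(values)
        loose = classify_gene(_series(values), bounds, ClassificationParams(lo, 3.0))
        strict = classify_gene(_series(values), bounds, ClassificationParams(hi, 3.0))
        assert set(strict.up_times) <= set(loose.up_times)
        assert set(strict.down_times) <= set(loose.down_times)
        if loose.call is Behavior.UNCHANGED:
            assert strict.call is Behavior.UNCHANGED

    def test_large_sd_multiplier_reduces_to_pure_fold_rule(self):
        values = [0.5, 1.5, -0.8, -2.0, 0.9]
        population = np.array([values, [0.0] * 5, [0.2] * 5])
        k = 1e9
        bounds = [
            per_timepoint_bounds(population[:, j], k) for j in range(len(values))
        ]
        call = classify_gene(
            _series(values), bounds, ClassificationParams(1.0, k),
            times=range(1, 6),
        )
        pure_up = tuple(t for t, v in enumerate(values, 1) if v > 1.0)
        pure_down = tuple(t for t, v in enumerate(values, 1) if v < -1.0)
        assert call.up_times == pure_up and call.down_times == pure_down


def _call(gene, lineage, behavior):
    up = (1.0,) if behavior in (Behavior.UP, Behavior.UP_DOWN) else ()
    down = (2.0,) if behavior in (Behavior.DOWN, Behavior.UP_DOWN) else ()
    return BehaviorCall(gene, lineage, behavior, up_times=up, down_times=down)


def _call_sets(pairs):
    """pairs: list of (osteoblast behavior, adipocyte behavior)."""
    osteo = {f"g{i}": _call(f"g{i}", OSTEOBLAST, o) for i, (o, _) in enumerate(pairs)}
    adipo = {f"g{i}": _call(f"g{i}", ADIPOCYTE, a) for i, (_, a) in enumerate(pairs)}
    return osteo, adipo


# Published cross-tabulation of 1,270 transcription factors:
# rows adipocyte, columns osteoblast, order UP/DOWN/UP_DOWN/UNCHANGED.
TABLE1_CELLS = (
    (22, 6, 4, 70),
    (25, 40, 21, 132),
    (3, 5, 2, 2),
    (42, 26, 7, 863),
)
ORDER = (Behavior.UP, Behavior.DOWN, Behavior.UP_DOWN, Behavior.UNCHANGED)


def table1_call_sets():
    pairs = []
    for a, row in zip(ORDER, TABLE1_CELLS):
        for o, count in zip(ORDER, row):
            pairs.extend([(o, a)] * count)
    return _call_sets(pairs)


class TestCrossTabulation:
    def test_empty_input_gives_zero_table(self):
        table = cross_tabulate({}, {})
        assert table.grand_total == 0
        assert count_changed(table) == 0

    def test_hand_tallied_five_gene_table(self):
        pairs = [
            (Behavior.UP, Behavior.UP),
            (Behavior.DOWN, Behavior.UP),
            (Behavior.DOWN, Behavior.DOWN),
            (Behavior.UNCHANGED, Behavior.UNCHANGED),
            (Behavior.UNCHANGED, Behavior.UNCHANGED),
        ]
        table = cross_tabulate(*_call_sets(pairs))
        assert table.cell(Behavior.UP, Behavior.UP) == 1
        assert table.cell(Behavior.UP, Behavior.DOWN) == 1
        assert table.cell(Behavior.DOWN, Behavior.DOWN) == 1
        assert table.cell(Behavior.UNCHANGED, Behavior.UNCHANGED) == 2
        assert table.grand_total == 5
        assert count_changed(table) == 3

    def test_published_1270_tf_marginals(self):
        table = cross_tabulate(*table1_call_sets())
        assert table.cells == TABLE1_CELLS
        assert table.col_totals == (92, 77, 34, 1067)
        assert table.row_totals == (102, 218, 12, 938)
        assert table.grand_total == 1270
        assert count_changed(table) == 407

    def test_gene_in_one_lineage_only_is_error(self):
        osteo, adipo = _call_sets([(Behavior.UP, Behavior.UP)])
        adipo["extra"] = _call("extra", ADIPOCYTE, Behavior.UP)
        with pytest.raises(DataError, match="extra"):
            cross_tabulate(osteo, adipo)

    @given(
        behaviors=st.lists(
            st.tuples(st.sampled_from(ORDER), st.sampled_from(ORDER)),
            min_size=0, max_size=60,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_conservation_and_marginal_consistency(self, behaviors):
        table = cross_tabulate(*_call_sets(behaviors))
        assert table.grand_total == len(behaviors)
        assert sum(table.row_totals) == sum(table.col_totals) == len(behaviors)
        unchanged_both = sum(
            1 for o, a in behaviors
            if o is Behavior.UNCHANGED and a is Behavior.UNCHANGED
        )
        assert count_changed(table) == len(behaviors) - unchanged_both


class TestSwitchCandidates:
    def test_pure_opposite_calls_qualify(self):
        pairs = [
            (Behavior.UP, Behavior.DOWN),
            (Behavior.UP, Behavior.DOWN),
            (Behavior.UP_DOWN, Behavior.DOWN),  # impure: excluded
            (Behavior.UP, Behavior.UP),
            (Behavior.DOWN, Behavior.UP),
            (Behavior.UNCHANGED, Behavior.UNCHANGED),
        ]
        osteo, adipo = _call_sets(pairs)
        assert candidate_switch_genes(osteo, adipo) == ["g0", "g1"]
        assert candidate_switch_genes(osteo, adipo, ("DOWN", "UP")) == ["g4"]

    def test_all_unchanged_gives_empty_list(self):
        pairs = [(Behavior.UNCHANGED, Behavior.UNCHANGED)] * 4
        assert candidate_switch_genes(*_call_sets(pairs)) == []

    def test_invalid_direction_rejected(self):
        with pytest.raises(DataError):
            candidate_switch_genes({}, {}, ("UP", "UP"))


class TestContingencyTableType:
    def test_negative_cell_rejected(self):
        cells = [[0] * 4 for _ in range(4)]
        cells[0][0] = -1
        with pytest.raises(DataError):
            ContingencyTable4(cells=tuple(tuple(r) for r in cells))

    def test_inconsistent_call_construction_rejected(self):
        with pytest.raises(DataError):
            BehaviorCall("g", OSTEOBLAST, Behavior.UP, up_times=(), down_times=())
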