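"""AICc partitioning, Tukey-Kramer comparisons, trend fit, heat-map bins."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hdpmeta import metapredict as mp
from hdpmeta.types import DegenerateInputError
from conftest import make_study


def outcomes_from(values_by_level, variable="pct_carrier_case"):
    out = []
    i = 0
    for level, values in values_by_level.items():
        for v in values:
            out.append(mp.StudyOutcome(f"S{i}", variable, float(v), level))
            i += 1
    return out


class TestComputeOutcomes:
    def test_percentages_and_null_rr(self):
        s = make_study(cases=(40, 40, 20), controls=(40, 40, 20))
        outcomes = {o.variable: o.value for o in mp.compute_outcomes([s])}
        assert outcomes["pct_variant_case"] == pytest.approx(20.0)
        assert outcomes["pct_carrier_case"] == pytest.approx(60.0)
        assert outcomes["rr_variant"] == pytest.approx(1.0)
        assert outcomes["rr_carrier"] == pytest.approx(1.0)

    def test_composition_oracle_from_raw_counts(self):
        s = make_study(cases=(10, 30, 60), controls=(50, 30, 20))
        outcomes = {o.variable: o.value for o in mp.compute_outcomes([s])}
        assert outcomes["pct_het_ctrl"] == pytest.approx(100 * 30 / 100)
        assert outcomes["rr_variant"] == pytest.approx((60 / 100) / (20 / 100))

    def test_double_zero_outcome_omitted(self):
        s = make_study(cases=(50, 50, 0), controls=(60, 40, 0))
        variables = {o.variable for o in mp.compute_outcomes([s])}
        assert "rr_variant" not in variables
        assert "pct_variant_case" in variables  # percentage is still defined


class TestAicc:
    def test_hand_arithmetic(self):
        # 20*ln(0.5) + 2*2 + 2*2*3/17
        expected = 20 * math.log(0.5) + 4.0 + 12.0 / 17.0
        assert mp.aicc(10.0, 20, 2) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_sse(self):
        assert mp.aicc(5.0, 20, 2) < mp.aicc(10.0, 20, 2)

    def test_undefined_when_overparameterized(self):
        with pytest.raises(DegenerateInputError):
            mp.aicc(1.0, 3, 2)

    def test_perfect_fit_dominates(self):
        assert mp.aicc(0.0, 20, 3) == float("-inf")


class TestPartitionSplit:
    def test_clear_shift_at_level_four(self):
        data = {2: [10.0, 10.1, 10.2, 9.9, 10.0], 3: [10.1, 9.8, 10.0, 10.2, 9.9],
                4: [20.0, 19.9, 20.1, 20.0, 20.2]}
        r = mp.partition_split(outcomes_from(data))
        assert r.chosen.groups == ((2, 3), (4,))
        assert r.is_split

    def test_constant_data_prefers_no_split(self):
        data = {l: [7.0] * 6 for l in (2, 3, 4)}
        r = mp.partition_split(outcomes_from(data))
        assert r.chosen.groups == ((2, 3, 4),)
        assert not r.is_split

    def test_single_level_rejected(self):
        with pytest.raises(DegenerateInputError):
            mp.partition_split(outcomes_from({3: [1.0] * 8}))

    def test_min_leaf_excludes_candidate(self):
        # level 4 has only 2 observations: both split candidates that
        # isolate it die, and {2}|{3,4} dies on the level-2 side too
        data = {2: [1.0] * 3, 3: [2.0] * 6, 4: [9.0, 9.5]}
        r = mp.partition_split(outcomes_from(data), min_leaf=5)
        assert r.chosen.groups == ((2, 3, 4),)

    def test_group_stats_match_table_layout(self):
        data = {2: [10.0, 12.0, 11.0, 13.0, 9.0], 3: [11.0, 10.0, 12.0, 9.5, 12.5],
                4: [21.0, 19.0, 20.0, 22.0, 18.0]}
        r = mp.partition_split(outcomes_from(data))
        g1, g2 = r.group_stats
        pooled = data[2] + data[3]
        assert g1.count == 10 and g2.count == 5
        assert g1.mean == pytest.approx(np.mean(pooled))
        assert g1.sd == pytest.approx(np.std(pooled, ddof=1))

    @settings(max_examples=250)
    @given(
        st.tuples(
            st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=12),
            st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=12),
            st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=12),
        )
    )
    def test_agrees_with_exhaustive_enumeration(self, triple):
        """Independent oracle: enumerate the no-split model and both
        contiguous cuts of levels {2,3,4}, score by a direct AICc
        transcription, take the argmin with simpler-model tie-break."""
        data = dict(zip((2, 3, 4), triple))
        n = sum(len(v) for v in data.values())

        def sse(groups):
            total = 0.0
            for grp in groups:
                vals = np.concatenate([np.asarray(data[l]) for l in grp])
                total += float(np.sum((vals - vals.mean()) ** 2))
            return total

        def aicc_direct(s, k):
            if s / n == 0:
                return float("-inf")
            return n * math.log(s / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

        candidates = [((2, 3, 4),), ((2,), (3, 4)), ((2, 3), (4,))]
        scored = [
            (aicc_direct(sse(c), len(c) + 1), len(c), c) for c in candidates
        ]
        best = min(scored, key=lambda t: (t[0], t[1]))[2]
        r = mp.partition_split(outcomes_from(data))
        assert r.chosen.groups == best
        # ledger must contain every candidate and its own minimum
        assert len(r.candidates) == 3
        assert r.chosen.aicc == min(c.aicc for c in r.candidates)


class TestTukey:
    def test_identical_groups_null(self):
        r = mp.tukey_hsd({2: [5.0, 5.0, 5.0], 3: [5.0, 5.0, 5.0], 4: [5.0] * 3})
        assert all(c.difference == 0.0 for c in r.comparisons)
        assert all(c.p_adjusted == pytest.approx(1.0) for c in r.comparisons)

    def test_two_groups_reduce_to_t_test(self):
        """With two groups the studentized range collapses to the pooled
        two-sample t-test (q = |t| * sqrt(2))."""
        a = [12.1, 9.8, 11.0, 10.5, 13.0]
        b = [8.0, 9.1, 7.5, 10.2]
        r = mp.tukey_hsd({2: a, 4: b})
        t, p = stats.ttest_ind(a, b, equal_var=True)
        (pair,) = r.comparisons
        assert pair.p_adjusted == pytest.approx(p, rel=1e-6)
        assert pair.difference == pytest.approx(abs(np.mean(a) - np.mean(b)))

    def test_three_groups_match_scipy_tukey(self):
        """Independent route: scipy's Tukey HSD on unbalanced groups."""
        rng = np.random.default_rng(17)
        groups = {2: rng.normal(10, 2, 12), 3: rng.normal(11, 2, 9),
                  4: rng.normal(14, 2, 15)}
        ours = mp.tukey_hsd(groups)
        ref = stats.tukey_hsd(*(groups[l] for l in (2, 3, 4)))
        idx = {2: 0, 3: 1, 4: 2}
        for c in ours.comparisons:
            i, j = idx[c.level_a], idx[c.level_b]
            assert c.p_adjusted == pytest.approx(float(ref.pvalue[i, j]), abs=1e-8)
            ci = ref.confidence_interval(0.95)
            assert c.ci_low == pytest.approx(float(ci.low[i, j]), rel=1e-6)
            assert c.ci_high == pytest.approx(float(ci.high[i, j]), rel=1e-6)

    def test_p_monotone_in_difference(self):
        """At fixed SE and df, a larger mean difference never raises the
        adjusted p-value."""
        base = {2: [0.0, 1.0, -1.0, 0.5, -0.5]}
        last_p = 1.1
        for shift in (0.0, 1.0, 2.0, 4.0):
            groups = dict(base)
            groups[4] = [v + shift for v in base[2]]
            (pair,) = mp.tukey_hsd(groups).comparisons
            assert pair.p_adjusted <= last_p + 1e-12
            last_p = pair.p_adjusted

    def test_antisymmetric_difference_accessor(self):
        r = mp.tukey_hsd({2: [1.0, 2.0, 3.0], 4: [4.0, 5.0, 6.0]})
        assert r.difference(4, 2) == pytest.approx(3.0)
        assert r.difference(2, 4) == pytest.approx(-3.0)

    def test_needs_two_groups(self):
        with pytest.raises(DegenerateInputError):
            mp.tukey_hsd({2: [1.0, 2.0]})


class TestTrendFit:
    def test_three_level_means_interpolate_exactly(self):
        data = {2: [10.0], 3: [14.0], 4: [22.0]}
        fit = mp.nonlinear_fit(outcomes_from(data))
        assert fit.degree == 2
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)
        assert fit.fitted[3] == pytest.approx(14.0)

    def test_constant_values_flat_curve(self):
        data = {l: [6.0, 6.0, 6.0] for l in (2, 3, 4)}
        fit = mp.nonlinear_fit(outcomes_from(data))
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficients[2] == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        data = {l: list(rng.normal(5 + l, 1, 7)) for l in (2, 3, 4)}
        fit = mp.nonlinear_fit(outcomes_from(data))
        x = np.array([l for l in (2, 3, 4) for _ in range(7)], float)
        y = np.concatenate([data[l] for l in (2, 3, 4)])
        X = np.c_[np.ones_like(x), x, x**2]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, beta, rtol=1e-8)

    def test_degree_reduces_with_two_levels(self):
        fit = mp.nonlinear_fit(outcomes_from({2: [1.0, 2.0], 4: [3.0, 4.0]}))
        assert fit.degree == 1


class TestHeatmap:
    def test_count_conservation(self):
        data = {2: [5.0, 15.0, 25.0], 3: [35.0], 4: [45.0, 55.0]}
        grid = mp.heatmap_bins(outcomes_from(data), y_edges=range(0, 70, 10))
        assert grid.counts.sum() == 6
        assert grid.n_clipped == 0

    def test_single_outcome_single_cell(self):
        grid = mp.heatmap_bins(outcomes_from({3: [12.0]}), y_edges=[0, 10, 20, 30])
        assert grid.counts.sum() == 1
        assert grid.counts[0, 1] == 1

    def test_translation_invariance(self):
        data = {2: [3.0, 7.0], 4: [12.0, 18.0]}
        shifted = {l: [v + 100.0 for v in vs] for l, vs in data.items()}
        g1 = mp.heatmap_bins(outcomes_from(data), y_edges=[0, 5, 10, 15, 20])
        g2 = mp.heatmap_bins(
            outcomes_from(shifted), y_edges=[100, 105, 110, 115, 120]
        )
        assert np.array_equal(g1.counts, g2.counts)

    def test_outside_values_clipped_into_edge_bins(self):
        grid = mp.heatmap_bins(
            outcomes_from({2: [-5.0, 105.0]}), y_edges=[0, 50, 100]
        )
        assert grid.n_clipped == 2
        assert grid.counts[0, 0] == 1 and grid.counts[0, 1] == 1

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            mp.heatmap_bins(outcomes_from({2: [1.0]}), y_edges=[0, 0, 1])
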