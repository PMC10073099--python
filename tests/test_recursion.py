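"""Uniformity testing and recursive cABC behavior."""

import numpy as np
import pytest
from scipy import stats

from cabc import (ItemSet, RecursionConfig, ks_uniformity_test, partition,
                  recursive_cabc, tiered_items)
from cabc.errors import ConfigError


class TestUniformityTest:
    def test_evenly_spaced_grid_hugs_uniform_cdf(self):
        res = ks_uniformity_test(np.linspace(2.0, 5.0, 20))
        assert res.statistic == pytest.approx(1 / 20, abs=1e-12)
        assert res.p_value > 0.999
        assert not res.identical

    def test_identical_values_are_identity_not_uniform(self):
        res = ks_uniformity_test(np.full(10, 3.3))
        assert res.p_value == 0.0
        assert res.identical

    def test_matches_independent_ecdf_computation(self):
        rng = np.random.default_rng(41)
        x = rng.chisquare(1.0, 200)
        res = ks_uniformity_test(x)
        # direct ECDF-distance route
        s = np.sort(x)
        u = (s - s.min()) / (s.max() - s.min())
        n = len(s)
        d_plus = np.max(np.arange(1, n + 1) / n - u)
        d_minus = np.max(u - np.arange(0, n) / n)
        d = max(d_plus, d_minus)
        assert res.statistic == pytest.approx(d, abs=1e-10)
        assert res.p_value == pytest.approx(float(stats.kstwo.sf(d, n)), abs=1e-10)
        assert res.p_value < 0.05


class TestRecursion:
    def test_uniform_input_stops_at_depth_zero(self):
        rng = np.random.default_rng(43)
        items = ItemSet.from_values(rng.uniform(0, 1, 1000))
        trace = recursive_cabc(items)
        assert trace.depth == 0
        assert trace.stop_reason == "uniform_distribution"
        assert trace.final_set == items.labels
        assert trace.final_name == ""

    def test_three_tier_vector_recovers_dominant_items(self):
        items = tiered_items(((2, 90, 100), (8, 8, 12), (90, 0, 0.2)), seed=1)
        trace = recursive_cabc(items)
        assert trace.depth >= 2
        # the two dominant items are the final set, confirmed brute force
        top2 = tuple(np.array(items.labels)[np.argsort(-items.values)[:2]])
        assert set(trace.levels[1].set_a) <= set(trace.levels[0].set_a)
        assert set(trace.final_set) == set(top2)

    def test_levels_match_direct_partition_recomputation(self):
        items = tiered_items(((3, 50, 60), (10, 5, 8), (60, 0, 0.5)), seed=9)
        trace = recursive_cabc(items)
        current = items
        for lvl in trace.levels:
            expected = partition(current)
            assert lvl.set_a == expected.set_a
            current = current.subset(expected.set_a)

    def test_strict_shrinkage_and_log_depth(self):
        rng = np.random.default_rng(47)
        items = ItemSet.from_values(rng.lognormal(0, 3, 1000))
        trace = recursive_cabc(items)
        sizes = [len(l.input_labels) for l in trace.levels]
        a_sizes = [len(l.set_a) for l in trace.levels]
        assert all(a < s for a, s in zip(a_sizes, sizes))
        assert trace.depth <= 10

    def test_nesting_invariant(self):
        rng = np.random.default_rng(53)
        items = ItemSet.from_values(rng.chisquare(1, 500))
        trace = recursive_cabc(items)
        sets = [set(items.labels)] + [set(l.set_a) for l in trace.levels]
        for outer, inner in zip(sets, sets[1:]):
            assert inner < outer
        assert set(trace.final_set) <= sets[-1]

    def test_deterministic(self):
        items = tiered_items(((2, 90, 100), (8, 8, 12), (40, 0, 0.2)), seed=3)
        t1 = recursive_cabc(items)
        t2 = recursive_cabc(items)
        assert t1.to_dict() == t2.to_dict()

    def test_target_size_and_miller_preset(self):
        rng = np.random.default_rng(59)
        items = ItemSet.from_values(rng.lognormal(0, 3, 300))
        trace = recursive_cabc(items, RecursionConfig.miller())
        assert trace.stop_reason in ("target_size_reached",
                                     "uniform_distribution", "too_few_items")
        if trace.stop_reason == "target_size_reached":
            assert len(trace.final_set) <= 9

    def test_max_depth(self):
        rng = np.random.default_rng(61)
        items = ItemSet.from_values(rng.lognormal(0, 3, 300))
        trace = recursive_cabc(items, RecursionConfig(max_depth=1))
        assert trace.depth <= 1

    def test_forced_level_on_uniform_vector_keeps_41_percent(self):
        rng = np.random.default_rng(67)
        items = ItemSet.from_values(rng.uniform(0, 1, 2000))
        trace = recursive_cabc(items, RecursionConfig(defer_uniformity=True))
        assert trace.depth >= 1
        frac = len(trace.levels[0].set_a) / items.n
        assert frac == pytest.approx(0.41, abs=0.02)

    def test_level_callback_stops(self):
        items = tiered_items(((2, 90, 100), (8, 8, 12), (90, 0, 0.2)), seed=1)
        calls = []

        def stop_after_first(level):
            calls.append(level.name)
            return False

        trace = recursive_cabc(items, RecursionConfig(level_callback=stop_after_first))
        assert calls == ["A"]
        assert trace.stop_reason == "callback_stop"
        assert trace.final_set == trace.levels[0].set_a

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigError):
            RecursionConfig(alpha=1.5)
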