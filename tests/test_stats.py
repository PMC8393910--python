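"""Blocked dose tests, pairwise comparisons, compact letter displays and
the mixture-vs-component grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pparmix.errors import ConfigError, FitError
from pparmix.mixtures import MixtureDesign
from pparmix.stats import (
    ComparisonResult,
    dose_effect_test,
    letter_display,
    mixture_vs_component_grid,
    pairwise_compare,
)


def blocked(doses, folds_by_rep):
    d, y, r = [], [], []
    for rep, folds in enumerate(folds_by_rep, 1):
        d.extend(doses)
        y.extend(folds)
        r.extend([rep] * len(doses))
    return np.array(d), np.array(y), np.array(r)


class TestDoseEffect:
    def test_identical_folds_across_doses_give_p_one(self):
        # folds flat in dose; only tiny replicate-level jitter remains,
        # which the block term absorbs entirely
        doses = [0, 100, 200, 300]
        d, y, r = blocked(doses, [np.ones(4) + 1e-6, np.ones(4) - 1e-6])
        assert dose_effect_test(d, y, r) == pytest.approx(1.0)

    def test_strong_trend_is_significant(self):
        doses = np.array([0, 100, 200, 300])
        rng = np.random.default_rng(1)
        reps = [1 + 0.006 * doses + rng.normal(0, 0.05, 4) for _ in range(4)]
        d, y, r = blocked(doses, reps)
        assert dose_effect_test(d, y, r) < 1e-4

    def test_block_offsets_do_not_create_a_dose_effect(self):
        doses = [0, 100, 200, 300]
        d, y, r = blocked(doses, [np.ones(4), np.ones(4) + 5.0])
        assert dose_effect_test(d, y, r) > 0.5

    def test_degenerate_designs_rejected(self):
        with pytest.raises(FitError):
            dose_effect_test([0, 0, 0, 0], [1, 2, 1, 2], [1, 1, 2, 2])
        with pytest.raises(FitError):
            dose_effect_test([0, 100], [1, 2], [1, 1])


class TestPairwise:
    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(3)
        groups = {
            "lo": 1 + rng.normal(0, 0.1, 4),
            "hi": 10 + rng.normal(0, 0.1, 4),
        }
        [res] = pairwise_compare(groups)
        assert res.significant
        assert res.estimate == pytest.approx(9.0, abs=0.5)

    def test_identical_groups_null_result(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05])
        [res] = pairwise_compare({"a": vals, "b": vals.copy()})
        assert res.estimate == 0.0
        assert not res.significant

    def test_relabelling_and_location_invariance(self):
        rng = np.random.default_rng(4)
        g = {f"g{i}": rng.normal(i * 0.2, 0.3, 4) for i in range(3)}
        base = {(r.group_a, r.group_b): r.p_value for r in pairwise_compare(g)}
        shifted = pairwise_compare({k: v + 100.0 for k, v in g.items()})
        for r in shifted:
            assert r.p_value == pytest.approx(base[(r.group_a, r.group_b)], abs=1e-9)

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            pairwise_compare({"a": [1.0], "b": [1.0, 2.0]})

    @pytest.mark.parametrize("adjust", ["none", "bonferroni"])
    def test_alternative_adjustments_available(self, adjust):
        rng = np.random.default_rng(5)
        g = {f"g{i}": rng.normal(0, 1, 4) for i in range(3)}
        res = pairwise_compare(g, adjust=adjust)
        assert len(res) == 3
        assert all(0 <= r.p_value <= 1 for r in res)


def make_results(order, significant_pairs):
    res = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            sig = frozenset((a, b)) in significant_pairs
            res.append(ComparisonResult(a, b, 0.0, 0.01 if sig else 0.9, sig))
    return res


class TestLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = letter_display(make_results(["a", "b", "c"], set()))
        assert len({ls for ls in letters.values()}) == 1

    def test_all_different_disjoint_letters(self):
        order = ["t1", "t2", "t3"]
        pairs = {frozenset(p) for p in [("t1", "t2"), ("t1", "t3"), ("t2", "t3")]}
        letters = letter_display(make_results(order, pairs))
        sets = [set(ls) for ls in letters.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not sets[i] & sets[j]

    def test_chain_structure_gets_bridging_letter(self):
        # only the extremes differ: a / ab / b
        letters = letter_display(
            make_results(["g1", "g2", "g3"], {frozenset(("g1", "g3"))})
        )
        assert letters["g1"] == ("a",)
        assert letters["g2"] == ("a", "b")
        assert letters["g3"] == ("b",)

    def test_missing_pairs_rejected(self):
        res = make_results(["a", "b", "c"], set())[:-1]
        with pytest.raises(ValueError):
            letter_display(res)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_reconstructs_significance(self, data):
        """Sharing no letter must be exactly equivalent to a significant
        pairwise difference, for arbitrary significance patterns."""
        n = data.draw(st.integers(min_value=2, max_value=7))
        order = [f"t{i}" for i in range(n)]
        all_pairs = [
            frozenset((a, b)) for i, a in enumerate(order) for b in order[i + 1 :]
        ]
        chosen = {
            p for p in all_pairs if data.draw(st.booleans(), label=str(sorted(p)))
        }
        letters = letter_display(make_results(order, chosen))
        for p in all_pairs:
            a, b = sorted(p)
            share = bool(set(letters[a]) & set(letters[b]))
            assert share != (p in chosen)


class TestGrid:
    def _measurements(self):
        rng = np.random.default_rng(6)
        return {
            "C12:0@500": 4.0 + rng.normal(0, 0.1, 4),
            "C16:0@158": 3.0 + rng.normal(0, 0.1, 4),
            "C12:0+C16:0": 12.0 + rng.normal(0, 0.1, 4),  # 3x the component
        }

    def test_strong_mixture_effect_flagged(self):
        mix = MixtureDesign((("C12:0", 500.0), ("C16:0", 158.0)))
        grid = mixture_vs_component_grid(
            [mix],
            {"C12:0": "C12:0@500", "C16:0": "C16:0@158"},
            self._measurements(),
        )
        assert grid.loc["C12:0", "C12:0+C16:0"] is True
        assert grid.loc["C16:0", "C12:0+C16:0"] is True

    def test_identical_mixture_not_flagged(self):
        vals = np.array([3.0, 3.1, 2.9, 3.05])
        mix = MixtureDesign((("C16:0", 158.0), ("C18:0", 190.0)))
        grid = mixture_vs_component_grid(
            [mix],
            {"C16:0": "C16:0@158"},
            {"C16:0@158": vals, "C16:0+C18:0": vals.copy()},
        )
        assert grid.loc["C16:0", "C16:0+C18:0"] is False

    def test_fa_without_mixtures_has_empty_row(self):
        mix = MixtureDesign((("C16:0", 158.0), ("C18:0", 190.0)))
        grid = mixture_vs_component_grid(
            [mix],
            {"C12:0": "C12:0@500", "C16:0": "C16:0@158"},
            self._measurements()
            | {"C16:0+C18:0": np.array([3.0, 3.1, 2.9, 3.05])},
        )
        assert grid.loc["C12:0"].isna().all()

    def test_missing_single_measurement_rejected(self):
        mix = MixtureDesign((("C12:0", 500.0), ("C16:0", 158.0)))
        with pytest.raises(ConfigError):
            mixture_vs_component_grid(
                [mix], {"C12:0": "C12:0@500"}, {"C12:0+C16:0": np.ones(4)}
            )
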