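"""Simulator contracts: dose series geometry, truth evaluation, mixture
truth modes, determinism, viability shape, and statistical faithfulness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pparmix.errors import InvalidDesignError
from pparmix.normalize import fold_changes
from pparmix.mixtures import MixtureDesign
from pparmix.simulate import (
    PlateDesign,
    TruthModel,
    make_dose_series,
    parse_components,
    read_plate_csv,
    simulate_plate,
    true_fold,
    true_mixture_fold,
    write_plate_csv,
)


class TestDoseSeries:
    def test_ten_point_series_spans_zero_to_max(self):
        doses = make_dose_series(500, 10)
        assert doses[0] == 0.0
        assert doses[-1] == 500.0
        assert len(doses) == 10
        assert doses[1] == pytest.approx(500 / 9)

    @given(
        max_dose=st.floats(min_value=1.0, max_value=1000.0),
        n=st.integers(min_value=2, max_value=20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_series_evenly_spaced(self, max_dose, n):
        doses = make_dose_series(max_dose, n)
        assert len(doses) == n
        assert doses[0] == 0.0 and doses[-1] == pytest.approx(max_dose)
        assert np.allclose(np.diff(doses), max_dose / (n - 1))

    @pytest.mark.parametrize("bad", [(0, 10), (-5, 10), (500, 1), (500, 0)])
    def test_invalid_series_rejected(self, bad):
        with pytest.raises(InvalidDesignError):
            make_dose_series(*bad)


class TestTruth:
    def test_fold_is_one_at_vehicle_dose(self, noise_free_truth):
        for fa in noise_free_truth.fa_params:
            assert true_fold(fa, 0.0, noise_free_truth) == 1.0

    def test_quadratic_fold_and_vertex(self, quad_truth):
        assert true_fold("C16:0", 250, quad_truth) == pytest.approx(3.5)
        grid = np.linspace(0, 500, 5001)
        vals = [true_fold("C16:0", d, quad_truth) for d in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(250, abs=0.2)

    def test_unknown_fa_and_negative_dose(self, quad_truth):
        with pytest.raises(KeyError):
            true_fold("C99:9", 10, quad_truth)
        with pytest.raises(InvalidDesignError):
            true_fold("C16:0", -1, quad_truth)

    def test_intercept_other_than_one_rejected(self):
        with pytest.raises(InvalidDesignError):
            TruthModel(fa_params={"X": (2.0, 0.0, 0.0)})


class TestMixtureTruth:
    # linear truths give fold 2.0 at 100 µM (A) and 3.0 at 100 µM (B)
    @pytest.fixture
    def two_fa_truth(self):
        def build(mode="weighted", kappa=1.0):
            return TruthModel(
                fa_params={"A": (1.0, 0.01, 0.0), "B": (1.0, 0.02, 0.0)},
                mixture_mode=mode,
                kappa=kappa,
                noise_cv=0.0,
            )

        return build

    def test_single_component_degenerates_to_true_fold(self, two_fa_truth):
        for mode in ("weighted", "additive", "synergy"):
            t = two_fa_truth(mode)
            assert true_mixture_fold([("A", 100.0)], t) == pytest.approx(2.0)

    def test_weighted_mean_of_equal_folds(self, two_fa_truth):
        t = two_fa_truth("weighted")
        # A at 200 µM and B at 100 µM both sit at fold 3.0
        assert true_mixture_fold([("A", 200.0), ("B", 100.0)], t) == pytest.approx(3.0)

    def test_synergy_scales_additive_sum(self, two_fa_truth):
        t = two_fa_truth("synergy", kappa=1.5)
        assert true_mixture_fold(
            [("A", 100.0), ("B", 100.0)], t
        ) == pytest.approx(1.5 * (2.0 + 3.0))

    def test_empty_mixture_rejected(self, two_fa_truth):
        with pytest.raises(InvalidDesignError):
            true_mixture_fold([], two_fa_truth())


class TestSimulatePlate:
    def test_noise_free_vehicle_ratio_is_base_ratio(self, noise_free_truth):
        design = PlateDesign(n_replicates=2)
        df = simulate_plate(design, noise_free_truth, seed=0)
        ratio = df["firefly"] / df["renilla"]
        expected = noise_free_truth.base_firefly / noise_free_truth.base_renilla
        assert np.allclose(ratio, expected)

    def test_noise_free_fold_survives_normalization(self, quad_truth):
        design = PlateDesign(singles=(("C16:0", 250.0),), n_replicates=2)
        norm = fold_changes(simulate_plate(design, quad_truth, seed=0))
        treated = norm[norm["treatment"] != "vehicle"]
        assert np.allclose(treated["fold_change"], 3.5)

    def test_same_seed_reproduces_byte_identical_csv(
        self, noise_free_truth, small_series_design, tmp_path
    ):
        import dataclasses

        t = dataclasses.replace(noise_free_truth, noise_cv=0.1)
        a = simulate_plate(small_series_design, t, seed=42)
        b = simulate_plate(small_series_design, t, seed=42)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_plate_csv(a, pa)
        write_plate_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()
        c = simulate_plate(small_series_design, t, seed=43)
        assert not a["firefly"].equals(c["firefly"])

    def test_renilla_nonincreasing_in_total_dose_without_noise(self):
        truth = TruthModel(
            fa_params={"C16:0": (1.0, 0.001, 0.0)},
            noise_cv=0.0,
            viability_onset=50.0,
            viability_rate=0.01,
        )
        design = PlateDesign(fa_series={"C16:0": 500.0}, n_replicates=1)
        df = simulate_plate(design, truth, seed=0)
        treated = df[df["treatment"] != "vehicle"].copy()
        treated["dose"] = [parse_components(c)[0][1] for c in treated["components"]]
        treated = treated.sort_values("dose")
        assert (np.diff(treated["renilla"]) <= 1e-9).all()

    def test_synergy_with_unit_kappa_equals_additive_mode(self):
        params = {"A": (1.0, 0.01, 0.0), "B": (1.0, 0.02, 0.0)}
        mix = MixtureDesign((("A", 100.0), ("B", 50.0)))
        design = PlateDesign(mixtures=(mix,))
        kw = dict(fa_params=params, noise_cv=0.1)
        add = simulate_plate(design, TruthModel(mixture_mode="additive", **kw), 7)
        syn = simulate_plate(
            design, TruthModel(mixture_mode="synergy", kappa=1.0, **kw), 7
        )
        pd.testing.assert_frame_equal(add, syn)

    def test_mean_simulated_fold_unbiased_across_seeds(self, quad_truth):
        """Across 500 seeds the simulated fold at a fixed dose matches the
        truth within 3 standard errors."""
        import dataclasses

        truth = dataclasses.replace(quad_truth, noise_cv=0.10)
        design = PlateDesign(
            singles=(("C16:0", 250.0),),
            n_replicates=2,
            n_vehicle_per_replicate=4,
        )
        means = []
        for seed in range(500):
            norm = fold_changes(simulate_plate(design, truth, seed))
            means.append(
                norm.loc[norm["treatment"] != "vehicle", "fold_change"].mean()
            )
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 3.5) < 3 * se


class TestCsvRoundTrip:
    def test_components_round_trip_exactly(self, quad_truth, tmp_path):
        design = PlateDesign(fa_series={"C16:0": 500.0}, n_replicates=2)
        df = simulate_plate(design, quad_truth, seed=5)
        path = tmp_path / "plate.csv"
        write_plate_csv(df, path)
        back = read_plate_csv(path)
        doses = {
            parse_components(c)[0][1]
            for c in back["components"].unique()
            if c
        }
        assert doses == set(np.linspace(0, 500, 10))

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plate_id,firefly\nP1,1\n")
        with pytest.raises(InvalidDesignError):
            read_plate_csv(path)
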